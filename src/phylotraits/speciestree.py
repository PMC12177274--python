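"""Maximum-quartet-support species trees with coalescent branch lengths.

Each gene tree induces one of three unrooted resolutions (ab|cd, ac|bd,
ad|bc) for every four-taxon subset it contains.  The species tree is the
unrooted topology maximizing the total number of induced gene-tree quartets
it agrees with — for small taxon counts this optimum is found by exhaustive
enumeration of all (2n-5)!! unrooted binary topologies, which is the exact
version of the summary-coalescent estimator popularized by ASTRAL.

Under the multispecies coalescent, the probability that a gene-tree quartet
agrees with the species tree around an internal branch of length d
coalescent units is q = 1 - (2/3) e^{-d}; inverting gives
d = -ln(3(1-q)/2), which converts the observed quartet-support fraction q of
each internal branch into coalescent units.  q = 1/3 is the random-
resolution floor; q = 1 maps to a capped length (perfectly supported
branches would otherwise be infinite).

A lightweight multispecies-coalescent gene-tree simulator (rate-1
exponential coalescence within species-tree intervals) is included for
recovery experiments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import treekit
from .treekit import tip_labels

__all__ = [
    "QuartetTable",
    "SpeciesTreeResult",
    "induced_quartets",
    "quartet_table",
    "enumerate_topologies",
    "exact_quartet_species_tree",
    "coalescent_branch_length",
    "simulate_msc_gene_tree",
]

Split = frozenset  # frozenset({frozenset(pair), frozenset(pair)})


def _split(pair_a, pair_b) -> Split:
    return frozenset({frozenset(pair_a), frozenset(pair_b)})


@dataclass
class QuartetTable:
    """Counts of induced resolutions per four-taxon subset.

    ``counts[subset][split]`` is the number of gene trees inducing that
    resolution; ``n_trees[subset]`` counts gene trees containing all four
    taxa (resolved or not)."""

    counts: dict[frozenset, dict[Split, int]] = field(default_factory=dict)
    n_trees: dict[frozenset, int] = field(default_factory=dict)

    def add(self, subset: frozenset, split: Split | None) -> None:
        self.n_trees[subset] = self.n_trees.get(subset, 0) + 1
        if split is not None:
            per = self.counts.setdefault(subset, {})
            per[split] = per.get(split, 0) + 1

    def resolved(self, subset: frozenset) -> int:
        return sum(self.counts.get(subset, {}).values())


def induced_quartets(tree: dendropy.Tree) -> dict[frozenset, Split | None]:
    """Resolution induced by one tree for every four-taxon subset it has.

    A subset {a, b, c, d} resolves as ab|cd iff some edge of the tree
    separates {a, b} from {c, d}.  Subsets left unseparated by every edge
    (polytomies) map to ``None``.  Trees with fewer than four taxa
    contribute nothing.
    """
    taxa = sorted(tip_labels(tree))
    if len(taxa) < 4:
        return {}
    splits = [labels for labels, _ in treekit.edge_leaf_sets(tree)]
    all_taxa = frozenset(taxa)
    out: dict[frozenset, Split | None] = {}
    for quartet in itertools.combinations(taxa, 4):
        qset = frozenset(quartet)
        resolution = None
        for below in splits:
            inside = qset & below
            if len(inside) == 2:
                outside = qset - inside
                resolution = _split(inside, outside)
                break
        out[qset] = resolution
    return out


def quartet_table(gene_trees) -> QuartetTable:
    table = QuartetTable()
    for tree in gene_trees:
        for subset, split in induced_quartets(tree).items():
            table.add(subset, split)
    return table


# ---------------------------------------------------------------------------
# Topology enumeration (adjacency representation)
# ---------------------------------------------------------------------------


class _Topology:
    """Unrooted binary topology as an adjacency map; leaves carry labels."""

    def __init__(self, adj: dict[int, set[int]], leaves: dict[int, str]):
        self.adj = adj
        self.leaves = leaves

    def edges(self):
        seen = set()
        for a, nbrs in self.adj.items():
            for b in nbrs:
                if (b, a) not in seen:
                    seen.add((a, b))
                    yield (a, b)

    def leaf_set_below(self, a: int, b: int) -> frozenset:
        """Labels reachable from b without crossing edge (a, b)."""
        stack, visited = [b], {a, b}
        labels = set()
        while stack:
            node = stack.pop()
            if node in self.leaves:
                labels.add(self.leaves[node])
            for nbr in self.adj[node]:
                if nbr not in visited:
                    visited.add(nbr)
                    stack.append(nbr)
        return frozenset(labels)

    def nontrivial_splits(self) -> list[frozenset]:
        all_labels = frozenset(self.leaves.values())
        out = []
        for a, b in self.edges():
            side = self.leaf_set_below(a, b)
            if 2 <= len(side) <= len(all_labels) - 2:
                out.append(side)
        return out

    def internal_edges(self):
        for a, b in self.edges():
            if a not in self.leaves and b not in self.leaves:
                yield (a, b)

    def adjacent_subtrees(self, a: int, b: int) -> tuple[frozenset, ...]:
        """Leaf sets of the four subtrees around internal edge (a, b):
        two hanging off ``a`` (excluding b's side), two off ``b``."""
        sides = []
        for hub, other in ((a, b), (b, a)):
            for nbr in sorted(self.adj[hub] - {other}):
                sides.append(self.leaf_set_below(hub, nbr))
        return tuple(sides)

    def to_dendropy(self) -> dendropy.Tree:
        labels = sorted(self.leaves.values())
        ns = dendropy.TaxonNamespace(labels)
        # root at the internal node adjacent to the first leaf
        first_leaf = min(self.leaves, key=lambda i: self.leaves[i])
        start = next(iter(self.adj[first_leaf]))

        def build(node: int, parent: int) -> dendropy.Node:
            dnode = dendropy.Node()
            if node in self.leaves:
                dnode.taxon = ns.get_taxon(self.leaves[node])
            for nbr in sorted(self.adj[node]):
                if nbr != parent:
                    dnode.add_child(build(nbr, node))
            return dnode

        tree = dendropy.Tree(taxon_namespace=ns, seed_node=build(start, -1))
        tree.is_rooted = False
        return tree


def enumerate_topologies(taxa: list[str]):
    """Yield every unrooted binary topology over the given taxa.

    There are (2n-5)!! of them; built by sequentially attaching each taxon
    to every edge of every smaller topology.
    """
    taxa = sorted(taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")

    def grow(topo: _Topology, next_index: int):
        if next_index == n:
            yield topo
            return
        label = taxa[next_index]
        for a, b in list(topo.edges()):
            adj = {k: set(v) for k, v in topo.adj.items()}
            leaves = dict(topo.leaves)
            mid = max(adj) + 1
            leaf = mid + 1
            adj[a].discard(b)
            adj[b].discard(a)
            adj[a].add(mid)
            adj[b].add(mid)
            adj[mid] = {a, b, leaf}
            adj[leaf] = {mid}
            leaves[leaf] = label
            yield from grow(_Topology(adj, leaves), next_index + 1)

    # quartet seed: internal nodes 3,4; leaves 0..2 plus taxon 3 grown in
    adj = {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}
    leaves = {0: taxa[0], 1: taxa[1], 2: taxa[2]}
    yield from grow(_Topology(adj, leaves), 3)


def _score_topology(splits: list[frozenset], all_taxa: frozenset, table: QuartetTable) -> int:
    score = 0
    for subset, per_split in table.counts.items():
        resolution = _resolve_subset(subset, splits)
        if resolution is not None:
            score += per_split.get(resolution, 0)
    return score


def _resolve_subset(subset: frozenset, splits: list[frozenset]) -> Split | None:
    for side in splits:
        inside = subset & side
        if len(inside) == 2:
            return _split(inside, subset - inside)
    return None


# ---------------------------------------------------------------------------
# Exact search
# ---------------------------------------------------------------------------


@dataclass
class BranchSupport:
    split: frozenset  # one side of the bipartition
    q: float
    coalescent_length: float
    capped: bool
    n_quartets: int


@dataclass
class SpeciesTreeResult:
    tree: dendropy.Tree
    branches: list[BranchSupport]
    score: int
    n_candidates: int

    def newick(self) -> str:
        return treekit.write_newick(self.tree)


def exact_quartet_species_tree(
    gene_trees,
    taxa: list[str] | None = None,
    max_n: int = 9,
    length_cap: float = 9.0,
) -> SpeciesTreeResult:
    """Exhaustive maximum-quartet-support species tree for small taxon sets.

    Enumerates every unrooted topology over ``taxa`` (all taxa seen in the
    gene trees by default), scores each by the number of gene-tree-induced
    quartets agreeing with it, and returns the maximizer (ties broken by the
    lexicographically smallest split set, for determinism).  Per internal
    branch it reports the quartet support q — the frequency of gene-tree
    quartets agreeing with the branch's resolution, among resolved quartets
    built from one taxon out of each of the four subtrees adjacent to the
    branch (for those, the quartet's induced internal edge is exactly the
    focal branch) — and the coalescent-unit length -ln(3(1-q)/2).  Missing
    taxa per gene tree are allowed; unresolved quartets are skipped.
    """
    gene_trees = list(gene_trees)
    if taxa is None:
        taxa = sorted({l for t in gene_trees for l in tip_labels(t)})
    taxa = sorted(taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if n > max_n:
        raise ValueError(
            f"{n} taxa exceeds exact-search limit max_n={max_n}; "
            "heuristic search is out of scope"
        )
    table = quartet_table(gene_trees)
    all_taxa = frozenset(taxa)

    best = None
    n_candidates = 0
    for topo in enumerate_topologies(taxa):
        n_candidates += 1
        splits = topo.nontrivial_splits()
        score = _score_topology(splits, all_taxa, table)
        key = (-score, tuple(sorted(tuple(sorted(s)) for s in splits)))
        if best is None or key < best[0]:
            best = (key, topo, splits, score)
    _, topo, splits, score = best

    branches = []
    for a, b in topo.internal_edges():
        s1, s2, s3, s4 = topo.adjacent_subtrees(a, b)
        side = s1 | s2
        agree = 0
        resolved = 0
        n_quartets = 0
        # one taxon from each adjacent subtree: the induced internal edge of
        # every such quartet is exactly this branch
        for x1 in sorted(s1):
            for x2 in sorted(s2):
                for y1 in sorted(s3):
                    for y2 in sorted(s4):
                        subset = frozenset((x1, x2, y1, y2))
                        per = table.counts.get(subset)
                        if not per:
                            continue
                        n_quartets += 1
                        resolved += sum(per.values())
                        agree += per.get(_split((x1, x2), (y1, y2)), 0)
        q = agree / resolved if resolved else float("nan")
        if resolved:
            d, capped = coalescent_branch_length(q, cap=length_cap)
        else:
            d, capped = float("nan"), False
        branches.append(BranchSupport(side, q, d, capped, n_quartets))

    tree = topo.to_dendropy()
    _annotate(tree, branches)
    return SpeciesTreeResult(tree, branches, score, n_candidates)


def _annotate(tree: dendropy.Tree, branches: list[BranchSupport]) -> None:
    by_split = {b.split: b for b in branches}
    all_labels = frozenset(tip_labels(tree))
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        b = by_split.get(below[id(node)]) or by_split.get(all_labels - below[id(node)])
        if b is not None:
            node.edge.length = b.coalescent_length
            node.label = f"{b.q:.4f}"


def coalescent_branch_length(q: float, cap: float = 9.0) -> tuple[float, bool]:
    """Convert quartet support into coalescent units: d = -ln(3(1-q)/2).

    Returns (length, capped).  q below the random-resolution floor of 1/3 is
    an error; q = 1 (or a length beyond ``cap``) returns the cap with the
    flag set.
    """
    if not 1.0 / 3.0 - 1e-12 <= q <= 1.0:
        raise ValueError(f"quartet support q={q} outside [1/3, 1]")
    if q >= 1.0:
        return cap, True
    d = -math.log(3.0 * (1.0 - q) / 2.0)
    d = max(d, 0.0)
    if d > cap:
        return cap, True
    return d, False


# ---------------------------------------------------------------------------
# Multispecies-coalescent gene-tree simulation
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("label", "children", "height")

    def __init__(self, label=None, children=(), height=0.0):
        self.label = label
        self.children = list(children)
        self.height = height


def simulate_msc_gene_tree(
    species_tree: dendropy.Tree,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """One gene tree under the multispecies coalescent (one sample/species).

    Species-tree branch lengths are coalescent units; within each interval
    k lineages coalesce at rate k(k-1)/2, and remaining lineages are passed
    to the parent population.  The root population runs until a single
    lineage remains.  Output branch lengths are in coalescent units.
    """
    node_heights: dict[int, float] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            node_heights[id(node)] = 0.0
        else:
            # species divergence times assume an ultrametric species tree
            node_heights[id(node)] = max(
                node_heights[id(c)] + (c.edge.length or 0.0)
                for c in node.child_nodes()
            )

    def coalesce(lineages: list[_Lineage], t0: float, t_max: float) -> list[_Lineage]:
        t = t0
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            wait = rng.exponential(2.0 / (k * (k - 1)))
            if t + wait > t_max:
                break
            t += wait
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            merged = _Lineage(children=(a, b), height=t)
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append(merged)
        return lineages

    surviving: dict[int, list[_Lineage]] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            incoming = [_Lineage(label=node.taxon.label, height=0.0)]
        else:
            incoming = []
            for child in node.child_nodes():
                incoming.extend(surviving[id(child)])
        t0 = node_heights[id(node)]
        if node.parent_node is None:
            surviving[id(node)] = coalesce(incoming, t0, math.inf)
        else:
            t_max = t0 + (node.edge.length or 0.0)
            surviving[id(node)] = coalesce(incoming, t0, t_max)

    root = surviving[id(species_tree.seed_node)][0]

    def to_newick(lin: _Lineage, parent_height: float) -> str:
        length = parent_height - lin.height
        if lin.label is not None:
            return f"{lin.label}:{length:.10g}"
        inner = ",".join(to_newick(c, lin.height) for c in lin.children)
        return f"({inner}):{length:.10g}"

    inner = ",".join(to_newick(c, root.height) for c in root.children)
    return treekit.parse_newick(f"({inner});")
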