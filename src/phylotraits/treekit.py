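"""Newick/alignment plumbing and homolog-tree cleaning operators.

The operators here transform *homolog trees*: gene trees built from clusters
of similar transcripts, whose tips are labeled ``taxon@identifier`` and whose
branch lengths are expected substitutions per site.  Cleaning removes
assembly/contamination artifacts (aberrantly long tips), collapses redundant
isoforms that appear as monophyletic same-taxon tip groups, and splits ancient
(deep) paralog clades into independent homolog trees.  A neighbor-joining
builder on Jukes-Cantor distances stands in for maximum-likelihood inference.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Alignment",
    "CleaningParams",
    "TAXON_SEPARATOR",
    "taxon_of",
    "parse_newick",
    "write_newick",
    "clean_columns",
    "informative_chars",
    "jc_distance",
    "neighbor_joining",
    "trim_long_tips",
    "mask_monophyletic_duplicates",
    "cut_deep_paralogs",
    "edge_leaf_sets",
    "tip_labels",
]

#: Reserved separator between taxon name and sequence identifier in tip labels.
TAXON_SEPARATOR = "@"

#: Maximum Jukes-Cantor distance assigned when the mismatch fraction is at or
#: beyond the model's saturation point (p >= 3/4).
JC_CEILING = 10.0

_UNAMBIGUOUS = frozenset("ACGT")


def taxon_of(label: str) -> str:
    """Taxon part of a ``taxon@identifier`` tip label."""
    return label.split(TAXON_SEPARATOR, 1)[0]


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """In-memory multiple sequence alignment over ``{A, C, G, T, -, N}``.

    Rows map sequence id to an aligned character string; all rows must have
    equal length.  Sequences are stored upper-case.
    """

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        self.rows = {k: v.upper() for k, v in self.rows.items()}
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def subset(self, ids) -> "Alignment":
        return Alignment({i: self.rows[i] for i in ids})

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        return cls({r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.rows.items():
                fh.write(f">{name}\n{seq}\n")


def clean_columns(aln: Alignment, min_occupancy: float = 0.1):
    """Drop alignment columns with occupancy below ``min_occupancy``.

    Occupancy of a column is the fraction of rows holding an unambiguous or
    gap-free character (anything other than ``-`` or ``N``).  Columns with
    occupancy >= the threshold are kept (closed boundary).  Returns the
    cleaned alignment (or ``None`` when every column is removed) together with
    a report dict.
    """
    if not 0.0 < min_occupancy <= 1.0:
        raise ValueError("min_occupancy must be in (0, 1]")
    ids = aln.ids
    mat = np.array([list(aln.rows[i]) for i in ids])
    occupied = ~np.isin(mat, ["-", "N"])
    occupancy = occupied.mean(axis=0)
    keep = occupancy >= min_occupancy
    report = {
        "n_columns_in": aln.n_columns,
        "n_columns_kept": int(keep.sum()),
        "empty": not bool(keep.any()),
    }
    if report["empty"]:
        return None, report
    kept = mat[:, keep]
    return Alignment({i: "".join(row) for i, row in zip(ids, kept)}), report


def informative_chars(aln: Alignment, seq_id: str) -> int:
    """Number of unambiguous characters (A/C/G/T) in one alignment row."""
    if seq_id not in aln.rows:
        raise KeyError(f"unknown sequence id: {seq_id!r}")
    return sum(c in _UNAMBIGUOUS for c in aln.rows[seq_id])


def jc_distance(aln: Alignment, ceiling: float = JC_CEILING) -> pd.DataFrame:
    """Pairwise Jukes-Cantor distances, d = -3/4 ln(1 - 4p/3).

    The mismatch fraction p is computed over sites where both rows carry an
    unambiguous base.  Saturated pairs (p >= 3/4) get ``ceiling``.  A pair
    sharing zero comparable sites is an error.
    """
    ids = aln.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 rows for distances")
    mat = np.array([list(aln.rows[i]) for i in ids])
    ok = np.isin(mat, list(_UNAMBIGUOUS))
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared unambiguous sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((mat[i, shared] != mat[j, shared]).mean())
            if p >= 0.75:
                d = ceiling
            else:
                d = -0.75 * math.log1p(-4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a tree; raises on malformed input.

    Internal node labels are ignored; ``@`` is legal in unquoted labels.
    """
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_newick_list(path) -> list[dendropy.Tree]:
    """Read a multi-tree newick file (one tree per line/statement)."""
    trees = dendropy.TreeList.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return list(trees)


def write_newick(tree: dendropy.Tree) -> str:
    buf = io.StringIO()
    tree.write(
        file=buf,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=True,
        real_value_format_specifier=".12g",
    )
    return buf.getvalue().strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Classic neighbor joining on a symmetric distance matrix.

    Deterministic: the joined pair has the smallest Q value, ties broken by
    the lexicographically smallest (sorted) label pair, where a merged node
    is represented by the smallest tip label in its subtree.  Negative branch
    length estimates are clamped to zero.
    """
    labels = list(dist.index)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dist.to_numpy(dtype=float).copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    reps = list(labels)  # lexicographic representative per active node
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        total = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - total[ai] - total[aj]
                pair = tuple(sorted((reps[active[ai]], reps[active[aj]])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (total[ai] - total[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        # distances from the new node to every other active node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0).reshape(-1, 1)])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes at an unrooted central node
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    root = dendropy.Node()
    for node, length in (
        (nodes[i], 0.5 * (dij + dik - djk)),
        (nodes[j], 0.5 * (dij + djk - dik)),
        (nodes[k], 0.5 * (dik + djk - dij)),
    ):
        root.add_child(node)
        node.edge.length = max(length, 0.0)

    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Cleaning operators
# ---------------------------------------------------------------------------


@dataclass
class CleaningParams:
    """Thresholds for homolog-tree cleaning.

    abs_cutoff / rel_cutoff are pendant-branch thresholds in subs/site;
    deep_cutoff is the internal-branch threshold marking deep paralogs;
    min_subclade_taxa is the minimum distinct-taxon count for a fragment to
    survive a deep split; min_occupancy is the column-cleaning threshold;
    rel_factor is how many times longer than its sister a pendant branch must
    be for the relative rule to fire.
    """

    abs_cutoff: float = 0.4
    rel_cutoff: float = 0.6
    deep_cutoff: float = 1.0
    min_subclade_taxa: int = 4
    min_occupancy: float = 0.1
    rel_factor: float = 10.0

    def __post_init__(self) -> None:
        for name in ("abs_cutoff", "rel_cutoff", "deep_cutoff", "rel_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_subclade_taxa < 1:
            raise ValueError("min_subclade_taxa must be >= 1")
        if not 0.0 < self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must be in (0, 1]")


@dataclass
class TrimReport:
    removed: list[tuple[str, str]] = field(default_factory=list)  # (tip, rule)
    degenerate: bool = False


def _pendant(leaf: dendropy.Node) -> float:
    return leaf.edge.length or 0.0


def _sister_min_pendant(leaf: dendropy.Node) -> float | None:
    """Shortest pendant length among leaves of the sibling clade(s)."""
    parent = leaf.parent_node
    if parent is None:
        return None
    pendants = [
        _pendant(other_leaf)
        for sib in parent.child_nodes()
        if sib is not leaf
        for other_leaf in sib.leaf_iter()
    ]
    return min(pendants) if pendants else None


def trim_long_tips(tree: dendropy.Tree, params: CleaningParams | None = None):
    """Remove tips on aberrantly long pendant branches.

    The absolute rule removes any tip whose pendant branch exceeds
    ``abs_cutoff`` subs/site.  The relative rule removes a tip whose pendant
    branch exceeds ``rel_cutoff`` AND is more than ``rel_factor`` times the
    shortest pendant branch in its sister clade.  Both rules are evaluated on
    the input tree, then all flagged tips are pruned at once with unary nodes
    collapsed (edge lengths summed).
    """
    params = params or CleaningParams()
    work = _clone(tree)
    report = TrimReport()
    for leaf in work.leaf_node_iter():
        length = _pendant(leaf)
        if length > params.abs_cutoff:
            report.removed.append((leaf.taxon.label, "absolute"))
            continue
        if length > params.rel_cutoff:
            sister = _sister_min_pendant(leaf)
            if sister is not None and length > params.rel_factor * sister:
                report.removed.append((leaf.taxon.label, "relative"))
    doomed = {label for label, _ in report.removed}
    survivors = [label for label in tip_labels(work) if label not in doomed]
    if len(survivors) < 2:
        report.degenerate = True
        if not survivors:
            return None, report
    if doomed:
        work.prune_taxa_with_labels(sorted(doomed), suppress_unifurcations=True)
    return work, report


def mask_monophyletic_duplicates(
    tree: dendropy.Tree, aln: Alignment
) -> dendropy.Tree:
    """Collapse monophyletic same-taxon tip groups to their best transcript.

    Every maximal clade whose tips all belong to one taxon is reduced to the
    single tip with the most unambiguous alignment characters (ties broken by
    lexicographically smallest label).  Applied repeatedly until no such
    group remains, so nested same-taxon clades collapse fully.
    """
    work = _clone(tree)
    for label in tip_labels(work):
        if label not in aln.rows:
            raise KeyError(f"alignment missing row for tip {label!r}")
    while True:
        doomed: set[str] = set()
        for node in work.preorder_node_iter():
            if node.is_leaf():
                continue
            leaves = [l.taxon.label for l in node.leaf_iter()]
            taxa = {taxon_of(l) for l in leaves}
            if len(taxa) != 1:
                continue
            parent = node.parent_node
            if parent is not None:
                parent_taxa = {taxon_of(l.taxon.label) for l in parent.leaf_iter()}
                if len(parent_taxa) == 1:
                    continue  # not maximal
            keeper = min(leaves, key=lambda l: (-informative_chars(aln, l), l))
            doomed.update(l for l in leaves if l != keeper)
        if not doomed:
            return work
        work.prune_taxa_with_labels(sorted(doomed), suppress_unifurcations=True)


@dataclass
class DeepCutReport:
    n_cut_edges: int = 0
    discarded: list[list[str]] = field(default_factory=list)


def cut_deep_paralogs(tree: dendropy.Tree, params: CleaningParams | None = None):
    """Split a homolog tree at deep internal branches.

    Every internal edge of length >= ``deep_cutoff`` subs/site is cut;
    fragments with at least ``min_subclade_taxa`` distinct taxa are emitted as
    independent homolog trees, smaller fragments are reported as discarded.
    """
    params = params or CleaningParams()
    report = DeepCutReport()
    fragments: list[dendropy.Tree] = []

    def split(t: dendropy.Tree) -> None:
        for node in t.preorder_node_iter():
            edge = node.edge
            if (
                node.is_leaf()
                or edge.tail_node is None
                or edge.length is None
                or edge.length < params.deep_cutoff
            ):
                continue
            report.n_cut_edges += 1
            parent = edge.tail_node
            parent.remove_child(node)
            sub = dendropy.Tree(
                taxon_namespace=t.taxon_namespace, seed_node=node
            )
            node.edge.length = None
            t.suppress_unifurcations()
            split(sub)
            split(t)
            return
        fragments.append(t)

    split(_clone(tree))

    kept = []
    for frag in fragments:
        labels = tip_labels(frag)
        if len({taxon_of(l) for l in labels}) >= params.min_subclade_taxa:
            kept.append(frag)
        else:
            report.discarded.append(sorted(labels))
    return kept, report


# ---------------------------------------------------------------------------
# Shared tree utilities
# ---------------------------------------------------------------------------


def edge_leaf_sets(tree: dendropy.Tree) -> list[tuple[frozenset, float]]:
    """Per edge: the set of tip labels below it and the edge length.

    Covers every edge with a tail node (i.e. all but the root edge); the
    complement side of each edge is the remaining tips.
    """
    below: dict[int, frozenset] = {}
    out = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
        if node.edge.tail_node is not None:
            out.append((below[id(node)], node.edge.length or 0.0))
    return out
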