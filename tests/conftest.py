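"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from phylotraits import treekit
from phylotraits.treekit import taxon_of


def random_homolog_newick(
    rng: np.random.Generator,
    n_tips: int = 12,
    taxa: list[str] = ("A", "B", "C", "D", "E", "F"),
    max_len: float = 0.3,
) -> str:
    """Random homolog-tree newick: random joins, random taxon per tip."""
    counters: dict[str, int] = {}
    parts = []
    for _ in range(n_tips):
        taxon = taxa[rng.integers(0, len(taxa))]
        idx = counters.get(taxon, 0)
        counters[taxon] = idx + 1
        parts.append(f"{taxon}@{idx}")
    groups = [f"{p}:{rng.uniform(0.01, max_len):.6f}" for p in parts]
    while len(groups) > 2:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        a = groups.pop(j)
        b = groups.pop(i)
        groups.append(f"({a},{b}):{rng.uniform(0.01, max_len):.6f}")
    return f"({groups[0]},{groups[1]});"


def random_labeled_newick(
    rng: np.random.Generator, labels, max_len: float = 0.3
) -> str:
    """Random binary tree newick over exactly the given labels (each once)."""
    groups = [f"{lab}:{rng.uniform(0.01, max_len):.6f}" for lab in labels]
    while len(groups) > 2:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        a = groups.pop(j)
        b = groups.pop(i)
        groups.append(f"({a},{b}):{rng.uniform(0.01, max_len):.6f}")
    return f"({groups[0]},{groups[1]});"


def tree_to_graph(tree) -> tuple[nx.Graph, dict[int, str]]:
    """Undirected weighted graph view of a dendropy tree (independent of the
    package's own edge utilities)."""
    graph = nx.Graph()
    leaves: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        graph.add_node(id(node))
        if node.is_leaf():
            leaves[id(node)] = node.taxon.label
        if node.parent_node is not None:
            graph.add_edge(id(node), id(node.parent_node), weight=node.edge.length or 0.0)
    return graph, leaves


def unrooted_splits(tree) -> set[frozenset]:
    """Canonical nontrivial splits of a tree (smaller-sorted side kept)."""
    labels = frozenset(treekit.tip_labels(tree))
    out = set()
    for side, _ in treekit.edge_leaf_sets(tree):
        if 2 <= len(side) <= len(labels) - 2:
            out.add(min(side, labels - side, key=lambda s: (len(s), sorted(s))))
    return out


def quartet_by_path_distance(tree, quartet) -> frozenset | None:
    """Path-distance quartet oracle: the pairing minimizing the sum of
    topological (edge-count) distances is the induced resolution; ties mean
    the quartet is unresolved."""
    graph, leaves = tree_to_graph(tree)
    by_label = {lab: nid for nid, lab in leaves.items()}
    a, b, c, d = sorted(quartet)
    dist = {}
    for x, y in itertools.combinations((a, b, c, d), 2):
        dist[(x, y)] = nx.shortest_path_length(graph, by_label[x], by_label[y])
    sums = {
        frozenset({frozenset({a, b}), frozenset({c, d})}): dist[(a, b)] + dist[(c, d)],
        frozenset({frozenset({a, c}), frozenset({b, d})}): dist[(a, c)] + dist[(b, d)],
        frozenset({frozenset({a, d}), frozenset({b, c})}): dist[(a, d)] + dist[(b, c)],
    }
    best = min(sums.values())
    winners = [k for k, v in sums.items() if v == best]
    return winners[0] if len(winners) == 1 else None


def brute_force_max_inclusion(tree, min_taxa: int) -> list[frozenset]:
    """Independent Maximum-Inclusion oracle.

    Enumerates every edge-defined subtree via graph component splitting,
    keeps duplication-free ones, and greedily extracts the best by the
    (distinct taxa, tips, branch sum, label set) preference until none with
    >= min_taxa distinct taxa remains.  Works on label sets only.
    """
    graph, leaves = tree_to_graph(tree)
    active = set(leaves.values())
    by_label = {lab: nid for nid, lab in leaves.items()}

    def steiner_sum(labels) -> float:
        """Total edge weight of the Steiner tree spanning these leaves —
        the branch-length sum of the induced subtree (unary paths kept)."""
        if len(labels) < 2:
            return 0.0
        edges = set()
        labs = sorted(labels)
        for x, y in itertools.combinations(labs, 2):
            path = nx.shortest_path(graph, by_label[x], by_label[y])
            edges.update(frozenset(p) for p in zip(path, path[1:]))
        return sum(graph.edges[tuple(e)]["weight"] for e in edges)

    def candidates(current: set[str]):
        # enumerate every edge-defined bipartition of the induced tree on
        # `current` (split the Steiner subgraph at each of its edges), keep
        # duplication-free sides with their own-subtree branch sums
        keep_nodes = set()
        labs = sorted(current)
        for x, y in itertools.combinations(labs, 2):
            keep_nodes.update(nx.shortest_path(graph, by_label[x], by_label[y]))
        if not keep_nodes:
            keep_nodes = {by_label[labs[0]]}
        sub = graph.subgraph(keep_nodes).copy()
        sides = {frozenset(current)}
        for u, v in list(sub.edges()):
            sub2 = sub.copy()
            sub2.remove_edge(u, v)
            comp = nx.node_connected_component(sub2, u)
            labels_a = frozenset(
                leaves[n] for n in comp if n in leaves and leaves[n] in current
            )
            sides.add(labels_a)
            sides.add(frozenset(current) - labels_a)
        out = []
        for labels in sides:
            if not labels:
                continue
            taxa = [taxon_of(l) for l in labels]
            if len(set(taxa)) == len(taxa):
                out.append((labels, steiner_sum(labels)))
        return out

    extracted = []
    while active:
        taxa_left = {taxon_of(l) for l in active}
        if len(taxa_left) < min_taxa:
            break
        cands = candidates(active)
        if not cands:
            break
        best = min(
            cands,
            key=lambda c: (
                -len({taxon_of(l) for l in c[0]}),
                -len(c[0]),
                round(c[1], 9),
                tuple(sorted(c[0])),
            ),
        )
        if len({taxon_of(l) for l in best[0]}) < min_taxa:
            break
        extracted.append(best[0])
        active -= best[0]
        if len(active) < 2:
            break
    return extracted


def mcl_oracle(graph: nx.Graph, inflation: float) -> set[frozenset]:
    """Direct re-implementation of the MCL expansion/inflation iteration,
    run to a fixed point, with a connected-component cluster readout."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, d in graph.edges(data=True):
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = d.get("weight", 1.0)
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    for i in range(n):
        m[i, i] = loops[i]
    m = m / m.sum(axis=0)
    for _ in range(500):
        prev = m
        m = m @ m
        m = m ** inflation
        m[m < 1e-12] = 0.0
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < 1e-10:
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if m[i, j] > 1e-6:
                support.add_edge(i, j)
    return {
        frozenset(nodes[i] for i in comp)
        for comp in nx.connected_components(support)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20250918)
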