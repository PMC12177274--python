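"""Transcript redundancy reduction and homolog clustering.

Mirrors the front end of a transcriptome-phylogenomics pipeline: collapse
near-identical isoforms with a greedy 0.99-identity dedup, build an
all-by-all similarity graph, and partition it into putative homolog clusters
with Markov clustering (MCL, inflation 1.4).

The similarity scorer counts distinct shared k-mers (default k = 21) rather
than running an external aligner: it is dependency-free, monotone in
sequence similarity, and adequate for graph clustering.  Strand handling is
single-strand by default (reverse complements are not compared), with an
option to also index the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np

__all__ = [
    "SeqRecord",
    "read_fasta",
    "write_fasta",
    "dedup_greedy",
    "containment_identity",
    "build_similarity_graph",
    "mcl",
    "ClusterSet",
]


class SeqRecord(NamedTuple):
    id: str
    seq: str


def read_fasta(path) -> list[SeqRecord]:
    from Bio import SeqIO

    records = [SeqRecord(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in FASTA input")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# Greedy redundancy reduction
# ---------------------------------------------------------------------------


def containment_identity(short: str, long: str) -> float:
    """Best gapless identity of the shorter sequence inside the longer.

    Slides the shorter sequence over every offset of the longer and returns
    max(matches) / len(shorter).  Quadratic, intended for modest inputs.
    """
    if len(short) > len(long):
        short, long = long, short
    if not short:
        return 0.0
    s = np.frombuffer(short.encode(), dtype=np.uint8)
    l = np.frombuffer(long.encode(), dtype=np.uint8)
    best = 0
    for off in range(len(l) - len(s) + 1):
        matches = int((s == l[off : off + len(s)]).sum())
        if matches > best:
            best = matches
            if best == len(s):
                break
    return best / len(s)


def dedup_greedy(
    records: list[SeqRecord], identity_threshold: float = 0.99
) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Greedy length-sorted redundancy reduction (cd-hit style).

    Records are visited by decreasing length (ties by id); each joins the
    first existing representative with containment identity >= the
    threshold, otherwise it becomes a new representative.  Returns the
    representatives (in visit order) and a map representative id -> member
    ids (each representative is its own first member).  Idempotent.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    reps: list[SeqRecord] = []
    membership: dict[str, list[str]] = {}
    for rec in sorted(records, key=lambda r: (-len(r.seq), r.id)):
        for rep in reps:
            if containment_identity(rec.seq, rep.seq) >= identity_threshold:
                membership[rep.id].append(rec.id)
                break
        else:
            reps.append(rec)
            membership[rec.id] = [rec.id]
    return reps, membership


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def _kmers(seq: str, k: int, both_strands: bool) -> set[str]:
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    if both_strands:
        rc = seq.translate(_RC)[::-1]
        kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return kmers


def build_similarity_graph(
    records: list[SeqRecord],
    k: int = 21,
    min_score: float = 1.0,
    both_strands: bool = False,
) -> nx.Graph:
    """All-by-all similarity graph scored by distinct shared k-mers.

    Nodes are all record ids (including singletons); an undirected edge
    (i, j) with weight = |kmers_i & kmers_j| is kept iff the weight is at
    least ``min_score``.  No self-loops.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    shortest = min((len(r.seq) for r in records), default=k)
    if records and k > shortest:
        raise ValueError(f"k={k} longer than shortest sequence ({shortest})")
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in records)
    sets = {r.id: _kmers(r.seq, k, both_strands) for r in records}
    ids = [r.id for r in records]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            score = len(sets[ids[i]] & sets[ids[j]])
            if score >= min_score:
                graph.add_edge(ids[i], ids[j], weight=float(score))
    return graph


def graph_to_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:g}\n")


def graph_from_tsv(path) -> nx.Graph:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for _, row in df.iterrows():
        graph.add_edge(str(row["id_a"]), str(row["id_b"]), weight=float(row["score"]))
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterSet:
    """A partition of graph nodes into clusters."""

    clusters: list[frozenset[str]]
    converged: bool = True
    n_iterations: int = 0

    def as_map(self) -> dict[str, int]:
        return {node: i for i, members in enumerate(self.clusters) for node in members}

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.clusters)


def mcl(
    graph: nx.Graph,
    inflation: float = 1.4,
    tol: float = 1e-6,
    max_iter: int = 200,
    prune: float = 1e-9,
) -> ClusterSet:
    """Markov clustering of a weighted similarity graph.

    Builds a column-stochastic transition matrix from edge weights with
    self-loops of weight equal to each node's maximum incident edge weight
    (1 for isolated nodes), then alternates expansion (matrix squaring) and
    inflation (elementwise power + column renormalization), pruning entries
    below ``prune``, until the largest column change drops below ``tol``.
    Clusters are read off from attractors (nodes with mass on their own
    diagonal): each attractor's cluster is its row support, overlapping
    attractor rows are merged, and any remaining node joins the cluster of
    its largest-probability attractor (ties by lexicographic node id).
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("graph is empty")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("edge weights must be >= 0")
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        change = np.abs(inflated - m).max()
        m = inflated
        if change < tol:
            converged = True
            break

    clusters = _read_clusters(m, nodes)
    return ClusterSet(clusters=clusters, converged=converged, n_iterations=iteration)


def _read_clusters(m: np.ndarray, nodes: list[str]) -> list[frozenset[str]]:
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 1e-7]
    if not attractors:  # fall back: every node its own cluster
        return [frozenset([node]) for node in nodes]
    support = {i: set(np.nonzero(m[i] > 1e-7)[0]) | {i} for i in attractors}
    # merge attractors with overlapping support into cluster seeds
    merged: list[set[int]] = []
    for i in attractors:
        placed = None
        for group in merged:
            if any(support[i] & support[j] for j in group):
                placed = group
                break
        if placed is None:
            merged.append({i})
        else:
            placed.add(i)
    # repeat merging until stable (chains of overlap)
    changed = True
    while changed:
        changed = False
        for a in range(len(merged)):
            for b in range(a + 1, len(merged)):
                sup_a = set().union(*(support[i] for i in merged[a]))
                sup_b = set().union(*(support[i] for i in merged[b]))
                if sup_a & sup_b:
                    merged[a] |= merged[b]
                    del merged[b]
                    changed = True
                    break
            if changed:
                break

    cluster_of_attractor = {}
    for ci, group in enumerate(merged):
        for i in group:
            cluster_of_attractor[i] = ci
    members: dict[int, set[str]] = {ci: set() for ci in range(len(merged))}
    for j in range(n):
        # assign to the cluster of the attractor holding the largest mass on j
        best = min(
            attractors,
            key=lambda i: (-(m[i, j] + (1e-12 if i == j else 0.0)), nodes[i]),
        )
        if m[best, j] <= 0 and j not in cluster_of_attractor:
            members.setdefault(len(merged) + j, set()).add(nodes[j])
            continue
        if j in cluster_of_attractor:
            members[cluster_of_attractor[j]].add(nodes[j])
        else:
            members[cluster_of_attractor[best]].add(nodes[j])
    return sorted(
        (frozenset(s) for s in members.values() if s), key=lambda s: sorted(s)
    )


def clusters_to_tsv(clusters: ClusterSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tseq_id\n")
        for ci, members in enumerate(clusters.clusters):
            for node in sorted(members):
                fh.write(f"{ci}\t{node}\n")
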