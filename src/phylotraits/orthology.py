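"""Maximum-Inclusion extraction of single-copy ortholog trees.

A cleaned homolog tree may still contain paralogs (two or more tips from the
same taxon).  Maximum Inclusion (MI) repeatedly carves out the largest
subtree that is *duplication-free* — at most one tip per taxon — emits it as
an ortholog, deletes its tips from the working tree, and repeats until no
subtree with at least ``min_taxa`` distinct taxa remains.  Every edge of an
unrooted tree defines two candidate rooted subtrees (the tips below it and
the complement); both directions are examined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from . import treekit
from .treekit import CleaningParams, taxon_of, tip_labels

__all__ = ["OrthologSet", "maximum_inclusion", "best_duplication_free_subtree"]


@dataclass
class OrthologSet:
    """Disjoint single-copy subtrees extracted from one homolog tree."""

    orthologs: list[dendropy.Tree]
    source: str = ""
    discarded_tips: list[str] = field(default_factory=list)
    trim_report: treekit.TrimReport | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tree in self.orthologs:
            labels = tip_labels(tree)
            taxa = [taxon_of(l) for l in labels]
            if len(set(taxa)) != len(taxa):
                raise ValueError("ortholog contains two tips of one taxon")
            if seen & set(labels):
                raise ValueError("orthologs share a tip")
            seen |= set(labels)

    @property
    def tip_sets(self) -> list[frozenset[str]]:
        return [frozenset(tip_labels(t)) for t in self.orthologs]


def _duplication_free(labels: frozenset[str]) -> bool:
    taxa = [taxon_of(l) for l in labels]
    return len(set(taxa)) == len(taxa)


def _candidate_key(labels: frozenset[str], branch_sum: float):
    """Sort key for MI candidates: more distinct taxa, then more tips, then
    smaller subtree branch-length sum, then lexicographically smallest tip
    set.  Built so that ``min()`` selects the preferred candidate.  The
    branch sum is rounded so that sums differing only by float accumulation
    noise (e.g. after unary-collapse summation) fall through to the
    deterministic lexicographic tie-break."""
    return (
        -len({taxon_of(l) for l in labels}),
        -len(labels),
        round(branch_sum, 9),
        tuple(sorted(labels)),
    )


def best_duplication_free_subtree(tree: dendropy.Tree) -> frozenset[str] | None:
    """Tip set of the best duplication-free edge-defined subtree, or None."""
    below: dict[int, frozenset] = {}
    below_sum: dict[int, float] = {}
    edges: list[tuple[frozenset, float, float]] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            below_sum[id(node)] = 0.0
        else:
            kids = node.child_nodes()
            below[id(node)] = frozenset().union(*(below[id(c)] for c in kids))
            below_sum[id(node)] = sum(
                below_sum[id(c)] + (c.edge.length or 0.0) for c in kids
            )
        if node.edge.tail_node is not None:
            edges.append(
                (below[id(node)], node.edge.length or 0.0, below_sum[id(node)])
            )
    root = tree.seed_node
    all_labels = below[id(root)]
    total_length = below_sum[id(root)]

    # The same unrooted side can surface through several rooted edges (the
    # stored root splits one unrooted edge in two); keep the smallest branch
    # sum, which corresponds to the subtree's own edges only.
    best_sum: dict[frozenset, float] = {}
    if _duplication_free(all_labels):
        best_sum[all_labels] = total_length
    for labels, length, bsum in edges:
        comp = all_labels - labels
        comp_sum = total_length - bsum - length
        for side, side_sum in ((labels, bsum), (comp, comp_sum)):
            if side and _duplication_free(side):
                if side not in best_sum or side_sum < best_sum[side]:
                    best_sum[side] = side_sum
    if not best_sum:
        return None
    candidates = [(_candidate_key(side, s), side) for side, s in best_sum.items()]
    return min(candidates)[1]


def maximum_inclusion(
    tree: dendropy.Tree,
    params: CleaningParams | None = None,
    min_taxa: int = 4,
    source: str = "",
    trim: bool = True,
    trim_each_iteration: bool = False,
) -> OrthologSet:
    """Extract single-copy ortholog trees by Maximum Inclusion.

    Long tips are trimmed once up front (absolute 0.4 / relative 0.6
    subs/site by default); set ``trim_each_iteration`` to re-apply trimming
    after each extraction.  Each emitted ortholog has at least ``min_taxa``
    distinct taxa; remaining tips are reported as discarded.
    """
    params = params or CleaningParams()
    work = tree.clone(depth=1)
    trim_report = None
    if trim:
        work, trim_report = treekit.trim_long_tips(work, params)
    orthologs: list[dendropy.Tree] = []
    extra_discarded: list[str] = []
    if work is None:
        return OrthologSet([], source=source, trim_report=trim_report)

    while True:
        labels = tip_labels(work)
        if len({taxon_of(l) for l in labels}) < min_taxa:
            break
        best = best_duplication_free_subtree(work)
        if best is None or len({taxon_of(l) for l in best}) < min_taxa:
            break
        if len(best) == len(labels):
            orthologs.append(work)
            work = None
            break
        ortho = work.extract_tree_with_taxa_labels(labels=sorted(best))
        orthologs.append(ortho)
        remaining = sorted(set(labels) - best)
        if len(remaining) < 2:
            work = None
            extra_discarded = remaining
            break
        work = work.extract_tree_with_taxa_labels(labels=remaining)
        if trim_each_iteration:
            work, _ = treekit.trim_long_tips(work, params)
            if work is None:
                break

    discarded = sorted(tip_labels(work)) if work is not None else []
    discarded = sorted(set(discarded) | set(extra_discarded))
    return OrthologSet(
        orthologs, source=source, discarded_tips=discarded, trim_report=trim_report
    )


def write_manifest(ortholog_sets: list[OrthologSet], path) -> None:
    """TSV manifest: ortholog_id, n_taxa, tips, source."""
    with open(path, "w") as fh:
        fh.write("ortholog_id\tn_taxa\ttips\tsource\n")
        i = 0
        for oset in ortholog_sets:
            for tree in oset.orthologs:
                labels = sorted(tip_labels(tree))
                taxa = {taxon_of(l) for l in labels}
                fh.write(f"ortho{i:05d}\t{len(taxa)}\t{','.join(labels)}\t{oset.source}\n")
                i += 1
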