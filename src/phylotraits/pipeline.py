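"""End-to-end phylogenomic chain on synthetic transcriptomes.

Wires the stages together in the order a transcriptome phylogenomics study
runs them: per-taxon transcript sets -> greedy redundancy reduction ->
all-by-all similarity graph -> Markov clustering -> per-cluster distance
trees -> tree cleaning (long tips, monophyletic same-taxon masking, deep
paralog cutting) -> Maximum-Inclusion orthologs -> maximum-quartet-support
species tree in coalescent units.

Real studies insert an aligner and ML tree inference here; synthetic
alignments are emitted pre-aligned and neighbor joining on Jukes-Cantor
distances stands in for ML, so the chain is fully runnable at desk scale
with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from . import homology, orthology, speciestree, synthgen, treekit
from .homology import SeqRecord
from .treekit import Alignment, CleaningParams

__all__ = ["PipelineResult", "run_synthetic_pipeline", "relabel_to_taxa"]


def relabel_to_taxa(tree: dendropy.Tree) -> dendropy.Tree:
    """Collapse ``taxon@identifier`` tip labels down to the taxon name.

    Used when single-copy ortholog trees feed species-tree estimation.
    """
    text = treekit.write_newick(tree)
    out = treekit.parse_newick(text)
    for leaf in out.leaf_node_iter():
        leaf.taxon.label = treekit.taxon_of(leaf.taxon.label)
    return out


@dataclass
class PipelineResult:
    clusters: homology.ClusterSet
    homolog_trees: list[dendropy.Tree]
    ortholog_sets: list[orthology.OrthologSet]
    species_tree: speciestree.SpeciesTreeResult | None
    skipped_clusters: list[frozenset] = field(default_factory=list)

    @property
    def ortholog_trees(self) -> list[dendropy.Tree]:
        return [t for oset in self.ortholog_sets for t in oset.orthologs]


def run_synthetic_pipeline(
    species_tree: synthgen.SimSpeciesTree,
    cfg: synthgen.GeneFamilyConfig,
    isoform_rate: float = 0.0,
    k: int = 10,
    min_score: float = 3.0,
    inflation: float = 1.4,
    params: CleaningParams | None = None,
    min_taxa: int = 4,
    max_n: int = 9,
    estimate_species_tree: bool = True,
) -> PipelineResult:
    """Generate families and run the whole chain on them.

    Returns the Markov clusters, the cleaned homolog trees, the
    Maximum-Inclusion ortholog sets, and (when at least one ortholog tree
    spans four taxa) the exact quartet species tree over the taxa present.
    Clusters with fewer than four sequences, or mixing alignments of
    unequal length, are skipped and reported.
    """
    params = params or CleaningParams()
    families = synthgen.simulate_gene_families(species_tree, cfg)
    fam_data: list[tuple[synthgen.GeneFamily, Alignment]] = []
    for fam in families:
        if fam.degenerate or fam.tree is None:
            continue
        aln = synthgen.simulate_sequences(
            fam.tree, cfg.seq_length, seed=cfg.seed + 7919 * (fam.family_id + 1)
        )
        fam_data.append((fam, aln))

    taxa = species_tree.taxa
    pooled: list[SeqRecord] = []
    for ti, taxon in enumerate(taxa):
        try:
            recs = synthgen.make_transcript_set(
                taxon,
                [(fam.tree, aln) for fam, aln in fam_data],
                isoform_rate=isoform_rate,
                seed=cfg.seed + 104729 * (ti + 1),
            )
        except ValueError:
            continue
        deduped, _ = homology.dedup_greedy([SeqRecord(*r) for r in recs])
        pooled.extend(deduped)

    graph = homology.build_similarity_graph(pooled, k=k, min_score=min_score)
    # log-compress shared-k-mer counts before clustering: raw counts span
    # orders of magnitude between close and distant relatives, and Markov
    # clustering on such skewed weights severs the weak (deep) edges of a
    # family; log scores play the role of an aligner's bit score
    import math as _math

    for _, _, data in graph.edges(data=True):
        data["weight"] = _math.log2(1.0 + data["weight"])
    clusters = homology.mcl(graph, inflation=inflation)

    row_of = {}
    for fam, aln in fam_data:
        for label, row in aln.rows.items():
            row_of[label] = row

    homolog_trees: list[dendropy.Tree] = []
    ortholog_sets: list[orthology.OrthologSet] = []
    skipped: list[frozenset] = []
    for ci, members in enumerate(clusters.clusters):
        rows = {}
        ok = True
        for rec_id in sorted(members):
            base = rec_id.rsplit(".", 1)[0]
            if base not in row_of:
                ok = False
                break
            rows[rec_id] = row_of[base]
        if not ok or len(rows) < 4 or len({len(r) for r in rows.values()}) != 1:
            skipped.append(members)
            continue
        aln = Alignment(rows)
        cleaned, report = treekit.clean_columns(aln, params.min_occupancy)
        if cleaned is None:
            skipped.append(members)
            continue
        dist = treekit.jc_distance(cleaned)
        tree = treekit.neighbor_joining(dist)
        tree, _ = treekit.trim_long_tips(tree, params)
        if tree is None or len(treekit.tip_labels(tree)) < 2:
            skipped.append(members)
            continue
        tree = treekit.mask_monophyletic_duplicates(tree, cleaned)
        fragments, _ = treekit.cut_deep_paralogs(tree, params)
        for frag in fragments:
            homolog_trees.append(frag)
            ortholog_sets.append(
                orthology.maximum_inclusion(
                    frag, params, min_taxa=min_taxa, source=f"cluster{ci}", trim=False
                )
            )

    gene_trees = [
        relabel_to_taxa(t)
        for oset in ortholog_sets
        for t in oset.orthologs
        if len(treekit.tip_labels(t)) >= 4
    ]
    sp_result = None
    if estimate_species_tree and gene_trees:
        sp_result = speciestree.exact_quartet_species_tree(
            gene_trees, taxa=taxa, max_n=max_n
        )
    return PipelineResult(
        clusters=clusters,
        homolog_trees=homolog_trees,
        ortholog_sets=ortholog_sets,
        species_tree=sp_result,
        skipped_clusters=skipped,
    )
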