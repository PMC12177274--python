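"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: gene families
evolving along a species tree by a birth-death duplication/loss process,
Jukes-Cantor sequence alignments, per-taxon transcript sets with redundant
isoforms, F2 segregation cohorts, efficiency-aware qPCR Cq tables,
two-region RNA-seq count matrices with planted region-biased genes, and
Bernoulli pollinator-choice trials.  All generators are deterministic under a
fixed seed.

The generative models are deliberately simple so that each generator is
itself testable against closed forms: gene duplication and loss are Poisson
along branches, substitutions are Jukes-Cantor (expected pairwise difference
fraction 3/4(1-e^{-4d/3})), genotypes are Mendelian 1:2:1 draws, and choice
trials are i.i.d. Bernoulli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import treekit
from .treekit import TAXON_SEPARATOR, Alignment

__all__ = [
    "SimSpeciesTree",
    "GeneFamilyConfig",
    "GeneFamily",
    "F2SimConfig",
    "QPCRSimConfig",
    "default_species_tree",
    "simulate_gene_family",
    "simulate_gene_families",
    "simulate_sequences",
    "make_transcript_set",
    "parse_transcript_id",
    "simulate_f2",
    "simulate_cq",
    "simulate_choices",
    "simulate_counts",
]


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass
class SimSpeciesTree:
    """A known species tree: rooted binary topology with branch lengths in
    coalescent units, plus a multiplier converting those units to expected
    substitutions per site for sequence-level simulation."""

    tree: dendropy.Tree
    subs_scale: float = 0.05

    def __post_init__(self) -> None:
        labels = treekit.tip_labels(self.tree)
        if len(labels) == 0:
            raise ValueError("species tree has no tips")
        if len(set(labels)) != len(labels):
            raise ValueError("species tree tip labels must be unique")
        for node in self.tree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError("species tree branch lengths must be >= 0")
        if self.subs_scale <= 0:
            raise ValueError("subs_scale must be positive")

    @classmethod
    def from_newick(cls, text: str, subs_scale: float = 0.05) -> "SimSpeciesTree":
        return cls(tree=treekit.parse_newick(text), subs_scale=subs_scale)

    @property
    def taxa(self) -> list[str]:
        return sorted(treekit.tip_labels(self.tree))


def default_species_tree(subs_scale: float = 0.05) -> SimSpeciesTree:
    """Six-taxon reference species tree.

    Shaped like a small clade with two sister-species pairs, a third pair,
    and deep internal branches of >= 1 coalescent unit, so that downstream
    quartet-based estimation has a recoverable signal.  Pendant branches of
    1 coalescent unit x ``subs_scale`` give realistic transcript divergence
    for a recent radiation.
    """
    newick = (
        "(((A:1.0,B:1.0):1.5,(C:1.0,D:1.0):1.5):1.2,(E:1.5,F:1.5):2.2):0.0;"
    )
    return SimSpeciesTree.from_newick(newick, subs_scale=subs_scale)


@dataclass
class GeneFamilyConfig:
    n_families: int = 100
    dup_rate: float = 0.1
    loss_rate: float = 0.05
    seq_length: int = 500
    contaminant_prob: float = 0.0
    contaminant_length: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.contaminant_prob <= 1.0:
            raise ValueError("contaminant_prob must be in [0, 1]")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")


@dataclass
class F2SimConfig:
    n_individuals: int = 48
    model: str = "dominant"  # or "codominant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class QPCRSimConfig:
    """Configuration for a Cq table with known ground truth.

    ``true_rel_expression`` maps gene -> sample -> true expression ratio
    relative to the reference gene.  Efficiencies are amplification factors
    per cycle in (1, 2] (2 = perfect doubling)."""

    true_rel_expression: dict[str, dict[str, float]]
    efficiency_target: float = 2.0
    efficiency_ref: float = 2.0
    base_cq: float = 20.0
    noise_sd: float = 0.0
    reference_gene: str = "ACTIN1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("efficiency_target", "efficiency_ref"):
            e = getattr(self, name)
            if not 1.0 < e <= 2.0:
                raise ValueError(f"{name} must be in (1, 2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Gene family simulation (birth-death along the species tree)
# ---------------------------------------------------------------------------


class _GNode:
    __slots__ = ("children", "length", "label")

    def __init__(self, label=None):
        self.children: list[_GNode] = []
        self.length: float = 0.0
        self.label = label


@dataclass
class GeneFamily:
    """A simulated gene tree with its true ortholog partition.

    ``ortholog_groups`` are the tip sets of maximal duplication-free subtrees
    (one group per surviving locus); within a group every taxon appears at
    most once.  ``degenerate`` flags families with fewer than two surviving
    tips."""

    family_id: int
    tree: dendropy.Tree | None
    ortholog_groups: list[frozenset[str]]
    contaminant_tips: list[str] = field(default_factory=list)
    degenerate: bool = False

    @property
    def tip_labels(self) -> list[str]:
        return [] if self.tree is None else treekit.tip_labels(self.tree)


def simulate_gene_family(
    species_tree: SimSpeciesTree,
    cfg: GeneFamilyConfig,
    family_id: int = 0,
    rng: np.random.Generator | None = None,
) -> GeneFamily:
    """Evolve one gene family along the species tree.

    Duplications and losses occur as Poisson events along each species-tree
    branch (rates per lineage per coalescent unit, applied in time order); a
    duplication copies the whole subtending lineage, which then evolves
    independently down the remaining species tree.  Tips are labeled
    ``taxon@family.copy``.  The returned ortholog groups partition the tips
    by locus: the lineage that keeps evolving through a duplication retains
    its locus id, the new copy receives a fresh one.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sp_root = species_tree.tree.seed_node
    total_rate = cfg.dup_rate + cfg.loss_rate
    locus_counter = [0]
    copy_counter: dict[str, int] = {}
    tip_locus: dict[str, int] = {}

    def new_locus() -> int:
        locus_counter[0] += 1
        return locus_counter[0]

    def make_tip(taxon: str, locus: int) -> _GNode:
        idx = copy_counter.get(taxon, 0)
        copy_counter[taxon] = idx + 1
        label = f"{taxon}{TAXON_SEPARATOR}{family_id}.{idx}"
        tip_locus[label] = locus
        return _GNode(label=label)

    def at_node(sp_node, locus: int) -> _GNode | None:
        if sp_node.is_leaf():
            return make_tip(sp_node.taxon.label, locus)
        survivors = []
        for child in sp_node.child_nodes():
            g = evolve(child, child.edge.length or 0.0, locus)
            if g is not None:
                survivors.append(g)
        if not survivors:
            return None
        if len(survivors) == 1:
            return survivors[0]
        node = _GNode()
        node.children = survivors
        return node

    def evolve(sp_node, remaining: float, locus: int) -> _GNode | None:
        # Returns the gene subtree entered at the top of this branch segment;
        # the returned node's .length is the distance from the entry point.
        if total_rate > 0:
            t = rng.exponential(1.0 / total_rate)
        else:
            t = math.inf
        if t >= remaining:
            g = at_node(sp_node, locus)
            if g is None:
                return None
            g.length += remaining
            return g
        if rng.random() < cfg.loss_rate / total_rate:
            return None  # loss: lineage pruned
        # duplication: the copy starts a new locus from this point
        a = evolve(sp_node, remaining - t, locus)
        b = evolve(sp_node, remaining - t, new_locus())
        survivors = [g for g in (a, b) if g is not None]
        if not survivors:
            return None
        if len(survivors) == 1:
            survivors[0].length += t
            return survivors[0]
        node = _GNode()
        node.length = t
        node.children = survivors
        return node

    root = at_node(sp_root, locus=0)
    tips = sorted(tip_locus)
    groups: dict[int, set[str]] = {}
    for label, locus in tip_locus.items():
        groups.setdefault(locus, set()).add(label)
    ortholog_groups = sorted(
        (frozenset(g) for g in groups.values()), key=lambda g: sorted(g)
    )

    if root is None or len(tips) < 2:
        return GeneFamily(family_id, None, ortholog_groups, degenerate=True)

    # contaminant injection: inflate pendant branch lengths on random tips
    contaminants = []
    scale = species_tree.subs_scale

    def to_newick(node: _GNode) -> str:
        if not node.children:
            if node.label in contaminants:
                length = cfg.contaminant_length
            else:
                length = node.length * scale
            return f"{node.label}:{length:.10g}"
        inner = ",".join(to_newick(c) for c in node.children)
        return f"({inner}):{node.length * scale:.10g}"

    if cfg.contaminant_prob > 0:
        for label in tips:
            if rng.random() < cfg.contaminant_prob:
                contaminants.append(label)

    if len(root.children) == 1:
        root = root.children[0]
    text = f"({','.join(to_newick(c) for c in root.children)});" if root.children else f"({to_newick(root)});"
    tree = treekit.parse_newick(text)
    return GeneFamily(family_id, tree, ortholog_groups, contaminant_tips=contaminants)


def simulate_gene_families(
    species_tree: SimSpeciesTree, cfg: GeneFamilyConfig
) -> list[GeneFamily]:
    """Generate ``cfg.n_families`` independent families from one seed."""
    rng = np.random.default_rng(cfg.seed)
    return [
        simulate_gene_family(species_tree, cfg, family_id=i, rng=rng)
        for i in range(cfg.n_families)
    ]


# ---------------------------------------------------------------------------
# Sequence simulation (Jukes-Cantor)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_sequences(
    gene_tree: dendropy.Tree, seq_length: int, seed: int = 0
) -> Alignment:
    """Evolve an alignment along a gene tree under Jukes-Cantor.

    Branch lengths are expected substitutions/site; per site the probability
    of observing a different base across a branch of length b is
    3/4 (1 - e^{-4b/3}).  The output has one (gap-free, pre-aligned) row per
    tip.  Deterministic for a fixed seed.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    root = gene_tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=seq_length)
    rows: dict[str, str] = {}
    for node in gene_tree.preorder_node_iter():
        if node is not root:
            b = node.edge.length or 0.0
            p = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
            parent_seq = seqs[id(node.parent_node)]
            seq = parent_seq.copy()
            mask = rng.random(seq_length) < p
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut)) % 4
            seqs[id(node)] = seq
        if node.is_leaf():
            rows[node.taxon.label] = "".join(_BASES[seqs[id(node)]])
    return Alignment(rows)


# ---------------------------------------------------------------------------
# Transcript sets
# ---------------------------------------------------------------------------


def make_transcript_set(
    taxon: str,
    families: list[tuple[dendropy.Tree, Alignment]],
    isoform_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Assemble the transcript records for one taxon.

    Each gene copy present in a family yields one record; with probability
    ``isoform_rate`` a near-identical duplicate record (>= 99.5% identity) is
    added, emulating the redundant isoforms that the 0.99-identity dedup
    stage removes.  Record ids follow ``taxon@family.copy.isoform``.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    found = False
    for tree, aln in families:
        for label in treekit.tip_labels(tree):
            if treekit.taxon_of(label) != taxon:
                continue
            found = True
            seq = aln.rows[label].replace("-", "")
            records.append((f"{label}.0", seq))
            if rng.random() < isoform_rate:
                arr = np.array(list(seq))
                n_mut = max(1, int(0.003 * len(seq)))
                pos = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
                for p in pos:
                    choices = [b for b in "ACGT" if b != arr[p]]
                    arr[p] = choices[rng.integers(0, 3)]
                records.append((f"{label}.1", "".join(arr)))
    if not found:
        raise ValueError(f"taxon {taxon!r} not present in any family")
    return records


def parse_transcript_id(record_id: str) -> tuple[str, int, int, int]:
    """Split ``taxon@family.copy.isoform`` back into its components."""
    taxon, rest = record_id.split(TAXON_SEPARATOR, 1)
    family, copy, isoform = rest.split(".")
    return taxon, int(family), int(copy), int(isoform)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# F2 cohorts
# ---------------------------------------------------------------------------

GENOTYPES = ("AA", "Aa", "aa")


def simulate_f2(cfg: F2SimConfig) -> pd.DataFrame:
    """Draw an F2 cohort from selfing a heterozygous F1.

    Genotypes follow the Mendelian 1/4 : 1/2 : 1/4 law.  Under the dominant
    model AA and Aa collapse into one phenotype class ("pigmented" bullseye)
    while aa is "pale"; the codominant model keeps three classes.
    """
    if cfg.model not in ("dominant", "codominant"):
        raise ValueError(f"unknown F2 model: {cfg.model!r}")
    rng = np.random.default_rng(cfg.seed)
    genotypes = rng.choice(GENOTYPES, size=cfg.n_individuals, p=[0.25, 0.5, 0.25])
    if cfg.model == "dominant":
        phenotype_map = {"AA": "pigmented", "Aa": "pigmented", "aa": "pale"}
    else:
        phenotype_map = {"AA": "parent_a", "Aa": "hybrid", "aa": "parent_b"}
    return pd.DataFrame(
        {
            "individual": [f"F2_{i:04d}" for i in range(cfg.n_individuals)],
            "genotype": genotypes,
            "phenotype": [phenotype_map[g] for g in genotypes],
        }
    )


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------


def simulate_cq(cfg: QPCRSimConfig) -> pd.DataFrame:
    """Emit a Cq table whose efficiency-corrected ratios are known.

    Model: a transcript at relative abundance N crosses the detection
    threshold T after Cq = log_E(T / N) cycles for a primer pair with
    per-cycle amplification factor E.  T is anchored so the reference gene
    reads ``base_cq`` cycles, hence for a target with true ratio r,

        Cq_target = (base_cq * ln(E_ref) - ln(r)) / ln(E_target) + noise.

    With noise_sd = 0 the table round-trips exactly (to machine precision)
    through the efficiency-corrected (Pfaffl-type) relative-expression
    computation, for any pair of efficiencies.
    """
    rng = np.random.default_rng(cfg.seed)
    e_t, e_r = cfg.efficiency_target, cfg.efficiency_ref
    rows = []
    samples = sorted({s for per_gene in cfg.true_rel_expression.values() for s in per_gene})
    for sample in samples:
        cq_ref = cfg.base_cq + rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else cfg.base_cq
        rows.append(
            {
                "gene": cfg.reference_gene,
                "sample": sample,
                "cq": cq_ref,
                "efficiency": e_r,
                "is_reference": True,
            }
        )
    for gene, per_sample in sorted(cfg.true_rel_expression.items()):
        for sample, ratio in sorted(per_sample.items()):
            if ratio <= 0:
                raise ValueError("true relative expression must be positive")
            cq = (cfg.base_cq * math.log(e_r) - math.log(ratio)) / math.log(e_t)
            if cfg.noise_sd:
                cq += rng.normal(0.0, cfg.noise_sd)
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "cq": cq,
                    "efficiency": e_t,
                    "is_reference": False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Choice trials and count matrices
# ---------------------------------------------------------------------------


def simulate_choices(n: int, p: float, seed: int = 0) -> np.ndarray:
    """n i.i.d. Bernoulli(p) first-landing choices (1 = focal flower)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(n) < p).astype(int)


def simulate_counts(
    n_genes: int = 2000,
    n_proximal_biased: int = 60,
    n_distal_biased: int = 40,
    n_reps: int = 5,
    true_lfc: float = 4.0,
    dispersion: float = 0.05,
    mean_log: float = 4.0,
    mean_sd: float = 1.0,
    seed: int = 0,
):
    """Two-region count matrix with a planted set of region-biased genes.

    Counts are negative binomial around lognormal base means; planted genes
    get their proximal (or distal) group mean multiplied by 2**true_lfc.
    Five replicates per region by default, mirroring a five-biological-
    replicate RNA-seq design.  Returns (counts, groups, truth) where truth
    maps "proximal_biased"/"distal_biased" to the planted gene-id sets.
    """
    if n_proximal_biased + n_distal_biased > n_genes:
        raise ValueError("more planted genes than genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"proximal_{r + 1}" for r in range(n_reps)] + [
        f"distal_{r + 1}" for r in range(n_reps)
    ]
    groups = {s: ("proximal" if s.startswith("proximal") else "distal") for s in samples}
    base = np.exp(rng.normal(mean_log, mean_sd, size=n_genes))
    mean_prox = base.copy()
    mean_dist = base.copy()
    prox_idx = np.arange(n_proximal_biased)
    dist_idx = np.arange(n_proximal_biased, n_proximal_biased + n_distal_biased)
    mean_prox[prox_idx] *= 2.0 ** true_lfc
    mean_dist[dist_idx] *= 2.0 ** true_lfc

    def draw(mean: np.ndarray) -> np.ndarray:
        # NB with var = m + dispersion * m^2
        r = 1.0 / dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=(n_genes, n_reps))

    counts = np.hstack([draw(mean_prox), draw(mean_dist)])
    truth = {
        "proximal_biased": frozenset(genes[i] for i in prox_idx),
        "distal_biased": frozenset(genes[i] for i in dist_idx),
    }
    return pd.DataFrame(counts, index=genes, columns=samples), groups, truth
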