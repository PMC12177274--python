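# Methods

This note documents the models behind `phylotraits`, the parameter choices
that matter, the numerical conventions, and the known limits of what a
green test establishes.

## 1. Synthetic data: the stated world

All pipeline stages are validated against generated data with known ground
truth. The generators are deliberately minimal, chosen so that each one is
itself checkable against a closed form or a trivial independent simulator.

**Species tree.** The reference tree has six taxa in three pairs,
`(((A,B),(C,D)),(E,F))`, ultrametric in coalescent units, with internal
branches of 1.2–2.2 coalescent units (CU) and pendant branches of 1–1.5 CU.
Internal branches ≥ 1 CU give a strong but not saturated quartet signal
(expected support q = 1 − (2/3)e^(−d) between 0.80 and 0.93), emulating a
recent radiation that is resolvable with a few hundred loci.
`subs_scale = 0.05` converts CU to expected substitutions/site: pendant
divergence ≈ 0.05–0.075 subs/site and maximal pairwise divergence
≈ 0.37 subs/site, typical transcriptome distances between congeneric
species and their near outgroups.

**Gene families.** Duplications and losses are Poisson events along each
species-tree branch (rates per lineage per CU, applied in time order); a
duplication copies the whole subtending lineage, which then evolves
independently down the remainder of the species tree — the standard linear
birth–death gene-family model. Each duplication assigns the new copy a
fresh *locus* id; the true ortholog partition is the grouping of tips by
locus, which coincides with the tip sets of maximal duplication-free
subtrees. Branch lengths are deterministic (structure × `subs_scale`);
there is no rate variation across lineages. Contaminants (mis-assembled or
mis-assigned transcripts, which manifest as implausibly long tips) are
injected by inflating a tip's pendant length to 1.5 subs/site with a
configurable probability — sequence content is untouched, because the
cleaning operators act on branch lengths.

**Sequences.** Jukes–Cantor along the gene tree: per branch of length b the
probability a site differs from its parent is 3/4·(1 − e^(−4b/3)). The
closed form makes the generator testable (a two-tip path of 0.1 subs/site
must show a difference fraction of ≈ 0.0936). No indels; alignments are
emitted pre-aligned, because multiple alignment is outside the package's
scope. Transcript sets add a near-identical isoform (≥ 99.5% identity,
0.3% of sites mutated) with probability `isoform_rate`, feeding the
0.99-identity dedup stage.

**Quantitative genetics and expression.** F2 cohorts draw genotypes from
the Mendelian (¼, ½, ¼) law; the dominant model collapses AA+Aa. Cq tables
follow the threshold model Cq = log_E(T/N): the detection threshold T is
anchored so the reference gene reads `base_cq` cycles, giving
Cq_target = (base_cq·ln E_ref − ln r)/ln E_target + noise for true ratio r.
This construction round-trips *exactly* (machine precision) through the
efficiency-corrected expression ratio for any pair of efficiencies — the
formulation that anchors both primers to a common threshold is the one
consistent with that requirement. Count matrices are negative binomial
(var = μ + 0.05 μ²; biological-replicate-level dispersion) around lognormal
base means, five replicates per region, with 60 + 40 planted region-biased
genes at true |log2FC| = 4 out of 2000 — scaled down roughly in proportion
from the ~940 + ~340 biased genes among an assembled transcriptome that
motivated the design. Choice trials are i.i.d. Bernoulli.

What the generators do **not** emulate: read-level noise, assembly
chimeras, indel evolution, rate heterogeneity, selection, linkage. A green
end-to-end test therefore establishes that the *operators* compose
correctly on data obeying their model assumptions, not that the pipeline
is robust to real assembly artifacts.

## 2. Homology: dedup, similarity graph, Markov clustering

`dedup_greedy` visits records by decreasing length and joins a record to
the first representative whose *containment identity* (best gapless
alignment of the shorter inside the longer, matches/len(shorter)) reaches
the threshold (default 0.99). This mirrors greedy length-sorted dedup
tools without implementing banded alignment; it is idempotent by
construction. Quadratic in sequence length; intended for desk-scale data.

`build_similarity_graph` scores pairs by the number of *distinct* shared
k-mers (default k = 21, single-strand; reverse-complement indexing is a
flag). `mcl` implements Markov clustering: column-stochastic matrix with
self-loops equal to each node's maximum incident weight, expansion
(squaring) alternating with inflation (elementwise power 1.4 +
renormalization), pruning below 1e-9, convergence when the largest entry
change drops below 1e-6 (cap 200 iterations; non-convergence is flagged
on the result, never raised). Clusters are read off attractor rows;
overlapping attractor supports merge; a non-attractor node joins its
largest-mass attractor, ties broken by lexicographic node id.

Inside the full pipeline two adjustments matter, both on the analysis
side: k = 10 (at k = 21 taxa ~0.37 subs/site apart share essentially no
k-mers and families shatter into per-taxon clusters) and log2(1+count)
edge weights before MCL (raw shared-k-mer counts span orders of magnitude
between close and distant relatives, and MCL severs the weak deep edges of
a family; log compression plays the role an aligner's bit score plays in
e-value-based graphs).

## 3. Tree cleaning

All operators take and return trees with branch lengths in subs/site and
tips labeled `taxon@identifier` (`@` is reserved). Pruning always
collapses unary nodes with length summation, so path lengths between
surviving tips are conserved (a tested invariant).

* `clean_columns` keeps alignment columns whose non-gap, non-N occupancy
  is ≥ the threshold (closed boundary at the default 0.1).
* `trim_long_tips`: the absolute rule removes tips with pendant length
  > 0.4 subs/site. The relative rule is underdetermined in common usage;
  here it removes a tip whose pendant exceeds 0.6 subs/site *and* is more
  than 10× the shortest pendant in its sister clade (factor configurable,
  and the sister-clade minimum reduces to the sister tip when that sister
  is a single tip). Both rules are evaluated on the input tree, then all
  flagged tips are pruned at once. Removal of ≥ 95% of injected
  contaminants at the defaults is a tested stochastic property.
* `mask_monophyletic_duplicates` reduces every maximal same-taxon clade to
  the tip with the most unambiguous characters (ties: lexicographic
  smallest label), iterated to a fixed point so nested clades collapse.
* `cut_deep_paralogs` cuts every internal edge ≥ 1.0 subs/site and keeps
  fragments with ≥ 4 distinct taxa (counting taxa, not tips); smaller
  fragments are reported as discarded.
* `neighbor_joining` is the classic agglomeration with deterministic
  tie-breaking (smallest Q, then lexicographically smallest label pair,
  where a merged node is represented by its smallest tip label); negative
  length estimates are clamped to zero. It stands in for ML inference; an
  independent NJ implementation (scikit-bio) is the cross-check in tests,
  and on additive matrices the output is exact.
* `jc_distance` uses d = −¾ ln(1 − 4p/3) over sites where both rows are
  unambiguous; saturated pairs (p ≥ ¾) get a ceiling of 10 subs/site and
  rows sharing no sites are an error rather than a guess.

## 4. Maximum Inclusion

Every edge of the (unrooted) homolog tree defines two candidate subtrees.
MI repeatedly selects, among candidates containing no repeated taxon, the
one maximizing (distinct taxa, then tip count, then smaller internal
branch-length sum, then lexicographically smallest tip set), emits it if
it has ≥ 4 distinct taxa (configurable), deletes its tips (collapsing
unary nodes), and repeats. Long-tip trimming runs once up front by
default, with a flag to re-apply per iteration. Branch sums are rounded to
1e-9 before comparison: sums that are equal up to float accumulation noise
(typical after unary-collapse summation of structurally identical copies)
must fall through to the lexicographic tie-break, otherwise the selection
between interchangeable duplicate copies becomes numerically arbitrary.

**Known limitation.** Unrooted MI cannot recover the true partition when
duplications flank the root on both sides of the tree: no single edge then
isolates the interleaved original locus, and the extraction, while still
single-copy (the hard invariant, asserted on every run), mixes copies.
At ~0.4 duplication events per family the effect is negligible (96.8%
exact group recovery in the seeded test); at ~1.1 events per family it
costs roughly a tenth of the groups. The recovery metric counts a masking
substitution between same-taxon sister copies as correct, since masking
picks by informative sites and cannot (and need not) distinguish loci.

## 5. Quartet species tree in coalescent units

Each gene tree induces one of three resolutions for every 4-taxon subset
it contains (found via the edge separating the pairs; polytomies leave the
subset unresolved and it is skipped, not split fractionally). The species
tree is the topology maximizing the number of agreeing induced quartets —
the maximum-quartet-support estimator, computed exactly by enumerating all
(2n−5)!! unrooted topologies (n ≤ 9; 135 135 candidates at the cap, well
inside a desk budget at the 6-taxon scale the tests use). Ties are broken
by the lexicographically smallest split set. Missing taxa per gene tree
are allowed; quartets are counted only over gene trees containing all four
taxa.

Per internal branch, support q is the frequency of agreeing gene-tree
quartets among those built from one taxon out of each of the four subtrees
adjacent to the branch. For exactly these quartets the induced internal
edge *is* the focal branch, so under the multispecies coalescent
E[q] = 1 − (2/3)e^(−d) and the length in coalescent units is recovered as
d = −ln(3(1−q)/2). (An earlier formulation aggregating over all
two-against-two subsets was discarded: quartets spanning several internal
branches agree more often, inflating d.) q = 1/3 is the random-resolution
floor (d = 0); q below it is an error; q = 1 is reported as a capped
d = 9 CU with a flag — mirroring how perfectly supported branches are
reported finitely. Support is reported as q itself; local posterior
probabilities are out of scope.

The bundled MSC simulator draws rate-1 exponential coalescence within each
species-tree interval (one sample per species, ultrametric species tree)
and exists for recovery experiments: with 200 loci on the reference tree
the topology is recovered in ≥ 95% of seeded replicates and mean branch
lengths land within 25% of truth.

## 6. Expression statistics

The DE stand-in is documented as such: median-of-ratios size factors
(computed over genes positive in all samples; single-sample matrices get
factor 1), log2 fold change of normalized group means with pseudocount 1,
and a Welch t-test on log2(normalized + 1). It deliberately does not
reproduce negative-binomial GLM inference with dispersion shrinkage, and
at the strict threshold (|log2FC| ≥ 2 and BH-adjusted P < 10⁻⁵, the
filter's defaults) its sensitivity at n = 5 is modest (~30% of planted
16-fold genes), though what it flags is essentially always a planted gene
(FDR control holds comfortably) and its ranking recovers > 90% of planted
genes at a relaxed α = 10⁻³. The filter accepts externally produced
(log2fc, padj) tables, so a stronger upstream test can be swapped in.
The printed filter threshold is read as |log2FC| ≥ 2 — the "fourfold
cutoff" reading — since its literal form ("≤ 2 or > 2") covers every gene.

Benjamini–Hochberg adjustment is the standard step-up (delegated to
statsmodels). Two properties worth stating precisely, because a commonly
repeated claim is wrong: the adjustment is monotone and dominating
(padj ≥ p, order-preserving), and re-adjusting its output can only inflate
it — but it is *not* idempotent on values (bh([1, .25]) = [1, .5] while
bh([1, .5]) = [1, 1]); it is a fixed point exactly on tied-tail outputs
such as (.01, .02, .03) → (.03, .03, .03).

qPCR relative expression is the single-sample efficiency-corrected form
ratio = E_ref^Cq_ref / E_target^Cq_target with efficiencies as per-cycle
amplification factors in (1, 2] (a percent input like 95 converts to
1.95). The two-sample test chooser runs Shapiro–Wilk on both groups
(n ≥ 3 each, otherwise the rank test is forced); if both pass at α = 0.05
a two-sided F-test (Levene optional) routes to Student's or Welch's t,
otherwise to the two-sided Wilcoxon rank-sum test.

## 7. Trait statistics

Segregation uses plain Pearson χ² (continuity correction off by default,
Yates as a flag) with df = classes − 1; expected counts below 1 raise a
validity flag rather than an error. `best_mendelian_ratio` returns the
candidate with the largest goodness-of-fit p-value along with the full
table. Note the exact size of the plain Pearson test at α = 0.05 for an
n = 48 cohort under a true 3:1 model is 0.0646 (binomial enumeration) —
slightly anti-conservative, a discreteness effect, with Yates
over-correcting to 0.0287; the calibration test asserts agreement with the
enumerated size rather than the nominal 5%.

Co-segregation reports the concordant fraction between marker genotypes
and the genotype predicted by each phenotype class, excluding missing
genotypes, with a permutation p-value over genotype shuffles (identity
permutation included, so p > 0; agrees with exhaustive enumeration on
small cohorts). Pigment content is A × CF × V_cuvette × V_extract /
(V_loaded × mass) in mg equivalent per g fresh weight, with the
conversion factor CF = 1/slope from an OLS standard curve (≥ 3 distinct
concentrations; CI from the slope standard error). Volumes are ml; a μl
constructor converts. The preference test reports the focal-choice
proportion, a two-sided one-sample t-test of the binary trials against
0.5 (two-sided is the default because it reproduces the printed worked
example; one-sided is a flag), and the exact binomial p alongside — with
zero variance the t statistic is undefined and only the proportion and
binomial p are returned, flagged.

## 8. Numerical conventions and degenerate inputs

Newick I/O preserves lengths to 1e-9 (12 significant digits on write);
internal node labels are ignored on read; `@` is legal unquoted. Empty
alignments after column cleaning, trees degenerate after trimming (< 2
tips), and families with < 2 surviving tips are flagged, not raised.
Deterministic tie-breaks everywhere randomness is not intended:
lexicographic label order in NJ, masking, MCL assignment, and MI; all
generators are exactly reproducible from their seed.
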