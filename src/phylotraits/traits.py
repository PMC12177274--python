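"""Mendelian genetics, pigment quantification, and pollinator statistics.

Covers the quantitative-genetics and phenotype side of a bullseye-pattern
study: chi-square goodness of fit of F2 segregation counts against
single-locus ratios (3:1 dominant, 1:2:1 codominant, ...), selection of the
best-fitting Mendelian ratio, genotype-phenotype co-segregation with a
permutation null, absorbance-based flavonoid quantification via a standard
curve, bullseye-geometry ratios, pairwise sequence identity, and the
one-sample t / exact binomial analysis of binary pollinator-choice trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegregationTest",
    "chisq_goodness",
    "best_mendelian_ratio",
    "cosegregation",
    "CosegregationResult",
    "standard_curve_cf",
    "StandardCurve",
    "PigmentAssay",
    "pigment_concentration",
    "bullseye_proportion",
    "fold_ratio",
    "percent_identity",
    "preference_test",
    "PreferenceResult",
]


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------


@dataclass
class SegregationTest:
    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    pvalue: float
    yates: bool = False
    low_expected: bool = False  # any expected class count < 1


def chisq_goodness(observed, ratio, yates: bool = False) -> SegregationTest:
    """Pearson chi-square goodness of fit of counts against a ratio.

    expected_i = N * ratio_i / sum(ratio); chi2 = sum (O-E)^2 / E with
    df = classes - 1.  Continuity (Yates) correction is off by default.
    Expected counts below 1 set a validity warning flag.
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.shape != rat.shape:
        raise ValueError("observed and ratio must be 1-D and the same length")
    if (obs < 0).any():
        raise ValueError("observed counts must be >= 0")
    if (rat <= 0).any():
        raise ValueError("ratio parts must be > 0")
    expected = obs.sum() * rat / rat.sum()
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff ** 2 / expected).sum())
    df = len(obs) - 1
    pvalue = float(stats.chi2.sf(chi2, df))
    return SegregationTest(
        observed=tuple(int(o) for o in obs),
        ratio=tuple(float(r) for r in rat),
        expected=tuple(float(e) for e in expected),
        chi2=chi2,
        df=df,
        pvalue=pvalue,
        yates=yates,
        low_expected=bool((expected < 1).any()),
    )


def best_mendelian_ratio(
    observed, candidates, yates: bool = False
) -> tuple[tuple[float, ...], list[SegregationTest]]:
    """Best-fitting candidate segregation ratio by goodness-of-fit p-value.

    Returns (winning ratio, full table of per-candidate tests, in input
    order).  Candidates whose length does not match the observed classes
    are rejected up front.
    """
    candidates = [tuple(c) for c in candidates]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate ratios")
    table = [chisq_goodness(observed, c, yates=yates) for c in candidates]
    best = max(table, key=lambda t: t.pvalue)
    return best.ratio, table


# ---------------------------------------------------------------------------
# Co-segregation
# ---------------------------------------------------------------------------


@dataclass
class CosegregationResult:
    n_scored: int
    n_missing: int
    concordant: int
    concordance: float
    permutation_p: float
    n_permutations: int


def cosegregation(
    cohort: pd.DataFrame,
    expected_map: dict[str, str],
    n_permutations: int = 10000,
    seed: int = 0,
    missing: str = "missing",
) -> CosegregationResult:
    """Concordance between marker genotypes and phenotype classes.

    ``cohort`` needs columns phenotype and genotype; ``expected_map`` gives
    the genotype predicted by each phenotype class.  Individuals with a
    missing genotype are excluded (and reported).  The permutation p-value
    is the fraction of genotype shuffles achieving at least the observed
    concordant count (including the identity, so p is never 0).
    """
    missing_mask = cohort["genotype"].astype(str) == missing
    scored = cohort[~missing_mask]
    if scored.empty:
        raise ValueError("no individuals with non-missing genotypes")
    unmapped = set(scored["phenotype"]) - set(expected_map)
    if unmapped:
        raise ValueError(f"expected_map missing phenotype classes: {sorted(unmapped)}")
    predicted = scored["phenotype"].map(expected_map).to_numpy()
    genotypes = scored["genotype"].to_numpy()
    concordant = int((predicted == genotypes).sum())
    n = len(scored)
    rng = np.random.default_rng(seed)
    hits = 1  # count the identity permutation
    for _ in range(n_permutations):
        if int((predicted == rng.permutation(genotypes)).sum()) >= concordant:
            hits += 1
    return CosegregationResult(
        n_scored=n,
        n_missing=int(missing_mask.sum()),
        concordant=concordant,
        concordance=concordant / n,
        permutation_p=hits / (n_permutations + 1),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Flavonoid quantification
# ---------------------------------------------------------------------------


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    conversion_factor: float  # 1 / slope, in mg ml^-1 AU^-1
    cf_ci: tuple[float, float]
    r_squared: float


def standard_curve_cf(absorbances, known_concs, ci: float = 0.95) -> StandardCurve:
    """Conversion factor from a standard curve (OLS absorbance ~ concentration).

    The conversion factor is 1/slope; its confidence interval is derived
    from the OLS slope standard error (delta on the reciprocal via the
    slope CI endpoints).  Requires >= 3 points over >= 3 distinct
    concentrations (replicates allowed).
    """
    a = np.asarray(absorbances, dtype=float)
    c = np.asarray(known_concs, dtype=float)
    if a.shape != c.shape or a.ndim != 1:
        raise ValueError("absorbances and concentrations must be matched 1-D arrays")
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    fit = stats.linregress(c, a)
    if fit.slope == 0:
        raise ValueError("zero slope: absorbance does not respond to concentration")
    tcrit = stats.t.ppf(0.5 + ci / 2.0, len(a) - 2)
    lo = fit.slope - tcrit * fit.stderr
    hi = fit.slope + tcrit * fit.stderr
    if lo <= 0 < fit.slope or hi <= 0 < fit.slope:
        cf_ci = (1.0 / hi, float("inf"))
    else:
        cf_ci = tuple(sorted((1.0 / lo, 1.0 / hi)))
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        conversion_factor=1.0 / float(fit.slope),
        cf_ci=cf_ci,
        r_squared=float(fit.rvalue) ** 2,
    )


_ML_PER_UL = 1e-3


@dataclass
class PigmentAssay:
    """One absorbance measurement with its extraction bookkeeping.

    Volumes are in ml (values given in microliters can be converted with
    ``PigmentAssay.from_ul``); tissue mass in g; conversion factor in
    mg ml^-1 AU^-1 from the matching standard curve.
    """

    absorbance: float
    conversion_factor: float
    vol_cuvette_total: float
    vol_extract_total: float
    vol_loaded: float
    tissue_mass: float

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        for name in ("vol_cuvette_total", "vol_extract_total", "vol_loaded", "tissue_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_ul(cls, absorbance, conversion_factor, vol_cuvette_total_ul,
                vol_extract_total_ul, vol_loaded_ul, tissue_mass_g):
        return cls(
            absorbance,
            conversion_factor,
            vol_cuvette_total_ul * _ML_PER_UL,
            vol_extract_total_ul * _ML_PER_UL,
            vol_loaded_ul * _ML_PER_UL,
            tissue_mass_g,
        )


def pigment_concentration(assay: PigmentAssay) -> float:
    """Pigment content in mg equivalent per g fresh tissue.

    value = A x CF x V_cuvette x V_extract / (V_loaded x mass): the
    absorbance converts to mg/ml in the cuvette, is scaled back up from the
    loaded aliquot to the whole extract, and normalized by tissue mass.
    Linear in absorbance.
    """
    return (
        assay.absorbance
        * assay.conversion_factor
        * assay.vol_cuvette_total
        * assay.vol_extract_total
        / (assay.vol_loaded * assay.tissue_mass)
    )


# ---------------------------------------------------------------------------
# Bullseye geometry and sequence identity
# ---------------------------------------------------------------------------


def bullseye_proportion(pigmented_area: float, total_area: float) -> float:
    """Pigmented region as a percentage of total petal area."""
    if total_area <= 0:
        raise ValueError("total_area must be > 0")
    if not 0 <= pigmented_area <= total_area:
        raise ValueError("pigmented_area must be in [0, total_area]")
    return 100.0 * pigmented_area / total_area


def fold_ratio(a: float, b: float) -> float:
    """Fold difference a/b (b must be positive)."""
    if b <= 0:
        raise ValueError("denominator must be > 0")
    return a / b


def percent_identity(n_diff: int, aligned_length: int) -> tuple[float, int]:
    """Percent identity over an alignment; returns (raw, rounded-to-int)."""
    if aligned_length <= 0:
        raise ValueError("aligned_length must be > 0")
    if not 0 <= n_diff <= aligned_length:
        raise ValueError("n_diff must be in [0, aligned_length]")
    raw = 100.0 * (aligned_length - n_diff) / aligned_length
    return raw, int(round(raw))


# ---------------------------------------------------------------------------
# Pollinator preference
# ---------------------------------------------------------------------------


@dataclass
class PreferenceResult:
    n: int
    n_focal: int
    proportion: float
    t_statistic: float | None
    t_pvalue: float | None
    binomial_p: float
    degenerate: bool = False  # all trials identical: t undefined


def preference_test(choices, null: float = 0.5, alternative: str = "two-sided") -> PreferenceResult:
    """First-landing preference for the focal flower.

    ``choices`` is a binary vector (1 = focal flower chosen).  Reports the
    preference proportion, a one-sample t-test of the trials against the
    null proportion (df = n - 1), and the exact binomial p-value.  With
    zero variance the t statistic is undefined and only the proportion and
    binomial p are reported.
    """
    x = np.asarray(choices, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of >= 2 trials")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("choices must be binary (0/1)")
    n = len(x)
    k = int(x.sum())
    binom = stats.binomtest(k, n, null, alternative=alternative).pvalue
    if x.std(ddof=1) == 0:
        return PreferenceResult(n, k, k / n, None, None, float(binom), degenerate=True)
    t = stats.ttest_1samp(x, null, alternative=alternative)
    return PreferenceResult(
        n=n,
        n_focal=k,
        proportion=k / n,
        t_statistic=float(t.statistic),
        t_pvalue=float(t.pvalue),
        binomial_p=float(binom),
    )
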