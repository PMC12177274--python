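"""Differential-expression filtering and efficiency-corrected qPCR.

The RNA-seq side provides a transparent stand-in for a negative-binomial
DE pipeline: median-of-ratios size factors, a Welch t-test on
log2(normalized count + 1), Benjamini-Hochberg FDR adjustment, and the
|log2FC| >= 2 & adjusted-P < 1e-5 filter used to call region-biased genes.
The filter also accepts externally produced (log2fc, padj) tables — the
stand-in test is not a re-implementation of shrinkage-based NB inference
and is documented as such.

The qPCR side implements efficiency-corrected (Pfaffl-type / modified
delta-Ct) relative expression against a single reference gene, plus the
normality/variance-guided chooser between Student's t, Welch's t, and the
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "de_test",
    "bh_adjust",
    "de_filter",
    "pfaffl_relative_expression",
    "relative_expression_table",
    "efficiency_from_percent",
    "choose_two_sample_test",
    "TestChoice",
]


# ---------------------------------------------------------------------------
# Count normalization and the stand-in DE test
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each gene with strictly positive counts in every sample, the ratio
    of each sample's count to the gene's geometric mean is formed; a
    sample's factor is the median of those ratios.  A single-sample matrix
    gets factor 1.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    sub = mat[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns)


def de_test(
    counts: pd.DataFrame,
    groups: dict[str, str],
    group_a: str = "proximal",
    group_b: str = "distal",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-group stand-in differential-expression test.

    Counts are normalized by median-of-ratios size factors; log2 fold change
    is log2((mean_a + pseudocount) / (mean_b + pseudocount)) of normalized
    group means (positive = biased toward ``group_a``); the p-value is a
    Welch t-test on log2(normalized + pseudocount).  Genes with zero
    variance in both groups and equal means get p = 1.
    """
    a_cols = [s for s in counts.columns if groups[s] == group_a]
    b_cols = [s for s in counts.columns if groups[s] == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    factors = size_factors(counts)
    norm = counts / factors
    a = norm[a_cols].to_numpy(dtype=float)
    b = norm[b_cols].to_numpy(dtype=float)
    log2fc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvalues = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    degenerate = (la.std(axis=1) == 0) & (lb.std(axis=1) == 0)
    pvalues = np.where(degenerate & (la.mean(axis=1) == lb.mean(axis=1)), 1.0, pvalues)
    pvalues = np.where(degenerate & (la.mean(axis=1) != lb.mean(axis=1)), 0.0, pvalues)
    return pd.DataFrame(
        {"gene": counts.index, "log2fc": log2fc, "pvalue": pvalues}
    ).set_index("gene")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_filter(
    records: pd.DataFrame, lfc_cut: float = 2.0, alpha: float = 1e-5
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag differentially expressed genes: |log2fc| >= lfc_cut and padj < alpha.

    ``records`` needs columns log2fc and either padj or pvalue (the latter is
    BH-adjusted on the fly).  Returns the table with a ``flag_de`` column and
    the counts of proximal-biased (log2fc >= +cut) and distal-biased
    (log2fc <= -cut) flagged genes.
    """
    out = records.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["flag_de"] = (out["log2fc"].abs() >= lfc_cut) & (out["padj"] < alpha)
    n_proximal = int(((out["log2fc"] >= lfc_cut) & out["flag_de"]).sum())
    n_distal = int(((out["log2fc"] <= -lfc_cut) & out["flag_de"]).sum())
    return out, {"proximal_biased": n_proximal, "distal_biased": n_distal}


# ---------------------------------------------------------------------------
# Efficiency-corrected qPCR
# ---------------------------------------------------------------------------


def efficiency_from_percent(percent: float) -> float:
    """Convert a percent amplification efficiency (e.g. 95) to a per-cycle
    amplification factor (1.95)."""
    if not 0.0 < percent <= 100.0:
        raise ValueError("percent efficiency must be in (0, 100]")
    return 1.0 + percent / 100.0


def _check_eff(e: float, name: str) -> None:
    if not 1.0 < e <= 2.0:
        raise ValueError(f"{name} must be in (1, 2], got {e}")


def pfaffl_relative_expression(
    cq_target: float, eff_target: float, cq_ref: float, eff_ref: float
) -> float:
    """Efficiency-corrected relative expression of a target vs a reference.

    ratio = E_ref^Cq_ref / E_target^Cq_target, the single-sample modified
    delta-Ct form: each primer pair's real amplification factor converts its
    Cq into a relative template amount, and the target amount is normalized
    by the reference gene's.
    """
    _check_eff(eff_target, "target efficiency")
    _check_eff(eff_ref, "reference efficiency")
    return eff_ref ** cq_ref / eff_target ** cq_target


def relative_expression_table(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative expression for every non-reference gene.

    Expects columns gene, sample, cq, efficiency, is_reference with exactly
    one reference row per sample.
    """
    out = []
    for sample, chunk in cq_table.groupby("sample"):
        ref = chunk[chunk["is_reference"]]
        if len(ref) != 1:
            raise ValueError(f"sample {sample!r} needs exactly one reference row")
        ref = ref.iloc[0]
        for _, row in chunk[~chunk["is_reference"]].iterrows():
            out.append(
                {
                    "gene": row["gene"],
                    "sample": sample,
                    "relative_expression": pfaffl_relative_expression(
                        row["cq"], row["efficiency"], ref["cq"], ref["efficiency"]
                    ),
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Normality/variance-guided two-sample test chooser
# ---------------------------------------------------------------------------


@dataclass
class TestChoice:
    test: str  # "student" | "welch" | "wilcoxon"
    pvalue: float
    shapiro_p: tuple[float, float] | None = None
    variance_p: float | None = None


def choose_two_sample_test(
    x, y, alpha: float = 0.05, variance_test: str = "f"
) -> TestChoice:
    """Pick Student's t, Welch's t, or the Wilcoxon rank-sum test.

    Shapiro-Wilk is run on both groups (needs n >= 3 each, otherwise the
    nonparametric test is forced).  If both look normal (p >= alpha), the
    variance-homogeneity test (two-sided F by default, Levene optionally)
    decides between Student (equal variances) and Welch; any non-normal
    group routes to the two-sided Wilcoxon rank-sum (Mann-Whitney) test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if len(x) < 3 or len(y) < 3:
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        return TestChoice("wilcoxon", float(p))
    sx = stats.shapiro(x).pvalue
    sy = stats.shapiro(y).pvalue
    if sx < alpha or sy < alpha:
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        return TestChoice("wilcoxon", float(p), shapiro_p=(float(sx), float(sy)))
    if variance_test == "levene":
        var_p = float(stats.levene(x, y).pvalue)
    else:
        f = np.var(x, ddof=1) / np.var(y, ddof=1)
        cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
        var_p = float(2.0 * min(cdf, 1.0 - cdf))
    equal_var = var_p >= alpha
    p = stats.ttest_ind(x, y, equal_var=equal_var).pvalue
    return TestChoice(
        "student" if equal_var else "welch",
        float(p),
        shapiro_p=(float(sx), float(sy)),
        variance_p=var_p,
    )
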