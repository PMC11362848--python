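"""Correlation and group-comparison statistics for density vectors.

The analysis contract is: test each variable for normality (Shapiro–Wilk,
normal iff p > .05); correlate normally distributed pairs with Pearson's r
and everything else with Kendall's tau-b (tie-corrected, the appropriate
choice for heavily tied per-pixel density vectors); compare group means with
ANOVA followed by pairwise t-tests under Bonferroni correction; analyze 2×2
cross tables with Fisher's exact test. Alpha defaults to 0.05.

The numerical work delegates to scipy.stats; this module owns the method
gate, the result containers and the degenerate-input contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "CorrelationResult",
    "GroupComparison",
    "kendall_tau_b",
    "pearson_r",
    "normality_gate",
    "fisher_exact_2x2",
    "compare_groups",
    "density_correlation",
]

ALPHA = 0.05
_SHAPIRO_MAX_N = 5000  # W-statistic calibration range; larger samples are thinned


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "kendall_tau_b"
    estimate: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    anova_p: float
    pairwise_p: pd.DataFrame  # Bonferroni-adjusted, symmetric
    n_comparisons: int


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    return x, y


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall's tau-b with tie correction.

    The p-value is exact (permutation enumeration) for small untied samples
    and otherwise uses the tie-adjusted normal approximation. An all-tied
    vector has no defined rank correlation: the estimate is NaN, flagged by
    a warning.
    """
    x, y = _check_pair(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("all-tied vector: tau-b undefined", stacklevel=2)
        return CorrelationResult("kendall_tau_b", float("nan"), float("nan"), len(x))
    method = "exact" if (len(x) <= 50 and len(np.unique(x)) == len(x)
                         and len(np.unique(y)) == len(y)) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return CorrelationResult("kendall_tau_b", float(res.statistic), float(res.pvalue), len(x))


def pearson_r(x, y) -> CorrelationResult:
    x, y = _check_pair(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Pearson r undefined", stacklevel=2)
        return CorrelationResult("pearson", float("nan"), float("nan"), len(x))
    res = sps.pearsonr(x, y)
    return CorrelationResult("pearson", float(res.statistic), float(res.pvalue), len(x))


def normality_gate(x, alpha: float = ALPHA) -> str:
    """Shapiro–Wilk gate driving the Pearson/Kendall method choice.

    Returns ``"normal"`` iff the Shapiro–Wilk p-value exceeds ``alpha``.
    Samples beyond the W-statistic's calibrated range are thinned to
    _SHAPIRO_MAX_N evenly spaced order statistics. Constant input fails.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    if np.all(x == x[0]):
        raise ValueError("constant sample: normality test undefined")
    if len(x) > _SHAPIRO_MAX_N:
        idx = np.linspace(0, len(x) - 1, _SHAPIRO_MAX_N).astype(int)
        x = np.sort(x)[idx]
    p = float(sps.shapiro(x).pvalue)
    return "normal" if p > alpha else "non_normal"


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 count table (sum of hypergeometric
    probabilities no larger than the observed one)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin: a row or column of the table is all zero")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def compare_groups(values, groups) -> GroupComparison:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests.

    Adjusted p = min(1, raw p × number of pairwise comparisons).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    anova_p = float(sps.f_oneway(*samples).pvalue)

    m = len(levels) * (len(levels) - 1) // 2
    mat = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels, columns=levels)
    for i, gi in enumerate(levels):
        for j in range(i + 1, len(levels)):
            gj = levels[j]
            raw = float(sps.ttest_ind(samples[i], samples[j]).pvalue)
            adj = min(1.0, raw * m)
            mat.loc[gi, gj] = mat.loc[gj, gi] = adj
    return GroupComparison(anova_p=anova_p, pairwise_p=mat, n_comparisons=m)


def density_correlation(
    table: pd.DataFrame,
    var_x: str,
    var_y: str,
    bins: int = 50,
) -> tuple[CorrelationResult, np.ndarray, np.ndarray, np.ndarray]:
    """Correlate two density columns of a cortex pixel table and summarize
    their joint distribution as a 2-D histogram.

    The normality gate picks the method: Pearson when both variables pass,
    Kendall's tau-b otherwise (per-pixel density vectors are rarely normal).
    Returns (result, histogram, x_edges, y_edges); histogram counts sum to
    the number of rows.
    """
    x = table[var_x].to_numpy(dtype=float)
    y = table[var_y].to_numpy(dtype=float)
    gate_x = normality_gate(x)
    gate_y = normality_gate(y)
    if gate_x == "normal" and gate_y == "normal":
        result = pearson_r(x, y)
    else:
        result = kendall_tau_b(x, y)
    hist, x_edges, y_edges = np.histogram2d(x, y, bins=bins)
    return result, hist, x_edges, y_edges
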