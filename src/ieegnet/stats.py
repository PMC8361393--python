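"""The D_rs distinguishability statistic and cohort-level tests.

D_rs asks whether node strength separates resected from spared tissue. It is
the normalized Mann-Whitney U statistic (equivalently, the area under the ROC
curve for classifying nodes as resected vs spared), oriented so that

* D_rs = 1   -> every resected node is weaker than every spared node,
* D_rs = 0   -> every resected node is stronger than every spared node,
* D_rs = 0.5 -> strength carries no information about the resection.

Ties receive half credit (midranks), which is exactly what makes D_rs the
normalized U statistic. Cohort comparisons use nonparametric tests (Wilcoxon
rank-sum and signed-rank), Fisher's exact test for categorical tables, and
Pearson correlation for the focality analysis; p-values are two-sided and
deliberately unadjusted (an FDR flag is available but off by default).
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .types import DrsResult, GroupComparison, InvalidSpecError


def distinguishability(
    strengths: np.ndarray,
    resected_mask: np.ndarray,
    condition: str = "GM",
    measure: str = "",
) -> DrsResult:
    """Resection-zone distinguishability of node strengths.

    D_rs = (1 / (n_r * n_s)) * sum over (resected r, spared s) pairs of
    [1 if s_r < s_s, 0.5 if equal, 0 otherwise], computed via midranks.

    Raises if either class is empty.
    """
    s = np.asarray(strengths, dtype=float)
    mask = np.asarray(resected_mask, dtype=bool)
    if s.shape != mask.shape:
        raise InvalidSpecError("strengths and mask differ in shape")
    n_r = int(mask.sum())
    n_s = int((~mask).sum())
    if n_r == 0 or n_s == 0:
        raise InvalidSpecError(
            f"both classes must be non-empty (resected={n_r}, spared={n_s})"
        )
    ranks = sps.rankdata(s)  # midranks
    # pairs where a resected node outranks a spared one (ties half credit)
    u_resected_higher = ranks[mask].sum() - n_r * (n_r + 1) / 2.0
    value = 1.0 - u_resected_higher / (n_r * n_s)
    return DrsResult(value=float(value), n_resected=n_r, n_spared=n_s,
                     condition=condition, measure=measure)


def rank_sum(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Exact null distribution for small tie-free samples, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidSpecError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        test="rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method=method,
    )


def sign_rank(paired_diffs: Sequence[float]) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; the exact distribution is used for n <= 25
    when the ranks are tie-free, otherwise the normal approximation.
    Raises if every difference is zero.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise InvalidSpecError("all paired differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", method=method)
    return GroupComparison(
        test="sign_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=d.size,
        n_b=d.size,
        median_a=float(np.median(d)),
        median_b=0.0,
        method=method,
    )


def fisher_exact(table_2x2: Sequence[Sequence[int]]) -> GroupComparison:
    """Two-sided Fisher's exact test (point-probability method) on a 2x2 table."""
    table = np.asarray(table_2x2)
    if table.shape != (2, 2):
        raise InvalidSpecError("Fisher's exact test needs a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if (table != np.round(table)).any() or (table < 0).any():
            raise InvalidSpecError("table entries must be non-negative integers")
        table = table.astype(int)
    res = sps.fisher_exact(table, alternative="two-sided")
    return GroupComparison(
        test="fisher_exact",
        statistic=float(res[0]),
        p_value=float(res[1]),
        n_a=int(table[:, 0].sum()),
        n_b=int(table[:, 1].sum()),
        method="exact",
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidSpecError("x and y differ in length")
    if x.size < 3:
        raise InvalidSpecError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidSpecError("constant input")
    rho, p = sps.pearsonr(x, y)
    return float(rho), float(p)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default upstream)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float))
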