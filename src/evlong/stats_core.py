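"""Statistical kernel for the EV peptide pipeline.

Six procedures, all two-sided: Wilcoxon rank-sum (exact for small tie-free
samples, normal approximation with tie and continuity correction otherwise),
Pearson chi-squared on a 2x2 table, Benjamini-Hochberg step-up adjustment,
Spearman rank correlation, the rank (Mann-Whitney) formulation of the ROC
AUC, and a two-sample t-test from summary statistics. Thin, documented
wrappers over scipy/statsmodels where those implement the textbook
procedure; the switching rules and degenerate-input policies live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Largest combined sample size at which the rank-sum test enumerates the
#: exact null distribution (tie-free inputs only). Above this, or with ties,
#: the tie-corrected normal approximation with continuity correction is used.
EXACT_RANKSUM_LIMIT = 14


class DegenerateTableError(ValueError):
    """A 2x2 table with an empty row or column margin: the test is undefined."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_value: float
    method_detail: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def rank_sum_test(x, y, exact_limit: int = EXACT_RANKSUM_LIMIT) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    The statistic reported is U for the first sample. With combined sample
    size at most ``exact_limit`` and no ties the p-value is computed by exact
    enumeration of the permutation null; otherwise by the normal
    approximation with average-rank tie correction and continuity correction.
    Identical constant samples are a fully tied comparison and return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= exact_limit and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), "exact")
    if np.all(pooled == pooled[0]):
        # all observations tied: statistic is the same under every labeling
        return TestResult(float(x.size * y.size / 2.0), 1.0, "approximate;tie-corrected")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), "approximate;tie-corrected")


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-squared test (1 df, no continuity correction) on
    the table [[a, b], [c, d]].

    Raises :class:`DegenerateTableError` when a row or column margin is zero;
    callers exclude such peptides rather than patching counts.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError(f"zero margin in 2x2 table {counts.tolist()}")
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(float(stat), float(p), "pearson;1df;no-continuity")


def bh_adjust(p_values, q: float = 0.01):
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(q_values, reject)`` where q_values are the monotone-enforced
    adjusted p-values and ``reject`` flags q_value <= q. Applied within one
    test family only; the pipeline runs it separately per track.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided p via the
    t approximation. Constant input is flagged as an error (rho undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman_corr requires at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def auc_rank(scores, labels) -> float:
    """ROC AUC by the rank (Mann-Whitney) formulation:
    (concordant + 0.5 * tied) / (positive x negative pairs).

    ``labels`` are binary with 1 = positive; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_rank requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def t_test_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> TestResult:
    """Two-sample t-test from group means, SDs, and sizes (two-sided).

    Pooled-variance by default (df = n1+n2-2); Welch with ``equal_var=False``.
    Intended for published summary rows: inputs are typically rounded, so
    recomputed p-values carry the rounding of the summaries.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return TestResult(float(t), float(p), "pooled" if equal_var else "welch")
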