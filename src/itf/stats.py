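"""Shared statistical primitives.

Rank-sum testing is implemented here rather than delegated wholesale to
scipy because the differential-methylation stage needs the exact null
distribution computed once per group-size pair and reused across thousands
of probes; scipy rebuilds it per call.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "rank_sum_test",
    "rank_sum_test_rows",
    "benjamini_hochberg",
    "rank_auc",
    "f_variance_test",
    "stars",
]

#: combined sample size at or below which the exact rank-sum null is used
EXACT_N_MAX = 25


@lru_cache(maxsize=32)
def _ranksum_cdf(n: int, m: int) -> np.ndarray:
    """CDF of the rank sum W of the first group (size n) under the null.

    Entry w of the returned array is P(W <= w); index 0 corresponds to the
    minimal rank sum n(n+1)/2.  Computed by dynamic programming over which
    ranks the first group occupies (no ties assumed).
    """
    total = n + m
    w_max = n * total - n * (n - 1) // 2  # sum of the n largest ranks
    w_min = n * (n + 1) // 2
    span = w_max - w_min + 1
    # dp[k, w] = number of k-subsets of ranks seen so far with sum w + w_min_k
    dp = np.zeros((n + 1, n * total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, total + 1):
        for k in range(min(r, n), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r > 0 else dp[k - 1, :]
    counts = dp[n, w_min : w_min + span]
    cdf = np.cumsum(counts)
    return cdf / cdf[-1]


def _exact_two_sided_p(w: float, n: int, m: int) -> float:
    cdf = _ranksum_cdf(n, m)
    w_min = n * (n + 1) // 2
    idx = int(round(w)) - w_min
    idx = min(max(idx, 0), len(cdf) - 1)
    p_low = cdf[idx]
    p_high = 1.0 - (cdf[idx - 1] if idx > 0 else 0.0)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _tie_correction(ranked: np.ndarray) -> float:
    _, counts = np.unique(ranked, return_counts=True)
    return float(np.sum(counts**3 - counts))


def rank_sum_test(a, b, *, exact_max_n: int = EXACT_N_MAX) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(u_statistic, p_value)`` where U is counted for group ``a``.
    Exact null distribution when the combined n is small and the data are
    tie-free; otherwise a tie-corrected normal approximation with
    continuity correction.  A fully tied input returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n < 1 or m < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n + m
    if np.ptp(pooled) == 0:
        return u, 1.0
    if not has_ties and (n + m) <= exact_max_n:
        return u, _exact_two_sided_p(w, n, m)
    total = n + m
    mu = n * m / 2.0
    tie = _tie_correction(pooled)
    sigma2 = n * m / 12.0 * ((total + 1) - tie / (total * (total - 1)))
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return u, float(min(1.0, 2.0 * sps.norm.sf(z)))


def rank_sum_test_rows(matrix: np.ndarray, group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for a CpG/gene x sample matrix.

    ``group_a``/``group_b`` are column index arrays.  The exact null table
    is shared across rows, which makes this fast for array-scale input.
    """
    matrix = np.asarray(matrix, dtype=float)
    out = np.empty(matrix.shape[0], dtype=float)
    for i in range(matrix.shape[0]):
        _, out[i] = rank_sum_test(matrix[i, group_a], matrix[i, group_b])
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(ranked, 1.0)
    return q


def rank_auc(scores, labels) -> float:
    """AUC as the rank (Mann-Whitney) statistic; ties count one half.

    ``labels`` is a boolean/0-1 array marking positives.  Raises on a
    single-class input where the AUC is undefined.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: truth contains a single class")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def f_variance_test(a, b) -> tuple[float, float]:
    """Two-sided variance-ratio (Fisher-Snedecor) test.

    F is the larger sample variance over the smaller, so F >= 1; the
    two-sided p doubles the upper tail of the matching F distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va if va > 0 else np.inf, len(b) - 1, len(a) - 1
    if not np.isfinite(f):
        return float("inf"), 0.0
    if va == vb:
        return 1.0, 1.0
    p = 2.0 * sps.f.sf(f, dfn, dfd)
    return float(f), float(min(1.0, p))


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
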