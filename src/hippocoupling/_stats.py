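"""Rank-test wrappers shared by the contrast and marker modules.

Both tests switch between the exact null distribution and the normal
approximation: exact where full enumeration is cheap and valid (no ties),
asymptotic with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Exact signed-rank null up to this many non-zero differences.
SIGNED_RANK_EXACT_MAX = 25
#: Exact rank-sum null up to this many total observations.
RANK_SUM_EXACT_MAX = 50


def signed_rank_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired vectors.

    Zero differences are dropped (the wilcox convention); with no non-zero
    differences the test is vacuous and p = 1.  Exact enumeration when the
    number of non-zero differences is at most ``SIGNED_RANK_EXACT_MAX`` and
    their magnitudes are tie-free; otherwise the normal approximation with
    tie correction and 0.5 continuity correction.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ties = len(np.unique(np.abs(d))) < d.size
    if d.size <= SIGNED_RANK_EXACT_MAX and not ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.pvalue)


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact when the pooled sample is tie-free and has at most
    ``RANK_SUM_EXACT_MAX`` observations, else normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    if pooled.size <= RANK_SUM_EXACT_MAX and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def fold_change_log2(
    values_a: np.ndarray,
    values_b: np.ndarray,
    mode: str = "expm1",
) -> float:
    """log2 fold change between two log-normalized value vectors.

    ``mode="expm1"`` (default): de-log, average, pseudocount 1 —
    log2((mean(expm1(a)) + 1) / (mean(expm1(b)) + 1)), the convention of
    the standard single-cell toolkit.  ``mode="logmeans"``: difference of
    log-means, log2-rescaled.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if mode == "expm1":
        return float(np.log2((np.expm1(a).mean() + 1.0) / (np.expm1(b).mean() + 1.0)))
    if mode == "logmeans":
        return float((a.mean() - b.mean()) / np.log(2.0))
    raise ValueError(f"unknown fold-change mode {mode!r}")
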