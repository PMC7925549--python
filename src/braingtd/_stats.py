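"""Rank-sum tests with exact small-sample enumeration.

The Mann-Whitney U null distribution is enumerated exhaustively whenever
n1 + n2 <= 12 (at most C(12,6) = 924 group assignments), which handles
ties without breaking them and returns exact p-values — in particular,
identical samples give a two-sided p of exactly 1.  Larger samples fall
back to scipy's tie-corrected normal approximation.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

EXACT_MAX_N = 12


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y; ties count one half."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_p(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """P-value of the Mann-Whitney (Wilcoxon rank-sum) test.

    ``alternative="greater"`` tests whether values in ``x`` are
    stochastically greater than those in ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # degenerate: no ordering information at all

    if x.size + y.size <= EXACT_MAX_N:
        return _exact_p(x, y, alternative)

    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def _exact_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    n1 = x.size
    pooled = np.concatenate([x, y])
    n = pooled.size
    observed = _u_statistic(x, y)
    mean_u = n1 * (n - n1) / 2.0

    idx = np.arange(n)
    hits = 0
    total = 0
    for group1 in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(group1)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if alternative == "greater":
            hits += u >= observed
        elif alternative == "less":
            hits += u <= observed
        else:
            hits += abs(u - mean_u) >= abs(observed - mean_u)
    return hits / total


def median_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    return float(np.median(arr)), float(q3 - q1)


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD with n-1 denominator over sqrt n).

    SEM is NaN for a single observation.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))
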