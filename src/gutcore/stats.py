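"""Small statistical utilities: Mann-Whitney / Wilcoxon rank-sum
comparisons and the between-marker agreement regression.

The Mann-Whitney test enumerates the exact null when the pooled sample
is small (n <= 12) and tie-free, and otherwise uses the tie-corrected
normal approximation; the rank-sum variant applies the continuity
correction and reports the W statistic in the R ``wilcox.test``
convention (W equals the U statistic of the first sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    method: str


def _has_ties(x, y) -> bool:
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U test; exact enumeration for small tie-free data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = (len(x) + len(y) <= 12) and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue), method)


def rank_sum_continuity(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Wilcoxon rank-sum test with continuity correction (normal
    approximation), W reported as U of the first sample."""
    res = sps.mannwhitneyu(
        np.asarray(x, float),
        np.asarray(y, float),
        alternative=alternative,
        method="asymptotic",
        use_continuity=True,
    )
    return RankTestResult(float(res.statistic), float(res.pvalue), "asymptotic+cc")


def marker_concordance_r2(values_a, values_b) -> float:
    """Ordinary least-squares R^2 between paired per-species estimates
    from the two markers (agreement of alpha-diversity patterns)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired values for a regression")
    res = sps.linregress(a, b)
    return float(res.rvalue ** 2)
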