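"""Shared statistical primitives (Spearman with small-sample p, rank tests)."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats

__all__ = ["spearman", "ranksum_p", "EXACT_N_MAX"]

#: Largest paired-sample size for which the Spearman p-value is computed by
#: exhaustive permutation enumeration (n! grows too fast beyond this).
EXACT_N_MAX = 7


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a defined p for degenerate input.

    Ties receive average ranks.  For n <= EXACT_N_MAX the p-value is the
    exact permutation tail probability (two-sided); otherwise the asymptotic
    t-approximation.  Constant input gives (nan rho reported as 0.0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    if x.size <= EXACT_N_MAX:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = _rank_corr(rx, ry)
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.asarray(perm))) >= abs(obs) - 1e-12:
                count += 1
        return float(obs), count / total
    rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return 0.0, 1.0
    return float(rho), float(p)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def ranksum_p(a, b) -> float:
    """Two-sided rank-sum (Mann-Whitney) p; exact for combined n <= 20."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return np.nan
    method = "exact" if (a.size + b.size) <= 20 and not _has_ties(a, b) else "asymptotic"
    try:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method=method).pvalue)
    except ValueError:
        return 1.0


def _has_ties(a, b) -> bool:
    combined = np.concatenate([a, b])
    return np.unique(combined).size < combined.size
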