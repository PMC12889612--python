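"""Depth, duration and prevalence of internal-state modulation.

Depth is the discriminability index d' between Engaged and Disengaged
pulse-response areas; duration is the time until per-pulse responses on
Futile trials become statistically indistinguishable from Effective trials;
prevalence is the fraction of cells whose ΔF/F differs between conditions at
a given time.  Region-level aggregates serve as a coarse stand-in for the
brain maps, and a two-way fixed-effects ANOVA (fish identity x trial type)
provides the across-fish comparison model.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import ranksum_p, spearman
from .errors import InvalidArgumentError

__all__ = [
    "dprime",
    "modulation_duration",
    "fraction_state_dependent",
    "depth_integration_regression",
    "anova_trialtype",
    "rolling_sd",
    "lmo_gating",
    "region_summary",
]


def dprime(a, b) -> float:
    """Discriminability index ``(μ1 - μ2) / sqrt((σ1² + σ2²)/2)``.

    Sample SDs.  When both SDs are zero: 0 for equal means, signed infinity
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("need >= 2 samples per condition")
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    denom = math.sqrt((s1 ** 2 + s2 ** 2) / 2)
    diff = a.mean() - b.mean()
    if denom == 0:
        if diff == 0:
            return 0.0
        return math.copysign(math.inf, diff)
    return float(diff / denom)


def modulation_duration(
    auc_eff: list[np.ndarray],
    auc_fut: list[np.ndarray],
    pulse_times: np.ndarray,
    probe_len: float,
    alpha: float = 0.05,
) -> float:
    """Time until per-pulse responses become indistinguishable across states.

    ``auc_eff[i]`` / ``auc_fut[i]`` hold the pulse-i response areas across
    trials of each condition; ``pulse_times`` are the pulse onsets relative
    to Probe onset.  A rank-sum test is run per pulse; the duration is the
    time of the first pulse from which p >= alpha holds for *all* subsequent
    pulses (0 if that is the first pulse, ``probe_len`` if the conditions
    remain distinguishable throughout).  Returns nan with < 2 trials in
    either condition.
    """
    n = len(pulse_times)
    if len(auc_eff) != n or len(auc_fut) != n:
        raise InvalidArgumentError("per-pulse samples must match pulse_times")
    ps = np.empty(n)
    for i in range(n):
        a, b = np.asarray(auc_eff[i]), np.asarray(auc_fut[i])
        if a.size < 2 or b.size < 2:
            return math.nan
        ps[i] = ranksum_p(a, b)
    indist = ps >= alpha
    # first index from which indistinguishability is sustained
    sustained = np.flip(np.logical_and.accumulate(np.flip(indist)))
    if not sustained.any():
        return float(probe_len)
    k = int(np.argmax(sustained))
    return float(pulse_times[k])


def fraction_state_dependent(
    snap_eff: np.ndarray,
    snap_fut: np.ndarray,
    alpha: float = 0.05,
) -> float:
    """Percent of cells whose ΔF/F differs between conditions at one time.

    ``snap_eff`` / ``snap_fut`` are cells x trials snapshots at the same
    paradigm-aligned time.  Returns a percentage.
    """
    snap_eff = np.atleast_2d(snap_eff)
    snap_fut = np.atleast_2d(snap_fut)
    if snap_eff.shape[1] < 2 or snap_fut.shape[1] < 2:
        raise InvalidArgumentError("need >= 2 trials per condition")
    n_cells = snap_eff.shape[0]
    hits = sum(ranksum_p(snap_eff[c], snap_fut[c]) < alpha
               for c in range(n_cells))
    return 100.0 * hits / n_cells


def depth_integration_regression(
    region_dprime: np.ndarray,
    region_long_tau_frac: np.ndarray,
) -> tuple[float, float, float]:
    """Across-region link between modulation depth and integrator prevalence.

    Spearman correlation and OLS slope of per-region mean d' against the
    per-region fraction of sensory cells with long decay (τ > 4 s).  Returns
    ``(rho, p, slope)``; all nan with < 4 regions or constant input.
    """
    x = np.asarray(region_long_tau_frac, dtype=float)
    y = np.asarray(region_dprime, dtype=float)
    if x.size < 4 or x.size != y.size:
        return math.nan, math.nan, math.nan
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan, math.nan
    rho, p = spearman(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return rho, p, slope


def anova_trialtype(df: pd.DataFrame) -> dict[str, float]:
    """Two-way fixed-effects ANOVA: measure ~ fish + trial type + interaction.

    ``df`` needs columns ``fish``, ``trial_type``, ``measure``; every fish
    must contribute both trial types.  Returns p-values for the three terms;
    the trial-type p is the reported statistic.  A constant measure gives
    p = 1 for every term by convention.
    """
    for col in ("fish", "trial_type", "measure"):
        if col not in df.columns:
            raise InvalidArgumentError(f"missing column {col!r}")
    counts = df.groupby(["fish", "trial_type"]).size().unstack(fill_value=0)
    if counts.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 fish")
    if (counts == 0).any().any() or counts.shape[1] < 2:
        raise InvalidArgumentError(
            "rank-deficient design: every fish needs both trial types")
    if np.ptp(df["measure"].to_numpy()) == 0:
        return {"fish": 1.0, "trial_type": 1.0, "interaction": 1.0}
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    model = ols("measure ~ C(fish) + C(trial_type) + C(fish):C(trial_type)",
                data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "fish": float(table.loc["C(fish)", "PR(>F)"]),
        "trial_type": float(table.loc["C(trial_type)", "PR(>F)"]),
        "interaction": float(table.loc["C(fish):C(trial_type)", "PR(>F)"]),
    }


def rolling_sd(x: np.ndarray, fs: float, window: float = 4.0) -> np.ndarray:
    """Centered rolling standard deviation (shrunken windows at the edges)."""
    x = np.asarray(x, dtype=float)
    k = max(int(round(window * fs)), 2)
    half = k // 2
    n = x.size
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    cnt = hi - lo
    mean = (c1[hi] - c1[lo]) / cnt
    var = (c2[hi] - c2[lo]) / cnt - mean ** 2
    return np.sqrt(np.maximum(var, 0.0))


def lmo_gating(
    traces: np.ndarray,
    frame_t: np.ndarray,
    pulse_onsets,
    early_window: tuple[float, float],
    late_window: tuple[float, float],
    fs: float,
    pulse_on: float = 1.0,
    sd_window: float = 4.0,
):
    """State-dependent gating of negative pulse responses in anti-motor cells.

    For each cell (row of ``traces``) the pulse-locked response (mean over
    the pulse minus the pre-pulse frame) is averaged over pulses falling in
    the early-Probe and the late (pre-recovery) window; a paired signed-rank
    test across cells compares the two.  Also returns the 4 s rolling-SD
    trace of the cell average.  Windows must not overlap.
    """
    if early_window[1] > late_window[0] and late_window[1] > early_window[0]:
        raise InvalidArgumentError("early and late windows must not overlap")
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    onsets = np.asarray(pulse_onsets, dtype=float)

    def pulse_resp(trace: np.ndarray, t0: float) -> float:
        idx = np.flatnonzero((frame_t >= t0) & (frame_t < t0 + pulse_on))
        pre = np.flatnonzero(frame_t < t0)
        if idx.size == 0 or pre.size == 0:
            return math.nan
        return float(trace[idx].mean() - trace[pre[-1]])

    def window_mean(trace: np.ndarray, win: tuple[float, float]) -> float:
        sel = onsets[(onsets >= win[0]) & (onsets < win[1])]
        vals = [pulse_resp(trace, t0) for t0 in sel]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    early = np.array([window_mean(tr, early_window) for tr in traces])
    late = np.array([window_mean(tr, late_window) for tr in traces])
    ok = ~(np.isnan(early) | np.isnan(late))
    if ok.sum() >= 2 and np.any(early[ok] != late[ok]):
        p = float(stats.wilcoxon(early[ok], late[ok]).pvalue)
    else:
        p = math.nan
    sd_trace = rolling_sd(traces.mean(axis=0), fs, sd_window)
    return sd_trace, early, late, p


def region_summary(cells: pd.DataFrame, tau_long: float = 4.0) -> pd.DataFrame:
    """Per-region aggregates over sensory-flagged cells.

    ``cells`` needs columns ``region, dprime, tau, sensory_pos, sensory_neg``.
    Returns mean d', quartiles, and the fraction of cells with τ > 4 s per
    region (the long-decay fraction used in the depth-vs-integration link).
    """
    sens = cells[cells["sensory_pos"] | cells["sensory_neg"]]
    rows = []
    for region, grp in sens.groupby("region"):
        d = grp["dprime"].dropna()
        taus = grp["tau"].dropna()
        rows.append({
            "region": region,
            "n_cells": len(grp),
            "mean_dprime": d.mean() if len(d) else math.nan,
            "q1_dprime": d.quantile(0.25) if len(d) else math.nan,
            "q3_dprime": d.quantile(0.75) if len(d) else math.nan,
            "frac_long_tau": (taus > tau_long).mean() if len(taus) else math.nan,
        })
    return pd.DataFrame(rows)
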