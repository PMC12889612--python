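"""Functional cell classification from ΔF/F, stimulus, vigor and latencies.

Cells are classified by Spearman rank correlation: sensory cells against the
stimulus velocity over the first six Probe pulses (12 s) of non-swimming
trials, motor cells against swim vigor during open-loop Evoke (where the
stimulus is constant), and motor-preparatory cells by ramping activity in
multiple windows (3-7 s) before the probe-evoked swim.  No multiple-
comparison correction is applied at the cell level; population statistics
are meant to be computed across fish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import spearman
from .errors import InvalidArgumentError

__all__ = [
    "CellTuning",
    "frame_resample",
    "sensory_correlation",
    "motor_correlation",
    "detect_motor_prep",
    "prep_onset_time",
    "classify_cells",
    "PREP_WINDOWS",
]

PREP_WINDOWS = (3.0, 4.0, 5.0, 6.0, 7.0)


@dataclass
class CellTuning:
    """Per-cell tuning summary (one row of the tuning table)."""

    cell_id: int
    sensory_rho: float = np.nan
    sensory_p: float = np.nan
    sensory_pos: bool = False
    sensory_neg: bool = False
    motor_rho: float = np.nan
    motor_p: float = np.nan
    motor: bool = False
    motor_neg: bool = False
    motor_prep: bool = False
    prep_rho: dict | None = None


def frame_resample(series: np.ndarray, dt: float, n_frames: int,
                   fs_img: float) -> np.ndarray:
    """Within-frame mean of a behavior-grid series at the imaging frame rate."""
    series = np.asarray(series, dtype=float)
    frame_len = 1.0 / fs_img
    t = np.arange(series.size) * dt
    idx = (t // frame_len).astype(int)
    keep = idx < n_frames
    sums = np.bincount(idx[keep], weights=series[keep], minlength=n_frames)
    counts = np.bincount(idx[keep], minlength=n_frames)
    return sums / np.maximum(counts, 1)


def _frames_in(frame_t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    return np.flatnonzero((frame_t >= t0) & (frame_t < t1))


def sensory_correlation(
    dff: np.ndarray,
    frame_t: np.ndarray,
    v_stim_frames: np.ndarray,
    trials,
    probe_window: float = 12.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each cell with v_stim over early Probe.

    Uses the first ``probe_window`` seconds of the Probe epoch (the first six
    pulses) of non-swimming trials — trials whose probe-evoked swim came
    after that window — concatenated across trials.  Requires at least three
    such trials.  Flags: ``sensory_pos`` iff p < alpha and rho > 0,
    ``sensory_neg`` iff p < alpha and rho < 0.
    """
    quiet = [t for t in trials
             if t.latency is not None and t.latency > probe_window]
    if len(quiet) < 3:
        raise InvalidArgumentError(
            f"need >= 3 non-swimming trials, got {len(quiet)}")
    idx = np.concatenate([_frames_in(frame_t, t.probe_on,
                                     t.probe_on + probe_window)
                          for t in quiet])
    stim = v_stim_frames[idx]
    rows = []
    for cid in range(dff.shape[0]):
        rho, p = spearman(dff[cid, idx], stim)
        rows.append({
            "cell_id": cid, "sensory_rho": rho, "sensory_p": p,
            "sensory_pos": bool(p < alpha and rho > 0),
            "sensory_neg": bool(p < alpha and rho < 0),
        })
    return pd.DataFrame(rows)


def motor_correlation(
    dff: np.ndarray,
    frame_t: np.ndarray,
    vigor_frames: np.ndarray,
    trials,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each cell with swim vigor in open-loop Evoke.

    Restricted to frames with nonzero vigor (m > 0) inside the Evoke epoch
    of Futile (open-loop) trials, where the stimulus is constant so motor and
    sensory drive are dissociated.  Emits a positive ``motor`` flag and a
    ``motor_neg`` flag for vigor-anticorrelated (anti-motor) cells.
    """
    open_trials = [t for t in trials if t.trial_type in ("Futile", "Replay")]
    if not open_trials:
        raise InvalidArgumentError("no open-loop trials available")
    idx = np.concatenate([_frames_in(frame_t, t.evoke_on, t.evoke_off)
                          for t in open_trials])
    idx = idx[vigor_frames[idx] > 0]
    vig = vigor_frames[idx]
    rows = []
    for cid in range(dff.shape[0]):
        rho, p = spearman(dff[cid, idx], vig)
        rows.append({
            "cell_id": cid, "motor_rho": rho, "motor_p": p,
            "motor": bool(p < alpha and rho > 0),
            "motor_neg": bool(p < alpha and rho < 0),
        })
    return pd.DataFrame(rows)


def detect_motor_prep(
    dff: np.ndarray,
    frame_t: np.ndarray,
    trials,
    windows=PREP_WINDOWS,
    alpha: float = 0.05,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Detect ramping motor-preparatory cells ahead of probe-evoked swims.

    For each window length ``w`` the trace samples within ``[swim - w,
    swim)`` of every qualifying Engaged trial are concatenated and rank-
    correlated with elapsed time toward the swim, so a ramp that rises into
    the swim yields rho > 0.  A cell is flagged iff for *every* window length
    rho > 0 with p < alpha and the cell's rho is in the top ``top_frac``
    across cells.  Trials shorter than the longest window are skipped.
    """
    wmax = max(windows)
    use = [t for t in trials
           if t.label == "Engaged" and not t.censored
           and t.latency is not None and t.latency >= wmax]
    n_cells = dff.shape[0]
    rho_mat = np.zeros((n_cells, len(windows)))
    p_mat = np.ones((n_cells, len(windows)))
    if use:
        for wi, w in enumerate(windows):
            idx_list, time_list = [], []
            for t in use:
                swim_t = t.probe_on + t.latency
                ii = _frames_in(frame_t, swim_t - w, swim_t)
                idx_list.append(ii)
                time_list.append(frame_t[ii] - swim_t)  # rises toward 0
            idx = np.concatenate(idx_list)
            tt = np.concatenate(time_list)
            for cid in range(n_cells):
                rho_mat[cid, wi], p_mat[cid, wi] = spearman(dff[cid, idx], tt)
    flags = np.ones(n_cells, dtype=bool)
    for wi in range(len(windows)):
        rho_w = rho_mat[:, wi]
        cutoff = np.quantile(rho_w, 1.0 - top_frac)
        flags &= (rho_w > 0) & (p_mat[:, wi] < alpha) & (rho_w >= cutoff)
    if not use:
        flags[:] = False
    rows = []
    for cid in range(n_cells):
        row = {"cell_id": cid, "motor_prep": bool(flags[cid])}
        for wi, w in enumerate(windows):
            row[f"prep_rho_{int(w)}s"] = rho_mat[cid, wi]
        rows.append(row)
    return pd.DataFrame(rows)


def prep_onset_time(avg_trace: np.ndarray, t_rel: np.ndarray,
                    baseline: np.ndarray, n_sd: float = 2.0) -> float:
    """Time before the swim at which preparatory activity starts to rise.

    ``avg_trace`` is the swim-aligned trial average at times ``t_rel``
    (negative, ending at the swim).  The onset is the earliest time of the
    final sustained excursion above baseline mean + ``n_sd`` baseline SD,
    returned as seconds before the swim (positive).  Returns nan when the
    trace never exceeds the threshold.
    """
    avg_trace = np.asarray(avg_trace, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    thr = baseline.mean() + n_sd * baseline.std(ddof=1 if baseline.size > 1 else 0)
    above = avg_trace > thr
    if not above.any() or not above[-1]:
        return math.nan
    # walk back from the swim through the contiguous supra-threshold run
    i = above.size - 1
    while i > 0 and above[i - 1]:
        i -= 1
    return float(-t_rel[i])


def classify_cells(
    dff: np.ndarray,
    frame_t: np.ndarray,
    v_stim_frames: np.ndarray,
    vigor_frames: np.ndarray,
    trials,
    alpha: float = 0.05,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Run all three classifiers and merge into one tuning table."""
    sens = sensory_correlation(dff, frame_t, v_stim_frames, trials, alpha=alpha)
    mot = motor_correlation(dff, frame_t, vigor_frames, trials, alpha=alpha)
    prep = detect_motor_prep(dff, frame_t, trials, alpha=alpha,
                             top_frac=top_frac)
    out = sens.merge(mot, on="cell_id").merge(prep, on="cell_id")
    return out
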