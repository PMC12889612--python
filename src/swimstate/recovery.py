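"""Dual-aligned time warping, progressive amplification, latency decoding.

Trials end at variable times (the probe-evoked swim), so trial averaging
uses a dual alignment: a left segment aligned to Probe onset, a right
segment aligned to the last pulse before the swim, and a middle segment
linearly resampled to a fixed number of scaled-time-unit (STU) bins.

Pulse responses grow in the lead-up to the behavioral response; a gradient-
boosted regression decoder trained per condition on half of the trials
predicts the remaining latency from single-pulse responses of behavior-
predictive cells (those whose pulse response anticorrelates with the
latency remaining from that pulse).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import spearman
from .errors import InvalidArgumentError

__all__ = [
    "WarpedTrialMatrix",
    "DecoderResult",
    "time_warp_align",
    "progressive_amplification",
    "select_behavior_predictive",
    "decode_latency",
]


@dataclass
class WarpedTrialMatrix:
    """Dual-aligned trial stack: left / middle (STU bins) / right segments."""

    left: np.ndarray      # trials x n_left frames (from Probe onset)
    middle: np.ndarray    # trials x n_stu warped bins
    right: np.ndarray     # trials x n_right frames (to last pulse before swim)
    trial_ids: list[int]

    def mean(self) -> np.ndarray:
        return np.concatenate([
            self.left.mean(axis=0), self.middle.mean(axis=0),
            self.right.mean(axis=0),
        ])


@dataclass
class DecoderResult:
    """Per-trial latency predictions and per-condition rank correlations."""

    predictions: pd.DataFrame      # trial_id, condition, predicted_s, actual_s
    rank_corr: dict[str, float]    # condition -> Spearman rho (test set)


def time_warp_align(
    traces: dict[int, np.ndarray],
    frame_t: np.ndarray,
    probe_on: dict[int, float],
    right_anchor: dict[int, float],
    left_len: float,
    right_len: float,
    n_stu: int = 20,
    fs: float = 3.0,
) -> WarpedTrialMatrix:
    """Dual-align trials of unequal duration.

    Per trial: ``left_len`` seconds of frames from Probe onset are copied
    verbatim, ``right_len`` seconds ending at the right anchor (the last
    pulse before the probe-evoked swim) are copied verbatim, and the frames
    in between are linearly resampled to ``n_stu`` bins.  Trials whose
    middle segment is empty are excluded with a warning.  ``traces`` maps
    trial_id to the full-session trace of one cell (or a population
    average).
    """
    n_left = int(round(left_len * fs))
    n_right = int(round(right_len * fs))
    lefts, mids, rights, ids = [], [], [], []
    for tid, trace in traces.items():
        t0 = probe_on[tid]
        t1 = right_anchor[tid]
        li = np.flatnonzero((frame_t >= t0))[:n_left]
        ri = np.flatnonzero(frame_t < t1)[-n_right:] if n_right else np.array([], int)
        if li.size < n_left or ri.size < n_right or (
                ri.size and li.size and ri[0] <= li[-1]):
            warnings.warn(f"trial {tid} too short for dual alignment; excluded",
                          stacklevel=2)
            continue
        mi = np.arange(li[-1] + 1, ri[0]) if n_right else np.arange(li[-1] + 1, trace.size)
        if mi.size == 0:
            warnings.warn(f"trial {tid} has an empty middle segment; excluded",
                          stacklevel=2)
            continue
        seg = trace[mi]
        if seg.size == n_stu:
            warped = seg.astype(float)
        else:
            src = np.linspace(0.0, 1.0, seg.size)
            dst = np.linspace(0.0, 1.0, n_stu)
            warped = np.interp(dst, src, seg)
        lefts.append(trace[li])
        mids.append(warped)
        rights.append(trace[ri])
        ids.append(tid)
    if not ids:
        raise InvalidArgumentError("no trial survived dual alignment")
    return WarpedTrialMatrix(
        left=np.vstack(lefts), middle=np.vstack(mids),
        right=np.vstack(rights), trial_ids=ids,
    )


def progressive_amplification(
    pulse_aucs: pd.DataFrame,
    max_index: int = 8,
) -> pd.DataFrame:
    """Mean ± SEM pulse response as a function of pulses-before-swim.

    ``pulse_aucs`` needs columns ``condition, trial_id, rel_index, auc``
    where ``rel_index`` is the (negative) pulse number relative to the
    probe-evoked swim (-1 = last pulse before the swim).  Returns one row
    per (condition, rel_index); SEM is nan for a single trial.
    """
    req = {"condition", "trial_id", "rel_index", "auc"}
    if not req.issubset(pulse_aucs.columns):
        raise InvalidArgumentError(f"need columns {sorted(req)}")
    sel = pulse_aucs[pulse_aucs["rel_index"].between(-max_index, -1)]
    rows = []
    for (cond, ridx), grp in sel.groupby(["condition", "rel_index"]):
        vals = grp["auc"].to_numpy()
        rows.append({
            "condition": cond, "rel_index": int(ridx),
            "mean_auc": float(vals.mean()),
            "sem_auc": float(vals.std(ddof=1) / math.sqrt(vals.size))
            if vals.size > 1 else math.nan,
            "n_trials": vals.size,
        })
    return pd.DataFrame(rows).sort_values(["condition", "rel_index"],
                                          ignore_index=True)


def select_behavior_predictive(
    pulse_resp: np.ndarray,
    latency_from_pulse: np.ndarray,
    alpha: float = 0.05,
) -> tuple[bool, float, float]:
    """Behavior-predictive selection for one cell.

    ``pulse_resp[k]`` is the cell's response to pulse k and
    ``latency_from_pulse[k]`` the time remaining from that pulse to the
    probe-evoked swim.  Predictive cells respond more strongly the closer
    the swim: rho < 0 with p < alpha.
    """
    rho, p = spearman(pulse_resp, latency_from_pulse)
    return bool(rho < 0 and p < alpha), rho, p


def decode_latency(
    features: pd.DataFrame,
    seed: int = 0,
    min_trials: int = 4,
) -> DecoderResult | None:
    """Decode the remaining latency to the probe-evoked swim per condition.

    ``features`` needs columns ``condition, trial_id, latency_s`` plus one
    column per predictive cell (the cell's response to the chosen pulse).
    Per condition the trials are split in half at random (seeded,
    stratified by condition), a gradient-boosted regression ensemble with
    the host library's default hyperparameters is fit on one half, and
    test-set predictions are rank-correlated with the actual latencies.
    Conditions with fewer than ``min_trials`` trials are skipped with a
    warning; returns None if no condition qualifies.
    """
    from sklearn.ensemble import GradientBoostingRegressor

    meta = {"condition", "trial_id", "latency_s"}
    feat_cols = [c for c in features.columns if c not in meta]
    if not feat_cols:
        raise InvalidArgumentError("no feature columns")
    rng = np.random.default_rng(seed)
    preds = []
    rank_corr: dict[str, float] = {}
    for cond, grp in features.groupby("condition"):
        if len(grp) < min_trials:
            warnings.warn(f"condition {cond!r}: only {len(grp)} trials; skipped",
                          stacklevel=2)
            continue
        order = rng.permutation(len(grp))
        half = len(grp) // 2
        train = grp.iloc[order[:half]]
        test = grp.iloc[order[half:]]
        model = GradientBoostingRegressor(random_state=int(rng.integers(2 ** 31)))
        model.fit(train[feat_cols].to_numpy(), train["latency_s"].to_numpy())
        yhat = model.predict(test[feat_cols].to_numpy())
        rho, _ = spearman(yhat, test["latency_s"].to_numpy())
        rank_corr[str(cond)] = rho
        for tid, pred, actual in zip(test["trial_id"], yhat, test["latency_s"]):
            preds.append({"trial_id": tid, "condition": cond,
                          "predicted_s": float(pred), "actual_s": float(actual)})
    if not preds:
        return None
    return DecoderResult(predictions=pd.DataFrame(preds), rank_corr=rank_corr)
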