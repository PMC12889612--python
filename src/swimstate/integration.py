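"""Leaky-integrator fits, inverse leakiness and pulse-response areas.

The core model is ``ΔF/F(t) = β ∫ v_flow(t - t') exp(-t'/τ) dt'``: a leaky
integration of stimulus velocity with memory time constant τ.  β has a
closed-form least-squares solution for each τ, so fitting reduces to a 1-D
search over τ (log-spaced grid plus golden-section refinement).  The fast
calcium indicator (~0.5 s decay) is deliberately ignored: its kinetics are
short relative to every τ of interest.

Inverse leakiness compares the response retained after six stimulus pulses
with the perfect-integrator prediction (sum of the six incremental pulse
responses): 1 for a perfect integrator, 0 for a memoryless responder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, InvalidArgumentError
from .synthetic import leaky_integrate

__all__ = [
    "IntegrationFit",
    "fit_leaky_integrator",
    "pulse_endpoints",
    "inverse_leakiness",
    "pulse_response_auc",
    "pulse_integration_auc",
    "estimate_pulse_template",
]

TAU_GRID = np.logspace(np.log10(0.1), np.log10(100.0), 64)


@dataclass
class IntegrationFit:
    """Result of a leaky-integrator fit."""

    beta: float
    tau: float
    sse: float
    converged: bool


def _beta_sse(trace: np.ndarray, integ: np.ndarray) -> tuple[float, float]:
    denom = float(integ @ integ)
    if denom <= 0:
        return 0.0, float(trace @ trace)
    beta = float(trace @ integ) / denom
    resid = trace - beta * integ
    return beta, float(resid @ resid)


def fit_leaky_integrator(
    trace: np.ndarray,
    v_flow: np.ndarray,
    fs: float,
    tau_grid: np.ndarray = TAU_GRID,
    refine: bool = True,
) -> IntegrationFit:
    """Fit β and τ of the leaky-integration model to one trace.

    ``trace`` must be baseline-subtracted and sampled at ``fs`` on the same
    clock as ``v_flow``.  β is solved in closed form for each τ on the grid;
    the grid optimum is refined by golden-section search on log τ between its
    neighbours.  The discrete integral uses exact exponential-hold updates,
    so a trace generated by the same recursion is recovered exactly.
    """
    trace = np.asarray(trace, dtype=float)
    v_flow = np.asarray(v_flow, dtype=float)
    if trace.shape != v_flow.shape:
        raise InvalidArgumentError("trace and v_flow must share a time base")
    if not np.any(trace):
        return IntegrationFit(beta=0.0, tau=math.nan, sse=0.0, converged=False)
    dt = 1.0 / fs

    def objective(log_tau: float) -> tuple[float, float]:
        integ = leaky_integrate(v_flow, math.exp(log_tau), dt)
        return _beta_sse(trace, integ)

    sses = np.empty(tau_grid.size)
    betas = np.empty(tau_grid.size)
    for i, tau in enumerate(tau_grid):
        betas[i], sses[i] = objective(math.log(tau))
    k = int(np.argmin(sses))
    tau_best, beta_best, sse_best = tau_grid[k], betas[k], sses[k]

    if refine and 0 < k < tau_grid.size - 1:
        lo, hi = math.log(tau_grid[k - 1]), math.log(tau_grid[k + 1])
        invphi = (math.sqrt(5) - 1) / 2
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = objective(c)[1], objective(d)[1]
        for _ in range(40):
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = objective(c)[1]
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = objective(d)[1]
        log_tau = (a + b) / 2
        beta_r, sse_r = objective(log_tau)
        if sse_r <= sse_best:
            tau_best, beta_best, sse_best = math.exp(log_tau), beta_r, sse_r
    return IntegrationFit(beta=beta_best, tau=float(tau_best),
                          sse=sse_best, converged=True)


def pulse_endpoints(
    trace: np.ndarray,
    frame_t: np.ndarray,
    pulse_onsets,
    pulse_on: float = 1.0,
    pulse_off: float = 1.0,
    n_pulses: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F at the last frame of each pulse-ON and pulse-OFF interval.

    Returns ``(on, off)`` where ``on[i-1]`` is the value at the last frame in
    the i-th ON interval and ``off[i]`` at the last frame of the i-th OFF
    interval, for i = 1..n_pulses; ``off[0]`` is the pre-first-pulse value.
    Intervals are half-open ``[start, end)``.
    """
    trace = np.asarray(trace, dtype=float)
    frame_t = np.asarray(frame_t, dtype=float)
    onsets = np.asarray(pulse_onsets, dtype=float)[:n_pulses]
    if onsets.size < n_pulses:
        raise FormatError(f"need {n_pulses} pulses, got {onsets.size}")
    frame_dt = np.median(np.diff(frame_t))
    if pulse_on < frame_dt or pulse_off < frame_dt:
        raise FormatError("pulse shorter than one imaging frame")
    on = np.empty(n_pulses)
    off = np.empty(n_pulses + 1)
    pre = np.flatnonzero(frame_t < onsets[0])
    off[0] = trace[pre[-1]] if pre.size else 0.0
    for i, t0 in enumerate(onsets):
        ion = np.flatnonzero((frame_t >= t0) & (frame_t < t0 + pulse_on))
        ioff = np.flatnonzero((frame_t >= t0 + pulse_on)
                              & (frame_t < t0 + pulse_on + pulse_off))
        if ion.size == 0 or ioff.size == 0:
            raise FormatError(f"pulse {i + 1} interval contains no frame")
        on[i] = trace[ion[-1]]
        off[i + 1] = trace[ioff[-1]]
    return on, off


def inverse_leakiness(on: np.ndarray, off: np.ndarray,
                      eps: float = 1e-9) -> float:
    """Accumulated response after six pulses relative to perfect integration.

    ``off[6] / Σ_{i=1..6} (on[i-1] - off[i-1])`` — 1 for a perfect-integrator
    staircase, 0 for a memoryless responder.  Returns nan when the perfect-
    integrator denominator is not positive (cell excluded from summaries).
    """
    on = np.asarray(on, dtype=float)
    off = np.asarray(off, dtype=float)
    if on.size < 6 or off.size < 7:
        raise InvalidArgumentError("need endpoints for pulses 1..6 and off[0]")
    denom = float(np.sum(on[:6] - off[:6]))
    if denom <= eps:
        return math.nan
    return float(off[6] / denom)


def pulse_response_auc(
    trace: np.ndarray,
    frame_t: np.ndarray,
    onset: float,
    window: float = 2.0,
    baseline: float = 0.0,
) -> float:
    """Trapezoidal area of the baseline-subtracted trace over one pulse.

    Integrates from ``onset`` over ``window`` seconds (default one pulse
    period).  A window running past the trace end is truncated with a
    warning.
    """
    trace = np.asarray(trace, dtype=float)
    frame_t = np.asarray(frame_t, dtype=float)
    if onset + window > frame_t[-1] + 1e-9:
        warnings.warn("AUC window exceeds trace; truncating", stacklevel=2)
    idx = np.flatnonzero((frame_t >= onset) & (frame_t <= onset + window))
    if idx.size < 2:
        return 0.0
    return float(np.trapezoid(trace[idx] - baseline, frame_t[idx]))


def estimate_pulse_template(
    traces: np.ndarray,
    frame_t: np.ndarray,
    first_pulse_onsets,
    period: float = 2.0,
) -> np.ndarray:
    """Single-pulse response template from trial-averaged first pulses.

    For each trial the trace segment over one pulse period from the first
    Probe pulse is extracted and baseline-subtracted (value just before the
    pulse); segments are truncated to the common length and averaged.
    """
    segs = []
    for t0 in first_pulse_onsets:
        idx = np.flatnonzero((frame_t >= t0) & (frame_t < t0 + period))
        if idx.size == 0:
            continue
        pre = np.flatnonzero(frame_t < t0)
        base = traces[pre[-1]] if pre.size else 0.0
        segs.append(traces[idx] - base)
    if not segs:
        raise InvalidArgumentError("no usable first-pulse segments")
    n = min(len(s) for s in segs)
    return np.mean([s[:n] for s in segs], axis=0)


def pulse_integration_auc(
    trace: np.ndarray,
    frame_t: np.ndarray,
    pulse_onsets,
    template: np.ndarray,
    period: float = 2.0,
    n_pulses: int = 6,
) -> float:
    """Baseline-accumulation area after removing the single-pulse response.

    The time-locked ``template`` is subtracted at each of the first
    ``n_pulses`` pulse onsets and the residual is trapezoid-integrated over
    the first ``n_pulses`` pulse periods.  A memoryless cell whose every
    pulse response equals the template yields ~0; a perfect integrator
    retains the accumulated staircase.
    """
    trace = np.asarray(trace, dtype=float).copy()
    frame_t = np.asarray(frame_t, dtype=float)
    template = np.asarray(template, dtype=float)
    onsets = np.asarray(pulse_onsets, dtype=float)[:n_pulses]
    if onsets.size < n_pulses:
        raise FormatError(f"need {n_pulses} pulses, got {onsets.size}")
    frame_dt = np.median(np.diff(frame_t))
    if template.size * frame_dt > period + frame_dt:
        raise FormatError("template longer than one pulse period")
    for t0 in onsets:
        idx = np.flatnonzero((frame_t >= t0) & (frame_t < t0 + period))
        m = min(idx.size, template.size)
        trace[idx[:m]] -= template[:m]
    t_end = onsets[0] + n_pulses * period
    idx = np.flatnonzero((frame_t >= onsets[0]) & (frame_t <= t_end))
    if idx.size < 2:
        return 0.0
    return float(np.trapezoid(trace[idx], frame_t[idx]))
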