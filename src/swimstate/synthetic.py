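"""Synthetic closed-loop virtual-reality sessions for larval zebrafish.

This module generates complete sessions — fictive behavior, visual stimulus,
a latent internal-state variable, and a cells x frames ΔF/F matrix — with the
statistical structure the downstream analyses assume.

The behavioral paradigm alternates two trial types.  On Effective trials the
fish swims in closed loop (motosensory gain ``G_ms > 0``) during the Evoke
epoch, so swimming produces visual feedback.  On Futile trials the Evoke epoch
is open loop (``G_ms = 0``): swimming is futile, a latent state variable ``s``
rises with each futile bout, and once ``s`` crosses a threshold the agent
becomes passive.  Five seconds of detected quiescence trigger a 3 s Pause
(8 s on Effective trials, equalizing pre-Probe quiescence at 8 s on both
types).  The Probe epoch then presents 1 s forward-motion pulses alternating
with 1 s gaps; the agent leakily integrates the stimulus with a
state-dependent time constant and swims when the integral crosses a bound,
so high-state (Futile) trials show longer latencies.

The stimulus obeys the closed-loop rule ``v_stim = v_flow - m * G_ms`` where
``m`` is swim vigor.

Neural populations: sensory-positive, sensory-negative, leaky-integrator
(state-dependent tau), motor-preparatory, motor-related, anti-motor gated
(L-MO-like) and unstructured noise cells.  Latent rates are convolved with a
fast calcium-indicator kernel (~0.5 s decay) and downsampled to the imaging
rate.

Manipulation modes: ``calex`` clamps the state variable at zero (calcium
extrusion); ``trpv1`` forces the state high during the second half of the
session irrespective of behavior (chemogenetic activation), with all trials
run in closed loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ConfigError, InvalidArgumentError
from .trials import TrialRecord

__all__ = [
    "ParadigmConfig",
    "PopulationConfig",
    "StateParams",
    "StateTrace",
    "EphysTrace",
    "Bout",
    "GroundTruth",
    "Session",
    "CELL_CLASSES",
    "closed_loop_step",
    "astro_state_step",
    "simulate_swim_agent",
    "synth_ephys",
    "synth_population",
    "indicator_kernel",
    "adapt_drive",
    "simulate_session",
]

CELL_CLASSES = (
    "sensory_pos",
    "sensory_neg",
    "integrator",
    "motor_prep",
    "motor",
    "anti_motor",
    "noise",
)

#: Brain regions used as labels for the coarse "brain map" stand-in, with the
#: target fraction of integrator cells among each region's sensory population.
SENSORY_REGION_INTEGRATOR_FRAC = {
    "TNR": 0.10,
    "PT": 0.20,
    "DRN": 0.35,
    "IPN": 0.50,
    "Cb": 0.65,
    "IO": 0.80,
}

_CLASS_REGIONS = {
    "sensory_neg": ("TNR", "PT"),
    "motor_prep": ("vMH", "vHB"),
    "motor": ("MO", "Cb"),
    "anti_motor": ("L-MO",),
    "noise": ("TNR", "PT", "Cb", "IO", "Hb", "DCH", "MO", "vMH"),
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ParadigmConfig:
    """Trial-structure parameters of the virtual-reality paradigm.

    Durations are seconds.  ``v_flow_probe`` defaults to ``v_flow_evoke``
    divided by 2.5 (the Probe pulses are slower than the Evoke flow so the
    behavioral response is delayed and integration can be observed).
    ``pause_futile + passivity_window`` must equal ``pause_effective`` so
    pre-Probe quiescence is 8 s on both trial types.
    """

    v_flow_evoke: float = 10.0          # mm/s
    v_flow_probe: float | None = None   # mm/s; default v_flow_evoke / 2.5
    g_ms: float = 2.0                   # mm/s per vigor unit (closed loop)
    pulse_on: float = 1.0               # s
    pulse_off: float = 1.0              # s
    pause_effective: float = 8.0        # s
    pause_futile: float = 3.0           # s
    passivity_window: float = 5.0       # s, online no-swim detection window
    probe_cap: float = 60.0             # s, Probe truncation
    n_trials: int = 20
    isi_engaged_max: float = 3.0        # s, max inter-swim interval when engaged
    evoke_effective: float = 13.0       # s, closed-loop Evoke duration
    evoke_futile_max: float | None = None  # s, open-loop swim timeout; default
                                        # evoke_effective - passivity_window so
                                        # a timed-out open-loop Evoke matches
                                        # the closed-loop Evoke duration
    iti: float = 3.0                    # s, inter-trial interval
    dt: float = 0.1                     # s, behavior integration step

    def __post_init__(self) -> None:
        if self.v_flow_probe is None:
            self.v_flow_probe = self.v_flow_evoke / 2.5
        self.validate()

    def validate(self) -> None:
        durations = (
            self.pulse_on, self.pulse_off, self.pause_effective,
            self.pause_futile, self.passivity_window, self.probe_cap,
            self.isi_engaged_max, self.evoke_effective, self.iti, self.dt,
        )
        if (self.evoke_futile_max is None
                and self.evoke_effective <= self.passivity_window):
            raise ConfigError(
                "evoke_effective must exceed passivity_window")
        if any(not np.isfinite(d) or d <= 0 for d in durations):
            raise ConfigError("all paradigm durations must be finite and > 0")
        if not math.isclose(self.pause_futile + self.passivity_window,
                            self.pause_effective, rel_tol=1e-9):
            raise ConfigError(
                "quiescence equalization requires pause_futile + "
                "passivity_window == pause_effective"
            )
        if self.probe_cap < self.pulse_on + self.pulse_off:
            raise ConfigError("probe_cap must cover at least one pulse period")
        if self.n_trials < 0:
            raise ConfigError("n_trials must be >= 0")


@dataclass
class StateParams:
    """Latent internal-state dynamics and the behaving agent's decision rule.

    The state ``s`` is a first-order leaky integrator of futile swim vigor
    (decay ``tau_a``, gain ``gain_k``).  Passivity begins when ``s`` crosses
    ``s_passive``.  During Probe the agent accumulates evidence with a
    state-dependent time constant interpolating ``tau_engaged`` (s = 0) to
    ``tau_disengaged`` (s = 1) and swims when the integral crosses a
    per-trial log-normal bound; bound and noise were calibrated so default
    latencies bracket 21.8 s (Effective) / 31.5 s (Futile).
    """

    tau_a: float = 150.0         # s, passive state decay (quiescence)
    tau_clear: float = 3.0       # s, active clearing by effective swimming
    res_delay: float = 10.0      # s, minimum time to spontaneous resolution
    res_mean: float = 12.0       # s, mean extra (exponential) resolution time
    tau_res: float = 3.0         # s, state decay once resolution has begun
    gain_k: float = 0.22         # state increment per unit futile vigor-second
    s_passive: float = 0.72      # passivity threshold on s
    tau_engaged: float = 11.2    # s, agent integration tau at s = 0
    tau_disengaged: float = 5.9  # s, agent integration tau at s = 1
    bound: float = 21.0          # evidence bound (mm)
    bound_sigma: float = 0.10    # log-normal sigma of the per-trial bound
    evidence_sigma: float = 2.0  # diffusion noise of the evidence (mm/sqrt(s))
    mode: str = "normal"         # normal | calex | trpv1
    trpv1_force: float = 0.9     # forced s level in trpv1 mode
    trpv1_start_frac: float = 0.5  # fraction of session after which s is forced

    def __post_init__(self) -> None:
        if self.tau_a <= 0 or self.tau_engaged <= 0 or self.tau_disengaged <= 0:
            raise ConfigError("state/integration time constants must be > 0")
        if self.mode not in ("normal", "calex", "trpv1"):
            raise ConfigError(f"unknown mode {self.mode!r}")


@dataclass
class PopulationConfig:
    """Neural-population forward-model parameters.

    Effect sizes default to the reported state-modulation depths: sensory
    responses 17% lower in the disengaged state, integrator output 87% lower,
    negative sensory responses 82% lower; integration time constants
    interpolate 11.2 s (engaged) to 5.9 s (disengaged); motor-preparatory
    ramps lead swim onset by ~3 s; indicator decay ~0.5 s.
    """

    n_total: int = 200
    n_cells: dict[str, int] | None = None
    tau_engaged: float = 11.2        # s
    tau_disengaged: float = 5.9      # s
    sensory_depth: float = 0.17      # fractional sensory suppression at s = 1
    integration_suppression: float = 0.87
    negative_suppression: float = 0.82
    prep_ramp_lead: float = 3.0      # s before swim onset
    frac_sensory_pos: float = 0.11
    frac_sensory_neg: float = 0.03
    indicator_decay: float = 0.5     # s
    indicator_rise: float = 0.05     # s
    noise_sd: float = 0.05           # ΔF/F units
    recovery_amp: float = 0.8        # fractional response gain before the
    recovery_amp_tau: float = 5.0    # probe-evoked swim (timescale, s)
    adapt_tau: float = 4.0           # s, adaptation depletion time constant
    adapt_recovery: float = 1.0      # s, adaptation recovery time constant
    adapt_depth: float = 0.9         # fractional adaptation of sustained drive
    fs_img: float = 3.0              # Hz
    mode: str = "normal"             # normal | calex | trpv1
    gain_sigma: float = 0.15         # log-normal sigma of per-cell gain
    indicator_on: bool = True

    def __post_init__(self) -> None:
        for name in ("sensory_depth", "integration_suppression",
                     "negative_suppression", "frac_sensory_pos",
                     "frac_sensory_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.tau_engaged <= 0 or self.tau_disengaged <= 0:
            raise ConfigError("tau values must be > 0")
        if self.fs_img not in (2, 3, 2.0, 3.0):
            raise ConfigError("fs_img must be 2 or 3 Hz")
        if self.mode not in ("normal", "calex", "trpv1"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_cells is None:
            n = self.n_total
            n_sp = round(self.frac_sensory_pos * n)
            n_sn = round(self.frac_sensory_neg * n)
            n_int = round(0.11 * n)
            n_prep = round(0.04 * n)
            n_mot = round(0.15 * n)
            n_anti = round(0.06 * n)
            n_noise = n - (n_sp + n_sn + n_int + n_prep + n_mot + n_anti)
            self.n_cells = {
                "sensory_pos": n_sp, "sensory_neg": n_sn,
                "integrator": n_int, "motor_prep": n_prep,
                "motor": n_mot, "anti_motor": n_anti, "noise": n_noise,
            }
        unknown = set(self.n_cells) - set(CELL_CLASSES)
        if unknown:
            raise InvalidArgumentError(f"unknown cell class(es): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Small value types
# ---------------------------------------------------------------------------

@dataclass
class Bout:
    """One swim bout in session time (seconds)."""

    onset: float
    offset: float
    vigor: float = 1.0

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise InvalidArgumentError("bout offset must exceed onset")


@dataclass
class EphysTrace:
    """Ventral-root-like voltage trace."""

    y: np.ndarray
    fs: float = 6000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise InvalidArgumentError("ephys samples must be finite")
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be > 0")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.y.size) / self.fs


@dataclass
class StateTrace:
    """Latent internal-state trajectory ``s(t)`` on the behavior grid."""

    t: np.ndarray
    s: np.ndarray
    tau_a: float
    gain_k: float

    def __post_init__(self) -> None:
        if np.any(self.s < 0):
            raise InvalidArgumentError("state must be non-negative")


@dataclass
class GroundTruth:
    """Generator-side truth used by oracle tests; never consumed by analyses."""

    bouts: list[Bout]
    cell_class: np.ndarray          # str per cell
    cell_gain: np.ndarray           # per-cell amplitude scale
    s: np.ndarray                   # latent state on the behavior grid
    trial_types: list[str]
    latencies: np.ndarray           # true latency per trial (s, capped)
    censored: np.ndarray            # bool per trial


@dataclass
class Session:
    """One complete synthetic session (all arrays share the session clock)."""

    t: np.ndarray                   # behavior grid (s)
    dt: float
    v_stim: np.ndarray
    v_flow: np.ndarray
    vigor: np.ndarray               # agent vigor m(t) on the behavior grid
    state: StateTrace
    bouts: list[Bout]
    trials: list[TrialRecord]
    ephys: EphysTrace
    dff: np.ndarray                 # cells x frames
    frame_t: np.ndarray             # frame-center times (s)
    fs_img: float
    regions: np.ndarray             # str per cell
    truth: GroundTruth
    paradigm: ParadigmConfig
    state_params: StateParams
    population: PopulationConfig
    seed: int

    def config_json(self) -> str:
        def _clean(d: dict) -> dict:
            return {k: v for k, v in d.items()}
        return json.dumps({
            "paradigm": _clean(asdict(self.paradigm)),
            "state": _clean(asdict(self.state_params)),
            "population": _clean(asdict(self.population)),
            "seed": self.seed,
        })


# ---------------------------------------------------------------------------
# Elementary steps
# ---------------------------------------------------------------------------

def closed_loop_step(v_flow: float, m: float, g_ms: float) -> float:
    """Closed-loop stimulus update: ``v_stim = v_flow - m * G_ms``.

    With ``g_ms = 0`` the environment is open loop and swimming leaves the
    stimulus unchanged.
    """
    if not (np.isfinite(v_flow) and np.isfinite(m) and np.isfinite(g_ms)):
        raise InvalidArgumentError("closed_loop_step requires finite inputs")
    if m < 0:
        raise InvalidArgumentError("vigor must be non-negative")
    return v_flow - m * g_ms


def astro_state_step(s: float, m: float, futile: bool, dt: float,
                     tau_a: float, gain_k: float, mode: str = "normal",
                     tau_clear: float | None = None) -> float:
    """One Euler-exponential step of the latent state.

    ``s' = s * exp(-dt/tau_a) + gain_k * m * dt`` while swimming futilely,
    pure exponential decay otherwise.  Effective (non-futile) swimming
    actively clears the state with the faster ``tau_clear`` when given,
    mirroring the return of the astrocytic signal to baseline upon
    behavioral recovery.  In ``calex`` mode the state is clamped at zero
    (calcium extrusion).
    """
    if tau_a <= 0:
        raise InvalidArgumentError("tau_a must be > 0")
    if dt <= 0:
        raise InvalidArgumentError("dt must be > 0")
    if s < 0:
        raise InvalidArgumentError("state must be non-negative")
    if mode == "calex":
        return 0.0
    if not futile and m > 0 and tau_clear is not None:
        return s * math.exp(-dt / tau_clear)
    out = s * math.exp(-dt / tau_a)
    if futile and m > 0:
        out += gain_k * m * dt
    return out


def _state_tau(s: float, tau_engaged: float, tau_disengaged: float) -> float:
    """Linear interpolation of the integration time constant in s."""
    sc = min(max(s, 0.0), 1.0)
    return tau_engaged + (tau_disengaged - tau_engaged) * sc


# ---------------------------------------------------------------------------
# Behaving agent
# ---------------------------------------------------------------------------

def _draw_bout(rng: np.random.Generator) -> tuple[float, float]:
    """(duration, vigor) of one swim bout."""
    dur = 0.35 + 0.3 * rng.random()
    vigor = float(np.exp(rng.normal(0.0, 0.2)))
    return dur, vigor


def _draw_gap(rng: np.random.Generator, isi_max: float,
              floor: float = 0.5) -> float:
    """Inter-bout gap for an engaged fish; log-normal, kept under isi_max.

    The floor keeps consecutive bouts resolvable by the envelope detector
    (smoothing on the 100 ms scale plus the 200 ms merge rule).
    """
    gap = float(np.exp(rng.normal(math.log(0.8), 0.3)))
    return min(max(gap, floor), 0.9 * isi_max)


def simulate_swim_agent(
    paradigm: ParadigmConfig,
    state_params: StateParams | None = None,
    seed: int = 0,
):
    """Simulate the behaving agent through ``n_trials`` alternating trials.

    Returns ``(bouts, v_stim, v_flow, vigor, trials, state_trace)`` where the
    series live on a uniform grid of step ``paradigm.dt`` and ``trials`` is a
    list of :class:`~swimstate.trials.TrialRecord` carrying true epoch
    boundaries and latencies.

    In closed loop the agent swims regularly (inter-swim interval under
    ``isi_engaged_max``); in open loop passivity begins once the latent state
    crosses ``s_passive``; a probe-evoked swim occurs when the leaky integral
    of ``v_stim`` (state-dependent tau) crosses a noisy bound, truncated at
    ``probe_cap``.
    """
    sp = state_params or StateParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    dt = paradigm.dt

    # Event lists built in continuous time, then rasterized once at the end.
    bouts: list[Bout] = []
    trials: list[TrialRecord] = []
    segs: list[tuple[float, float, float, float]] = []  # (t_on, t_off, v_flow, g_ms)

    trpv1 = sp.mode == "trpv1"
    # crude session-length estimate to place the trpv1 forcing window
    est_trial = (paradigm.evoke_effective + paradigm.pause_effective
                 + 30.0 + paradigm.iti)
    trpv1_t0 = sp.trpv1_start_frac * paradigm.n_trials * est_trial

    s = 0.0
    t = 0.0
    s_events: list[tuple[float, float]] = [(0.0, 0.0)]  # (time, value) checkpoints

    def step_state(t_now: float, duration: float, m: float, futile: bool) -> float:
        """Advance s over `duration` with constant vigor m; log checkpoints."""
        nonlocal s
        n = max(1, int(round(duration / dt)))
        for k in range(n):
            forced = trpv1 and (t_now + k * dt) >= trpv1_t0
            if forced:
                s = sp.trpv1_force
            else:
                s = astro_state_step(s, m, futile, dt, sp.tau_a, sp.gain_k,
                                     mode=sp.mode, tau_clear=sp.tau_clear)
            s_events.append((t_now + (k + 1) * dt, s))
        return t_now + n * dt

    for trial_id in range(paradigm.n_trials):
        trial_type = "Effective" if (trial_id % 2 == 0 or trpv1) else "Futile"
        open_loop = trial_type == "Futile"
        g_evoke = 0.0 if open_loop else paradigm.g_ms

        evoke_on = t
        # --- Evoke epoch ---
        if not open_loop:
            evoke_off = evoke_on + paradigm.evoke_effective
            segs.append((evoke_on, evoke_off, paradigm.v_flow_evoke, g_evoke))
            while True:
                dur, vig = _draw_bout(rng)
                if t + dur > evoke_off - 0.1:
                    break
                bouts.append(Bout(t, t + dur, vig))
                t = step_state(t, dur, vig, futile=False)
                gap = _draw_gap(rng, paradigm.isi_engaged_max)
                # leave room for the epoch-closing bout (resolvable gap)
                if t + gap > evoke_off - 1.2:
                    break
                t = step_state(t, gap, 0.0, futile=False)
            # the engaged fish swims through to the Evoke end: close the
            # epoch with a bout ending exactly at evoke_off so pre-Probe
            # quiescence equals pause_effective
            tail_dur, tail_vig = _draw_bout(rng)
            if bouts and bouts[-1].offset > evoke_off - tail_dur - 0.5:
                bouts[-1] = Bout(bouts[-1].onset, evoke_off, bouts[-1].vigor)
            else:
                bouts.append(Bout(evoke_off - tail_dur, evoke_off, tail_vig))
            if t < evoke_off:
                t = step_state(t, evoke_off - t, 0.0, futile=False)
            t = evoke_off
            last_offset = evoke_off
            pause_dur = paradigm.pause_effective
        else:
            # open loop: the fish struggles (long, vigorous bouts with short
            # gaps) until the state crosses the passivity threshold
            timeout = (paradigm.evoke_futile_max
                       if paradigm.evoke_futile_max is not None
                       else paradigm.evoke_effective - paradigm.passivity_window)
            evoke_cap = evoke_on + timeout
            while s < sp.s_passive and t < evoke_cap:
                dur = 0.6 + 0.8 * rng.random()
                vig = float(np.exp(rng.normal(0.2, 0.3)))
                bouts.append(Bout(t, t + dur, vig))
                t = step_state(t, dur, vig, futile=True)
                gap = min(max(float(np.exp(rng.normal(math.log(0.6), 0.3))), 0.5),
                          0.9 * paradigm.isi_engaged_max)
                t = step_state(t, gap, 0.0, futile=True)
            last_offset = bouts[-1].offset
            # online passivity detection: Evoke ends once the no-swim
            # interval reaches passivity_window
            target = last_offset + paradigm.passivity_window
            if t < target:
                t = step_state(t, target - t, 0.0, futile=True)
            evoke_off = last_offset + paradigm.passivity_window
            t = evoke_off
            segs.append((evoke_on, evoke_off, paradigm.v_flow_evoke, 0.0))
            pause_dur = paradigm.pause_futile

        # --- Pause epoch (v_flow = 0, no swimming) ---
        pause_on = evoke_off
        pause_off = pause_on + pause_dur
        segs.append((pause_on, pause_off, 0.0, paradigm.g_ms))
        t = step_state(t, pause_dur, 0.0, futile=False)
        t = pause_off

        # --- Probe epoch: evidence accumulation against a noisy bound ---
        probe_on = pause_off
        theta = sp.bound * float(np.exp(rng.normal(0.0, sp.bound_sigma)))
        # spontaneous resolution of the internal state during quiescence:
        # after a random delay the state collapses quickly, the stimulus
        # drive recovers, and the behavioral response follows
        t_res = sp.res_delay + float(rng.exponential(sp.res_mean))
        period = paradigm.pulse_on + paradigm.pulse_off
        evidence = 0.0
        latency = None
        tt = 0.0
        while tt < paradigm.probe_cap:
            in_pulse = (tt % period) < paradigm.pulse_on
            v = paradigm.v_flow_probe if in_pulse else 0.0
            tau = _state_tau(s, sp.tau_engaged, sp.tau_disengaged)
            decay = math.exp(-dt / tau)
            evidence = (evidence * decay + v * tau * (1.0 - decay)
                        + sp.evidence_sigma * math.sqrt(dt) * rng.standard_normal())
            forced = trpv1 and (probe_on + tt) >= trpv1_t0
            if forced:
                s = sp.trpv1_force
            else:
                tau_s = sp.tau_res if tt > t_res else sp.tau_a
                s = astro_state_step(s, 0.0, False, dt, tau_s, sp.gain_k,
                                     mode=sp.mode)
            tt += dt
            s_events.append((probe_on + tt, s))
            if evidence >= theta:
                latency = tt
                break
        censored = latency is None
        latency_rec = paradigm.probe_cap if censored else latency
        probe_off = probe_on + min(latency_rec + dt, paradigm.probe_cap) \
            if not censored else probe_on + paradigm.probe_cap
        segs.append((probe_on, probe_off, -1.0, paradigm.g_ms))  # -1 marks pulses
        if not censored:
            dur, vig = _draw_bout(rng)
            vig *= 1.2
            bouts.append(Bout(probe_on + latency, probe_on + latency + dur, vig))
        t = probe_off

        # --- inter-trial interval ---
        iti_on = t
        segs.append((iti_on, iti_on + paradigm.iti, 0.0, paradigm.g_ms))
        t = step_state(t, paradigm.iti, 0.0, futile=False)
        t = iti_on + paradigm.iti

        n_pulses = int(math.ceil((probe_off - probe_on) / period))
        pulse_onsets = [probe_on + k * period for k in range(n_pulses)
                        if probe_on + k * period < probe_off]
        trials.append(TrialRecord(
            trial_id=trial_id, trial_type=trial_type,
            evoke_on=evoke_on, evoke_off=evoke_off,
            pause_on=pause_on, pause_off=pause_off,
            probe_on=probe_on, probe_off=probe_off,
            pulse_onsets=pulse_onsets,
            latency=latency_rec, censored=censored,
        ))

    # ---- rasterize the session onto the uniform grid ----
    total_t = t + 2.0
    n = int(math.ceil(total_t / dt))
    tgrid = np.arange(n) * dt

    vigor = np.zeros(n)
    for b in bouts:
        i0, i1 = int(round(b.onset / dt)), int(round(b.offset / dt))
        vigor[i0:max(i1, i0 + 1)] = b.vigor

    v_flow = np.zeros(n)
    gms = np.full(n, paradigm.g_ms)
    for (t_on, t_off, vf, g) in segs:
        i0, i1 = int(round(t_on / dt)), int(round(t_off / dt))
        if vf == -1.0:  # Probe pulse train
            period = paradigm.pulse_on + paradigm.pulse_off
            rel = tgrid[i0:i1] - t_on
            v_flow[i0:i1] = np.where((rel % period) < paradigm.pulse_on,
                                     paradigm.v_flow_probe, 0.0)
        else:
            v_flow[i0:i1] = vf
        gms[i0:i1] = g

    v_stim = v_flow - vigor * gms

    # state on the grid from the checkpoints (both were logged at grid times)
    s_arr = np.zeros(n)
    ev_t = np.array([e[0] for e in s_events])
    ev_s = np.array([e[1] for e in s_events])
    idx = np.clip(np.round(ev_t / dt).astype(int), 0, n - 1)
    s_arr[idx] = ev_s
    # forward-fill between checkpoints (carry the last logged value)
    logged = np.zeros(n, dtype=bool)
    logged[idx] = True
    pos = np.where(logged, np.arange(n), -1)
    pos = np.maximum.accumulate(pos)
    s_arr = np.where(pos >= 0, s_arr[np.maximum(pos, 0)], 0.0)

    state = StateTrace(t=tgrid, s=s_arr, tau_a=sp.tau_a, gain_k=sp.gain_k)
    return bouts, v_stim, v_flow, vigor, trials, state


# ---------------------------------------------------------------------------
# Ephys forward model
# ---------------------------------------------------------------------------

def synth_ephys(
    bouts: Sequence[Bout],
    fs: float = 6000.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    duration: float | None = None,
    carrier_hz: float = 60.0,
    amp_per_vigor: float = 1.0,
    taper: float = 0.01,
) -> EphysTrace:
    """Render a ventral-root-like voltage trace from a bout list.

    Baseline Gaussian noise plus, inside each bout, an amplitude-modulated
    oscillatory burst whose RMS scales with the bout's vigor.  A short cosine
    taper (``taper`` seconds) avoids onset/offset clicks.
    """
    bouts = sorted(bouts, key=lambda b: b.onset)
    for a, b in zip(bouts, bouts[1:]):
        if b.onset < a.offset:
            raise InvalidArgumentError("bouts must be non-overlapping")
    if fs <= 2 * carrier_hz:
        raise InvalidArgumentError("fs must exceed twice the burst carrier")
    if duration is None:
        duration = (bouts[-1].offset + 1.0) if bouts else 1.0
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    n = int(round(duration * fs))
    y = rng.normal(0.0, noise_sd, size=n)
    tvec = np.arange(n) / fs
    for b in bouts:
        i0 = int(round(b.onset * fs))
        i1 = min(int(round(b.offset * fs)), n)
        if i1 <= i0:
            continue
        seg_t = tvec[i0:i1]
        amp = amp_per_vigor * b.vigor
        env = np.ones(i1 - i0)
        k = min(int(taper * fs), (i1 - i0) // 2)
        if k > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
            env[:k] = ramp
            env[-k:] = ramp[::-1]
        y[i0:i1] += amp * env * np.sin(2 * np.pi * carrier_hz * seg_t)
    return EphysTrace(y=y, fs=fs)


# ---------------------------------------------------------------------------
# Neural population forward model
# ---------------------------------------------------------------------------

def indicator_kernel(dt: float, decay: float = 0.5, rise: float = 0.05) -> np.ndarray:
    """Difference-of-exponentials calcium-indicator kernel, unit DC gain."""
    if decay <= 0 or rise <= 0 or rise >= decay:
        raise InvalidArgumentError("need 0 < rise < decay")
    tk = np.arange(0.0, 6.0 * decay, dt)
    k = np.exp(-tk / decay) - np.exp(-tk / rise)
    return k / k.sum()


def leaky_integrate(drive: np.ndarray, tau: np.ndarray | float, dt: float) -> np.ndarray:
    """Exact exponential-hold leaky integration of a piecewise-constant drive.

    ``I[k+1] = I[k]·exp(-dt/tau[k]) + drive[k]·tau[k]·(1 - exp(-dt/tau[k]))``
    which solves dI/dt = -I/tau + drive exactly when the drive is held
    constant over each step.
    """
    drive = np.asarray(drive, dtype=float)
    n = drive.size
    if np.isscalar(tau) or np.ndim(tau) == 0:
        if tau <= 0:
            raise InvalidArgumentError("tau must be > 0")
        # constant tau: the recursion is a first-order IIR filter
        from scipy.signal import lfilter
        d = math.exp(-dt / float(tau))
        out = lfilter([0.0, float(tau) * (1.0 - d)], [1.0, -d], drive)
        return out
    tau_arr = np.broadcast_to(np.asarray(tau, dtype=float), (n,))
    if np.any(tau_arr <= 0):
        raise InvalidArgumentError("tau must be > 0")
    out = np.zeros(n)
    acc = 0.0
    for k in range(n - 1):
        d = math.exp(-dt / tau_arr[k])
        acc = acc * d + drive[k] * tau_arr[k] * (1.0 - d)
        out[k + 1] = acc
    return out


def adapt_drive(drive: np.ndarray, dt: float, tau_dep: float = 4.0,
                tau_rec: float = 1.0, depth: float = 0.9) -> np.ndarray:
    """Sensory adaptation of a normalized drive (values in [0, 1]).

    An adaptation state q relaxes toward the instantaneous drive with time
    constant ``tau_dep`` while the stimulus is on and recovers toward zero
    with the faster ``tau_rec`` while it is off; the effective drive is
    ``drive * (1 - depth * q)``.  Sustained motion (the Evoke flow) is
    suppressed down to ``1 - depth`` after a few seconds, while sparse
    pulses separated by stimulus-free gaps remain nearly fully effective.
    """
    if tau_dep <= 0 or tau_rec <= 0:
        raise InvalidArgumentError("adaptation time constants must be > 0")
    n = drive.size
    q = 0.0
    out = np.empty(n)
    d_dep = math.exp(-dt / tau_dep)
    d_rec = math.exp(-dt / tau_rec)
    for k in range(n):
        v = drive[k]
        if v > 0:
            q = v + (q - v) * d_dep
        else:
            q = q * d_rec
        out[k] = v * (1.0 - depth * min(q, 1.0))
    return out


def _prep_ramp(tgrid: np.ndarray, onsets: np.ndarray, lead: float) -> np.ndarray:
    """Ramps rising linearly from 0 to 1 over `lead` s before each swim onset."""
    r = np.zeros_like(tgrid)
    for on in onsets:
        mask = (tgrid >= on - lead) & (tgrid < on)
        r[mask] = np.maximum(r[mask], 1.0 - (on - tgrid[mask]) / lead)
    return r


def _frame_average(x: np.ndarray, tgrid: np.ndarray, dt: float,
                   fs_img: float) -> tuple[np.ndarray, np.ndarray]:
    """Within-frame mean downsampling to the imaging rate."""
    frame_len = 1.0 / fs_img
    n_frames = int(math.floor(tgrid[-1] / frame_len))
    idx = np.minimum((tgrid // frame_len).astype(int), n_frames)
    sums = np.bincount(idx[idx < n_frames], weights=x[idx < n_frames],
                       minlength=n_frames)
    counts = np.bincount(idx[idx < n_frames], minlength=n_frames)
    frame_t = (np.arange(n_frames) + 0.5) * frame_len
    return sums / np.maximum(counts, 1), frame_t


def synth_population(
    trials: Sequence[TrialRecord],
    v_stim: np.ndarray,
    s: np.ndarray,
    bouts: Sequence[Bout],
    vigor: np.ndarray,
    cfg: PopulationConfig,
    dt: float,
    seed: int = 0,
    v_flow: np.ndarray | None = None,
    pulse_height: float | None = None,
):
    """Generate the cells x frames ΔF/F matrix plus ground truth.

    Per class a latent rate is built on the behavior grid, convolved with the
    indicator kernel, averaged into imaging frames at ``cfg.fs_img`` and
    corrupted with Gaussian noise.  See the module docstring for the class
    definitions.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    n = v_stim.size
    tgrid = np.arange(n) * dt
    s = np.asarray(s, dtype=float)
    if cfg.mode == "calex":
        s = np.zeros_like(s)
    sc = np.clip(s, 0.0, 1.0)

    # Saturating, unit-normalized forward-motion drive: sensory responses to
    # whole-field motion saturate with speed, so the (faster) Evoke flow and
    # the Probe pulses drive the population at comparable amplitude.
    vsp = np.maximum(v_stim, 0.0)
    if pulse_height is None:
        vf = np.maximum(v_flow if v_flow is not None else v_stim, 0.0)
        pulse_height = max(vf[vf > 0].min() if np.any(vf > 0) else 1.0, 1e-9)
    drive = np.minimum(vsp, pulse_height) / pulse_height
    if cfg.adapt_depth > 0:
        drive = adapt_drive(drive, dt, cfg.adapt_tau, cfg.adapt_recovery,
                            cfg.adapt_depth)

    swim_onsets = np.array([b.onset for b in bouts])
    ramp = _prep_ramp(tgrid, swim_onsets, cfg.prep_ramp_lead)
    m = np.asarray(vigor, dtype=float)
    m_norm = m / max(m.max(), 1e-9)

    # recovery-linked amplification: visual responses grow in the lead-up
    # to the probe-evoked swim on both trial types
    amp = np.ones(n)
    if cfg.recovery_amp > 0:
        for tr in trials:
            if tr.censored or tr.latency is None:
                continue
            swim_t = tr.probe_on + tr.latency
            mask = (tgrid >= tr.probe_on) & (tgrid < swim_t)
            amp[mask] = 1.0 + cfg.recovery_amp * np.exp(
                -(swim_t - tgrid[mask]) / cfg.recovery_amp_tau)

    rates: dict[str, np.ndarray] = {}
    rates["sensory_pos"] = drive * (1.0 - cfg.sensory_depth * sc) * amp
    integ = leaky_integrate(
        drive, cfg.tau_engaged + (cfg.tau_disengaged - cfg.tau_engaged) * sc, dt)
    # integration neurons are a subclass of the sensory-encoding population:
    # a fast pulse-locked component rides on the slow accumulated signal
    rates["integrator"] = (0.2 * rates["sensory_pos"]
                           + integ / cfg.tau_engaged * 2.0
                           * (1.0 - cfg.integration_suppression * sc))
    pulse01 = (drive > 0).astype(float) * np.minimum(drive, 1.0)
    rates["sensory_neg"] = 1.0 - 0.8 * pulse01 * (1.0 - cfg.negative_suppression * sc)
    rates["motor_prep"] = ramp
    rates["motor"] = m_norm
    rates["noise"] = np.zeros(n)

    classes: list[str] = []
    gains: list[float] = []
    latent_rows: list[np.ndarray] = []
    region_list: list[str] = []

    kern = indicator_kernel(dt, cfg.indicator_decay, cfg.indicator_rise)

    # region allocation for the combined sensory pool (see module constants)
    sens_regions = list(SENSORY_REGION_INTEGRATOR_FRAC)
    sens_frac = np.array([SENSORY_REGION_INTEGRATOR_FRAC[r] for r in sens_regions])

    for cls in CELL_CLASSES:
        n_c = cfg.n_cells.get(cls, 0)
        for j in range(n_c):
            g = float(np.exp(rng.normal(0.0, cfg.gain_sigma)))
            if cls == "anti_motor":
                phase = rng.uniform(0, 2 * np.pi)
                osc = 0.25 * np.sin(2 * np.pi * tgrid / 8.0 + phase)
                reliab = (rng.random(n) < 0.5).astype(float)
                # gate: negative pulse responses vanish at high state
                rate = (1.0 + osc - 2.0 * m_norm
                        - 0.5 * pulse01 * reliab * (1.0 - sc))
            else:
                rate = rates[cls]
            latent_rows.append(g * rate)
            classes.append(cls)
            gains.append(g)
            if cls in ("sensory_pos", "integrator"):
                w = sens_frac if cls == "integrator" else (1.0 - sens_frac)
                region = rng.choice(sens_regions, p=w / w.sum())
            else:
                region = rng.choice(_CLASS_REGIONS[cls])
            region_list.append(str(region))

    latent = np.vstack(latent_rows) if latent_rows else np.zeros((0, n))
    if cfg.indicator_on and latent.size:
        from scipy.signal import fftconvolve
        conv = fftconvolve(latent, kern[None, :], mode="full", axes=1)[:, :n]
    else:
        conv = latent

    frames = []
    frame_t = None
    for row in conv:
        fr, frame_t = _frame_average(row, tgrid, dt, cfg.fs_img)
        frames.append(fr)
    dff = np.vstack(frames) if frames else np.zeros((0, 0))
    if frame_t is None:
        frame_t = np.array([])
    if cfg.noise_sd > 0 and dff.size:
        dff = dff + rng.normal(0.0, cfg.noise_sd, size=dff.shape)

    truth = GroundTruth(
        bouts=list(bouts),
        cell_class=np.array(classes),
        cell_gain=np.array(gains),
        s=s,
        trial_types=[tr.trial_type for tr in trials],
        latencies=np.array([tr.latency for tr in trials], dtype=float),
        censored=np.array([tr.censored for tr in trials], dtype=bool),
    )
    return dff, frame_t, np.array(region_list), truth


# ---------------------------------------------------------------------------
# Whole-session driver
# ---------------------------------------------------------------------------

def simulate_session(
    paradigm: ParadigmConfig | None = None,
    state_params: StateParams | None = None,
    population: PopulationConfig | None = None,
    seed: int = 0,
    fs_ephys: float = 6000.0,
    ephys_noise_sd: float = 0.05,
) -> Session:
    """Simulate behavior, stimulus, latent state, ephys and ΔF/F for one fish.

    All randomness flows from ``seed`` through named substreams (behavior,
    ephys noise, calcium noise), so identical seeds give bitwise-identical
    sessions.
    """
    paradigm = paradigm or ParadigmConfig()
    sp = state_params or StateParams()
    pop = population or PopulationConfig(mode=sp.mode)
    if pop.mode != sp.mode:
        raise ConfigError("state and population modes must agree")

    bouts, v_stim, v_flow, vigor, trials, state = simulate_swim_agent(
        paradigm, sp, seed=seed)
    duration = state.t[-1] + paradigm.dt
    ephys = synth_ephys(bouts, fs=fs_ephys, noise_sd=ephys_noise_sd,
                        seed=seed, duration=duration)
    dff, frame_t, regions, truth = synth_population(
        trials, v_stim, state.s, bouts, vigor, pop, paradigm.dt,
        seed=seed, v_flow=v_flow, pulse_height=paradigm.v_flow_probe)
    return Session(
        t=state.t, dt=paradigm.dt, v_stim=v_stim, v_flow=v_flow, vigor=vigor,
        state=state, bouts=bouts, trials=trials, ephys=ephys,
        dff=dff, frame_t=frame_t, fs_img=pop.fs_img, regions=regions,
        truth=truth, paradigm=paradigm, state_params=sp, population=pop,
        seed=seed,
    )
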