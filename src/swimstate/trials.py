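"""Trial assembly, internal-state classification and probe-swim latency.

Each trial consists of Evoke / Pause / Probe epochs.  Effective trials run
the Evoke epoch in closed loop and are labelled ``Engaged`` when the fish
swam continuously (inter-swim interval at most 3 s) through to the Evoke end,
``Excluded`` otherwise.  Futile trials run the Evoke epoch in open loop and
are labelled ``Disengaged`` when a > 5 s no-swim interval covers the Evoke
end, ``Perseverant`` when the fish swam through to the Pause transition.

All times are seconds from session start; intervals are half-open
``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError

__all__ = [
    "TrialRecord",
    "build_trials",
    "classify_trial",
    "latency_to_probe_swim",
    "filter_for_dual_alignment",
    "trials_to_frame",
]


@dataclass
class TrialRecord:
    """One trial's type, epoch boundaries, label and probe-swim latency."""

    trial_id: int
    trial_type: str                  # Effective | Futile | Replay
    evoke_on: float
    evoke_off: float
    pause_on: float
    pause_off: float
    probe_on: float
    probe_off: float
    pulse_onsets: list[float] = field(default_factory=list)
    label: str | None = None         # Engaged | Disengaged | Perseverant | Excluded
    latency: float | None = None     # s from probe_on; cap value when censored
    censored: bool = False

    def __post_init__(self) -> None:
        b = (self.evoke_on, self.evoke_off, self.pause_on,
             self.pause_off, self.probe_on, self.probe_off)
        if any(x2 < x1 - 1e-9 for x1, x2 in zip(b, b[1:])):
            raise InvalidArgumentError("epoch boundaries must be non-decreasing")
        if self.latency is not None and self.latency < 0:
            raise InvalidArgumentError("latency must be >= 0")


def build_trials(
    epochs: pd.DataFrame,
    bouts,
    paradigm,
) -> list[TrialRecord]:
    """Assemble :class:`TrialRecord` objects from a stimulus epoch log.

    ``epochs`` must have columns ``trial_id, trial_type, epoch, on, off``
    with one row per (trial, epoch).  On Futile trials the Pause epoch is
    checked to begin ``passivity_window`` after the last Evoke swim offset;
    the Probe is truncated at ``probe_cap``.  Latencies and labels are filled
    by :func:`latency_to_probe_swim` and :func:`classify_trial`.
    """
    required = {"trial_id", "trial_type", "epoch", "on", "off"}
    if not required.issubset(epochs.columns):
        raise FormatError(f"epoch log must have columns {sorted(required)}")
    onsets = np.array(sorted(b.onset for b in bouts))
    offsets = np.array([b.offset for b in sorted(bouts, key=lambda b: b.onset)])
    if onsets.size and (epochs["on"].min() > onsets.min() + 1e-6
                        or epochs["off"].max() < onsets.max() - 1e-6):
        raise FormatError("stimulus log does not cover the bout onsets")

    out: list[TrialRecord] = []
    for tid, grp in epochs.groupby("trial_id", sort=True):
        by_epoch = {r.epoch: r for r in grp.itertuples()}
        missing = {"evoke", "pause", "probe"} - set(by_epoch)
        if missing:
            raise FormatError(f"trial {tid} missing epoch(s) {sorted(missing)}")
        ev, pa, pr = by_epoch["evoke"], by_epoch["pause"], by_epoch["probe"]
        if not (abs(ev.off - pa.on) < 1e-6 and abs(pa.off - pr.on) < 1e-6):
            raise FormatError(f"trial {tid} epochs are not contiguous")
        probe_off = min(pr.off, pr.on + paradigm.probe_cap)
        period = paradigm.pulse_on + paradigm.pulse_off
        n_pulses = int(np.ceil((probe_off - pr.on) / period))
        pulse_onsets = [pr.on + k * period for k in range(n_pulses)
                        if pr.on + k * period < probe_off]
        rec = TrialRecord(
            trial_id=int(tid), trial_type=str(grp["trial_type"].iloc[0]),
            evoke_on=ev.on, evoke_off=ev.off,
            pause_on=pa.on, pause_off=pa.off,
            probe_on=pr.on, probe_off=probe_off,
            pulse_onsets=pulse_onsets,
        )
        rec.latency, rec.censored = latency_to_probe_swim(rec, bouts)
        rec.label = classify_trial(rec, bouts, paradigm)
        out.append(rec)
    return out


def classify_trial(trial: TrialRecord, bouts, paradigm,
                   end_pause_rule: float | None = None,
                   gap_tolerance: float = 0.5) -> str:
    """Label one trial's internal state from its Evoke-epoch swim pattern.

    ``end_pause_rule`` is the maximal tolerated no-swim interval at the Evoke
    end of an Effective trial (default ``isi_engaged_max`` = 3 s; the
    whole-brain selection variant uses 3.3 s).  ``gap_tolerance`` absorbs
    bout-offset smearing of the detector when comparing the end-of-Evoke
    no-swim gap against ``passivity_window`` on Futile trials (the online
    detector produces gaps of exactly the window length).
    """
    rule = paradigm.isi_engaged_max if end_pause_rule is None else end_pause_rule
    ons = np.array(sorted(b.onset for b in bouts))
    offs = np.array([b.offset for b in sorted(bouts, key=lambda b: b.onset)])
    in_evoke = (offs > trial.evoke_on) & (ons < trial.evoke_off)
    e_on, e_off = ons[in_evoke], offs[in_evoke]

    if trial.trial_type == "Effective":
        if e_on.size == 0:
            return "Excluded"
        isis = (e_on[1:] - e_off[:-1]) if e_on.size > 1 else np.array([])
        end_gap = trial.evoke_off - e_off.max()
        if end_gap > rule:
            return "Excluded"
        if isis.size and isis.max() > paradigm.isi_engaged_max:
            return "Excluded"
        return "Engaged"
    if trial.trial_type in ("Futile", "Replay"):
        if e_on.size == 0:
            return "Disengaged"
        end_gap = trial.evoke_off - e_off.max()
        # the online passivity detector ends the Evoke epoch once the no-swim
        # interval reaches passivity_window, so the boundary case (gap equal
        # to the window) is passivity, not perseverance
        if end_gap >= paradigm.passivity_window - gap_tolerance:
            return "Disengaged"
        return "Perseverant"
    raise InvalidArgumentError(f"unknown trial type {trial.trial_type!r}")


def latency_to_probe_swim(trial: TrialRecord, bouts) -> tuple[float, bool]:
    """Latency (s) from Probe onset to the first bout; capped when censored.

    The boundary at ``probe_on`` is inclusive: a bout starting exactly at
    Probe onset counts as probe-evoked with latency 0.
    """
    ons = np.array(sorted(b.onset for b in bouts))
    in_probe = ons[(ons >= trial.probe_on) & (ons < trial.probe_off)]
    if in_probe.size == 0:
        return trial.probe_off - trial.probe_on, True
    return float(in_probe[0] - trial.probe_on), False


def filter_for_dual_alignment(trials, min_latency: float = 20.0):
    """Keep trials with probe-swim latency >= ``min_latency`` (boundary
    inclusive), so dual-aligned averages have non-overlapping segments."""
    return [t for t in trials
            if t.latency is not None and t.latency >= min_latency]


def trials_to_frame(trials) -> pd.DataFrame:
    """Tabulate trials (one row per trial) for CSV export."""
    rows = [{
        "trial_id": t.trial_id, "type": t.trial_type, "label": t.label,
        "evoke_on": t.evoke_on, "evoke_off": t.evoke_off,
        "pause_on": t.pause_on, "pause_off": t.pause_off,
        "probe_on": t.probe_on, "probe_off": t.probe_off,
        "latency_s": t.latency, "censored": t.censored,
    } for t in trials]
    return pd.DataFrame(rows)
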