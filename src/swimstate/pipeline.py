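"""End-to-end analysis pipeline and its configuration.

``analyze_session`` runs the full chain on one session (simulated in memory
or loaded from a container): swim detection, trial structuring, cell
classification, integration fits, state-modulation metrics and the recovery
analyses.  ``run_pipeline`` wraps it with file I/O, per-stage logging and a
JSON summary report; ``aggregate_fish`` pools several fish for the
across-fish statistics (ANOVA, region regression).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bouts as bouts_mod
from . import integration as integ_mod
from . import modulation as mod_mod
from . import recovery as rec_mod
from . import tuning as tuning_mod
from .bouts import BoutDetectionParams
from .errors import ConfigError
from .session import SessionView, epochs_table, read_session, write_session
from .synthetic import (ParadigmConfig, PopulationConfig, Session, StateParams,
                        indicator_kernel, leaky_integrate, simulate_session)
from .trials import build_trials, filter_for_dual_alignment, trials_to_frame

log = logging.getLogger("swimstate")

__all__ = [
    "PipelineConfig", "SessionAnalysis", "analyze_session", "run_pipeline",
    "aggregate_fish", "load_config", "dump_default_config",
]


@dataclass
class AnalysisConfig:
    """Thresholds and windows of the analysis stages."""

    alpha: float = 0.05
    probe_window: float = 12.0      # s, first six pulses
    baseline_window: float = 2.0    # s of pre-epoch baseline
    regressor_decay: float = 0.5    # s; sensory regressor is the stimulus
    regressor_rise: float = 0.05    # convolved with the indicator kernel
    tau_long: float = 4.0           # s, long-decay cutoff for region fractions
    n_stu: int = 20                 # scaled-time-unit bins
    dual_align_min_latency: float = 20.0
    top_frac: float = 0.05          # motor-prep population cutoff


@dataclass
class PipelineConfig:
    """Nested configuration mirroring each module's parameter types."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    state: StateParams = field(default_factory=StateParams)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    detection: BoutDetectionParams = field(default_factory=BoutDetectionParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    n_fish: int = 1
    fs_ephys: float = 6000.0
    out_dir: str = "swimstate_out"


_SECTIONS = {
    "paradigm": ParadigmConfig, "state": StateParams,
    "population": PopulationConfig, "detection": BoutDetectionParams,
    "analysis": AnalysisConfig,
}


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    kwargs = {}
    for key, val in doc.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            valid = set(cls.__dataclass_fields__)
            unknown = set(val) - valid
            if unknown:
                raise ConfigError(f"unknown key(s) in [{key}]: {sorted(unknown)}")
            kwargs[key] = cls(**val)
        elif key in ("seed", "n_fish", "fs_ephys", "out_dir"):
            kwargs[key] = val
        else:
            raise ConfigError(f"unknown config section {key!r}")
    return PipelineConfig(**kwargs)


def dump_default_config() -> str:
    """All defaults as a YAML document (for `swimstate config --dump-defaults`)."""
    cfg = PipelineConfig()
    doc = {name: asdict(getattr(cfg, name)) for name in _SECTIONS}
    doc.update({"seed": cfg.seed, "n_fish": cfg.n_fish,
                "fs_ephys": cfg.fs_ephys, "out_dir": cfg.out_dir})
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# Session analysis
# ---------------------------------------------------------------------------

@dataclass
class SessionAnalysis:
    """All per-session analysis products."""

    fish_id: int
    bouts: list
    trials: list
    trials_df: pd.DataFrame
    tuning: pd.DataFrame            # per-cell flags, rho, tau, d', leakiness
    pulses: pd.DataFrame            # cell x trial x pulse endpoints and AUCs
    modulation: pd.DataFrame        # cell_id, region, dprime, duration_s
    region_summary: pd.DataFrame
    amplification: pd.DataFrame
    decoder: rec_mod.DecoderResult | None
    warped_mean: np.ndarray | None
    report: dict


def _session_arrays(sess):
    """Normalize an in-memory Session or an on-disk SessionView."""
    if isinstance(sess, Session):
        return dict(
            ephys=sess.ephys, vigor=sess.vigor, dt=sess.dt,
            v_stim=sess.v_stim, v_flow=sess.v_flow,
            epochs=epochs_table(sess.trials), dff=sess.dff,
            frame_t=sess.frame_t, fs_img=sess.fs_img, regions=sess.regions,
            paradigm=sess.paradigm,
        )
    if isinstance(sess, SessionView):
        cfg = sess.config
        return dict(
            ephys=sess.ephys, vigor=sess.vigor, dt=sess.dt,
            v_stim=sess.v_stim, v_flow=sess.v_flow, epochs=sess.epochs,
            dff=sess.dff, frame_t=sess.frame_t, fs_img=sess.fs_img,
            regions=sess.regions,
            paradigm=ParadigmConfig(**cfg["paradigm"]),
        )
    raise TypeError(f"cannot analyze {type(sess)!r}")


def _grid_fit(trace_frames, idx, integ_grid, base_idx):
    """Closed-form beta + SSE over a tau grid restricted to frame subset idx."""
    x = trace_frames[idx]
    if base_idx.size:
        x = x - trace_frames[base_idx].mean()
    best = (np.nan, 0.0, np.inf)
    for tau, integ in integ_grid:
        ii = integ[idx]
        if base_idx.size:
            ii = ii - integ[base_idx].mean()
        denom = float(ii @ ii)
        if denom <= 0:
            continue
        beta = float(x @ ii) / denom
        sse = float(x @ x) - beta * float(x @ ii)
        if sse < best[2]:
            best = (tau, beta, sse)
    return best


def analyze_session(sess, seed: int = 0, fish_id: int = 0,
                    detection: BoutDetectionParams | None = None,
                    analysis: AnalysisConfig | None = None) -> SessionAnalysis:
    """Run the full analysis chain on one session."""
    ana = analysis or AnalysisConfig()
    arr = _session_arrays(sess)
    paradigm = arr["paradigm"]
    dff, frame_t, fs_img = arr["dff"], arr["frame_t"], arr["fs_img"]
    n_cells, n_frames = dff.shape

    detected = bouts_mod.detect_session_bouts(arr["ephys"], detection)
    trials = build_trials(arr["epochs"], detected, paradigm)
    trials_df = trials_to_frame(trials)

    v_stim_f = tuning_mod.frame_resample(arr["v_stim"], arr["dt"], n_frames, fs_img)
    v_flow_f = tuning_mod.frame_resample(arr["v_flow"], arr["dt"], n_frames, fs_img)
    vigor_f = tuning_mod.frame_resample(arr["vigor"], arr["dt"], n_frames, fs_img)
    # indicator-matched sensory regressor: correlating ΔF/F against the raw
    # pulse train misses slow cells whose pulse-locked ripple lags by the
    # indicator decay, so the stimulus is convolved with the same kernel
    from scipy.signal import fftconvolve
    kern = indicator_kernel(arr["dt"], ana.regressor_decay, ana.regressor_rise)
    v_sens = fftconvolve(np.maximum(arr["v_stim"], 0.0), kern)[: arr["v_stim"].size]
    v_sens_f = tuning_mod.frame_resample(v_sens, arr["dt"], n_frames, fs_img)

    tuning = tuning_mod.classify_cells(
        dff, frame_t, v_sens_f, vigor_f, trials,
        alpha=ana.alpha, top_frac=ana.top_frac)
    tuning["region"] = arr["regions"][: len(tuning)]

    # --- integration fits against the Probe pulse series: shared leaky
    # integrals of v_flow masked to the Probe epochs, one per grid tau
    frame_dt = 1.0 / fs_img
    probe_mask = np.zeros(n_frames, dtype=bool)
    for t in trials:
        probe_mask |= (frame_t >= t.probe_on) & (frame_t < t.probe_off)
    v_pulse_f = np.where(probe_mask, v_flow_f, 0.0)
    integ_grid = [(tau, leaky_integrate(v_pulse_f, tau, frame_dt))
                  for tau in integ_mod.TAU_GRID]

    quiet = {lab: [t for t in trials if t.label == lab
                   and t.latency is not None and t.latency > ana.probe_window]
             for lab in ("Engaged", "Disengaged")}

    period = paradigm.pulse_on + paradigm.pulse_off
    n_p6 = int(round(ana.probe_window / period))

    pulse_rows = []
    cell_rows = []
    for cid in range(n_cells):
        trace = dff[cid]
        row = {"cell_id": cid}
        cond_aucs: dict[str, list[list[float]]] = {}
        for lab in ("Engaged", "Disengaged"):
            trs = quiet[lab]
            if len(trs) >= 2:
                fit_idx = np.concatenate([
                    np.flatnonzero((frame_t >= t.probe_on)
                                   & (frame_t < t.probe_on + ana.probe_window))
                    for t in trs])
                base_idx = np.concatenate([
                    np.flatnonzero((frame_t >= t.probe_on - ana.baseline_window)
                                   & (frame_t < t.probe_on)) for t in trs])
                tau_hat, beta_hat, _ = _grid_fit(trace, fit_idx, integ_grid,
                                                 base_idx)
            else:
                tau_hat, beta_hat = np.nan, np.nan
            row[f"tau_{lab.lower()}"] = tau_hat
            row[f"beta_{lab.lower()}"] = beta_hat

            ons, offs = [], []
            per_pulse: list[list[float]] = [[] for _ in range(n_p6)]
            for t in trs:
                pre = np.flatnonzero(frame_t < t.probe_on)
                base = trace[pre[-1]] if pre.size else 0.0
                try:
                    on_i, off_i = integ_mod.pulse_endpoints(
                        trace, frame_t, t.pulse_onsets,
                        paradigm.pulse_on, paradigm.pulse_off, n_p6)
                except Exception:
                    continue
                ons.append(on_i - base)
                offs.append(off_i - base)
                for k in range(n_p6):
                    # incremental response: area relative to the pre-pulse
                    # value, isolating the fast pulse-locked component
                    pre_k = np.flatnonzero(frame_t < t.pulse_onsets[k])
                    base_k = trace[pre_k[-1]] if pre_k.size else base
                    auc = integ_mod.pulse_response_auc(
                        trace, frame_t, t.pulse_onsets[k],
                        window=period, baseline=base_k)
                    per_pulse[k].append(auc)
                    pulse_rows.append({
                        "cell_id": cid, "trial_id": t.trial_id,
                        "label": lab, "pulse_i": k + 1, "auc": auc,
                        "on": on_i[k] - base, "off": off_i[k + 1] - base,
                    })
            if ons:
                on_m = np.mean(ons, axis=0)
                off_m = np.mean(offs, axis=0)
                row[f"inv_leak_{lab.lower()}"] = integ_mod.inverse_leakiness(
                    on_m, off_m) if n_p6 >= 6 else np.nan
            else:
                row[f"inv_leak_{lab.lower()}"] = np.nan
            cond_aucs[lab] = per_pulse

        eng = [a for pulse in cond_aucs.get("Engaged", []) for a in pulse]
        dis = [a for pulse in cond_aucs.get("Disengaged", []) for a in pulse]
        if len(eng) >= 2 and len(dis) >= 2:
            row["dprime"] = mod_mod.dprime(eng, dis)
            row["duration_s"] = mod_mod.modulation_duration(
                [np.array(p) for p in cond_aucs["Engaged"]],
                [np.array(p) for p in cond_aucs["Disengaged"]],
                np.arange(n_p6) * period, probe_len=paradigm.probe_cap,
                alpha=ana.alpha)
        else:
            row["dprime"] = np.nan
            row["duration_s"] = np.nan
        cell_rows.append(row)

    cells = pd.DataFrame(cell_rows)
    tuning = tuning.merge(cells, on="cell_id")
    tuning["tau"] = tuning["tau_engaged"]
    pulses = pd.DataFrame(pulse_rows)

    modulation = tuning[["cell_id", "region", "dprime", "duration_s"]].copy()
    regions = mod_mod.region_summary(tuning, tau_long=ana.tau_long)

    # --- recovery analyses on the sensory population average
    sens_mask = (tuning["sensory_pos"] | tuning["sensory_neg"]).to_numpy()
    amp_rows = []
    feat_rows = []
    rng = np.random.default_rng(seed + 17)
    sens_ids = np.flatnonzero(tuning["sensory_pos"].to_numpy())
    pop_mean = dff[sens_ids].mean(axis=0) if sens_ids.size else dff.mean(axis=0)
    for t in trials:
        if t.censored or t.latency is None or t.label not in ("Engaged",
                                                              "Disengaged"):
            continue
        swim_t = t.probe_on + t.latency
        onsets = np.asarray(t.pulse_onsets)
        before = onsets[onsets < swim_t]
        if before.size == 0:
            continue
        pre = np.flatnonzero(frame_t < t.probe_on)
        base = pop_mean[pre[-1]] if pre.size else 0.0
        for j, t0 in enumerate(before):
            rel = j - before.size          # -1 is the last pulse before swim
            auc = integ_mod.pulse_response_auc(pop_mean, frame_t, t0,
                                               window=period, baseline=base)
            amp_rows.append({"condition": t.label, "trial_id": t.trial_id,
                             "rel_index": rel, "auc": auc})
        # decoder features: a random pulse 1..7 before the swim
        usable = [k for k in range(1, min(8, before.size + 1))]
        if usable:
            nth = int(rng.choice(usable))
            t0 = before[-nth]
            feats = {}
            for cid in sens_ids:
                pre_c = np.flatnonzero(frame_t < t.probe_on)
                base_c = dff[cid][pre_c[-1]] if pre_c.size else 0.0
                feats[f"cell{cid}"] = integ_mod.pulse_response_auc(
                    dff[cid], frame_t, t0, window=period, baseline=base_c)
            feat_rows.append({"condition": t.label, "trial_id": t.trial_id,
                              "latency_s": swim_t - t0, **feats})
    amplification = (rec_mod.progressive_amplification(pd.DataFrame(amp_rows))
                     if amp_rows else pd.DataFrame())
    decoder = None
    if feat_rows:
        feats_df = pd.DataFrame(feat_rows)
        # keep behavior-predictive cells (response anticorrelated with latency)
        keep = []
        for col in feats_df.columns:
            if not col.startswith("cell"):
                continue
            flag, _, _ = rec_mod.select_behavior_predictive(
                feats_df[col].to_numpy(), feats_df["latency_s"].to_numpy(),
                alpha=ana.alpha)
            if flag:
                keep.append(col)
        if keep:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                decoder = rec_mod.decode_latency(
                    feats_df[["condition", "trial_id", "latency_s"] + keep],
                    seed=seed)

    warped_mean = None
    long_trials = filter_for_dual_alignment(
        [t for t in trials if not t.censored],
        ana.dual_align_min_latency)
    if long_trials:
        traces = {t.trial_id: pop_mean for t in long_trials}
        probe_on = {t.trial_id: t.probe_on for t in long_trials}
        anchor = {}
        for t in long_trials:
            swim_t = t.probe_on + t.latency
            before = [p for p in t.pulse_onsets if p < swim_t]
            anchor[t.trial_id] = before[-1] if before else swim_t
        try:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                warped = rec_mod.time_warp_align(
                    traces, frame_t, probe_on, anchor,
                    left_len=6.0, right_len=4.0, n_stu=ana.n_stu, fs=fs_img)
            warped_mean = warped.mean()
        except Exception:
            warped_mean = None

    lat = trials_df.dropna(subset=["latency_s"])
    report = {
        "fish_id": fish_id,
        "n_bouts": len(detected),
        "n_trials": len(trials),
        "labels": trials_df["label"].value_counts().to_dict(),
        "mean_latency_effective": float(
            lat[lat["type"] == "Effective"]["latency_s"].mean()),
        "mean_latency_futile": float(
            lat[lat["type"] == "Futile"]["latency_s"].mean())
        if (lat["type"] == "Futile").any() else np.nan,
        "median_tau_engaged": float(np.nanmedian(tuning["tau_engaged"])),
        "median_tau_disengaged": float(np.nanmedian(tuning["tau_disengaged"])),
        "median_dprime": float(np.nanmedian(tuning["dprime"])),
        "n_sensory_pos": int(tuning["sensory_pos"].sum()),
        "n_sensory_neg": int(tuning["sensory_neg"].sum()),
        "n_motor": int(tuning["motor"].sum()),
        "n_motor_prep": int(tuning["motor_prep"].sum()),
        "decoder_rank_corr": decoder.rank_corr if decoder else None,
        "frac_state_dep_early": state_dependence_fraction(
            dff, frame_t, trials, offset=3.0, align="probe", alpha=ana.alpha),
        "frac_state_dep_preswim": state_dependence_fraction(
            dff, frame_t, trials, offset=-1.0, align="swim", alpha=ana.alpha),
    }
    return SessionAnalysis(
        fish_id=fish_id, bouts=detected, trials=trials, trials_df=trials_df,
        tuning=tuning, pulses=pulses, modulation=modulation,
        region_summary=regions, amplification=amplification, decoder=decoder,
        warped_mean=warped_mean, report=report,
    )


def state_dependence_fraction(dff: np.ndarray, frame_t: np.ndarray, trials,
                              offset: float, align: str = "probe",
                              alpha: float = 0.05) -> float:
    """Percent state-dependent cells at one paradigm-aligned time.

    ``align='probe'`` samples every labelled trial at ``probe_on + offset``;
    ``align='swim'`` at ``swim_time + offset`` (offset negative for
    pre-swim).  Returns the percentage of cells whose ΔF/F differs between
    Engaged and Disengaged trials (rank-sum test) at that time.
    """
    snaps = {"Engaged": [], "Disengaged": []}
    for t in trials:
        if t.label not in snaps:
            continue
        if align == "probe":
            when = t.probe_on + offset
        elif align == "swim":
            if t.censored or t.latency is None:
                continue
            when = t.probe_on + t.latency + offset
        else:
            raise ValueError("align must be 'probe' or 'swim'")
        if when < t.probe_on - 1e-9 or when > t.probe_off:
            continue
        k = int(np.argmin(np.abs(frame_t - when)))
        snaps[t.label].append(dff[:, k])
    if len(snaps["Engaged"]) < 2 or len(snaps["Disengaged"]) < 2:
        return np.nan
    return mod_mod.fraction_state_dependent(
        np.column_stack(snaps["Engaged"]),
        np.column_stack(snaps["Disengaged"]), alpha=alpha)


def aggregate_fish(analyses: list[SessionAnalysis],
                   analysis: AnalysisConfig | None = None) -> dict:
    """Across-fish statistics: latency ANOVA and region-level regression."""
    ana = analysis or AnalysisConfig()
    rows = []
    for a in analyses:
        for _, r in a.trials_df.iterrows():
            if r["latency_s"] is not None and not np.isnan(r["latency_s"]):
                rows.append({"fish": a.fish_id, "trial_type": r["type"],
                             "measure": r["latency_s"]})
    out: dict = {}
    df = pd.DataFrame(rows)
    try:
        out["latency_anova"] = mod_mod.anova_trialtype(df)
    except Exception as exc:
        out["latency_anova"] = {"error": str(exc)}
    pooled = pd.concat([a.tuning for a in analyses], ignore_index=True)
    regions = mod_mod.region_summary(pooled, tau_long=ana.tau_long)
    sel = regions.dropna(subset=["mean_dprime", "frac_long_tau"])
    rho, p, slope = mod_mod.depth_integration_regression(
        sel["mean_dprime"].to_numpy(), sel["frac_long_tau"].to_numpy())
    out["depth_vs_integration"] = {"rho": rho, "p": p, "slope": slope}
    out["region_summary"] = regions
    return out


# ---------------------------------------------------------------------------
# File-level orchestration
# ---------------------------------------------------------------------------

_CSV_UNITS = "# units: times s, vigor a.u., dff ΔF/F, auc ΔF/F*s\n"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_CSV_UNITS)
        df.to_csv(fh, index=False)


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Simulate and analyze ``cfg.n_fish`` sessions end to end.

    Writes session containers, result tables and a JSON + human-readable
    report under ``out_dir``.  Any stage failure aborts with the stage name;
    upstream outputs are preserved.
    """
    if cfg.paradigm.n_trials == 0:
        raise ConfigError("n_trials must be > 0 to run the pipeline")
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analyses = []
    stage = "simulate"
    try:
        for fish in range(cfg.n_fish):
            t0 = time.time()
            stage = f"simulate[fish{fish}]"
            sess = simulate_session(cfg.paradigm, cfg.state, cfg.population,
                                    seed=cfg.seed + fish,
                                    fs_ephys=cfg.fs_ephys)
            write_session(out / f"session_fish{fish}.h5", sess)
            log.info("%s: %d bouts, %.1f s (wall %.1fs)", stage,
                     len(sess.bouts), sess.t[-1], time.time() - t0)
            stage = f"analyze[fish{fish}]"
            t0 = time.time()
            a = analyze_session(sess, seed=cfg.seed + fish, fish_id=fish,
                                detection=cfg.detection, analysis=cfg.analysis)
            log.info("%s: %d trials, %d cells (wall %.1fs)", stage,
                     len(a.trials), len(a.tuning), time.time() - t0)
            _write_csv(bouts_mod.bouts_to_frame(a.bouts),
                       out / f"bouts_fish{fish}.csv")
            _write_csv(a.trials_df, out / f"trials_fish{fish}.csv")
            _write_csv(a.tuning, out / f"tuning_fish{fish}.csv")
            _write_csv(a.pulses, out / f"pulses_fish{fish}.csv")
            _write_csv(a.modulation, out / f"modulation_fish{fish}.csv")
            analyses.append(a)
        stage = "aggregate"
        agg = aggregate_fish(analyses, cfg.analysis)
        _write_csv(agg.pop("region_summary"), out / "region_summary.csv")
        report = {
            "per_fish": [a.report for a in analyses],
            "aggregate": agg,
            "median_dprime_all": float(np.nanmedian(np.concatenate(
                [a.tuning["dprime"].to_numpy() for a in analyses]))),
            "mode": cfg.state.mode,
        }
        report["calex_near_zero_dprime"] = bool(
            cfg.state.mode == "calex"
            and abs(report["median_dprime_all"]) <= 0.1)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        with open(out / "report.txt", "w") as fh:
            for a in analyses:
                fh.write(f"fish {a.fish_id}: "
                         f"{a.report['n_trials']} trials, "
                         f"latency E={a.report['mean_latency_effective']:.1f}s "
                         f"F={a.report['mean_latency_futile']:.1f}s, "
                         f"tau E={a.report['median_tau_engaged']:.1f}s "
                         f"D={a.report['median_tau_disengaged']:.1f}s\n")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
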