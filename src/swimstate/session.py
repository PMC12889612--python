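"""HDF5 session container: one hierarchical store per simulated fish.

Layout::

    /behavior/ephys      raw voltage trace     (attr: fs)
    /behavior/vigor      vigor on the behavior grid (attr: dt)
    /behavior/bouts      n x 3 (onset, offset, vigor), appended by detection
    /stimulus/v_stim     closed-loop stimulus velocity (behavior grid)
    /stimulus/v_flow     experimenter flow velocity (behavior grid)
    /stimulus/epochs     structured table: trial_id, trial_type, epoch, on, off
    /state/s             latent internal state (behavior grid)
    /neural/dff          cells x frames ΔF/F   (attrs: fs_img)
    /neural/frame_t      frame-center times
    /neural/regions      region label per cell
    /truth/*             generator ground truth (synthetic sessions only)

Root attrs: ``schema_version`` and ``config`` (resolved-config JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError
from .synthetic import Bout, EphysTrace, Session, StateTrace
from .trials import TrialRecord

__all__ = ["SCHEMA_VERSION", "write_session", "read_session", "SessionView",
           "epochs_table"]

SCHEMA_VERSION = "1.0"

_REQUIRED = [
    "/behavior/ephys", "/behavior/vigor",
    "/stimulus/v_stim", "/stimulus/v_flow", "/stimulus/epochs",
    "/state/s", "/neural/dff", "/neural/frame_t", "/neural/regions",
]


def epochs_table(trials) -> pd.DataFrame:
    """Stimulus epoch log (one row per trial epoch) from trial records."""
    rows = []
    for t in trials:
        for epoch, on, off in (("evoke", t.evoke_on, t.evoke_off),
                               ("pause", t.pause_on, t.pause_off),
                               ("probe", t.probe_on, t.probe_off)):
            rows.append({"trial_id": t.trial_id, "trial_type": t.trial_type,
                         "epoch": epoch, "on": on, "off": off})
    return pd.DataFrame(rows)


def write_session(path, session: Session) -> None:
    """Write a simulated session to an HDF5 container (atomic: temp + rename)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with h5py.File(tmp, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config"] = session.config_json()
        beh = f.create_group("behavior")
        d = beh.create_dataset("ephys", data=session.ephys.y)
        d.attrs["fs"] = session.ephys.fs
        d = beh.create_dataset("vigor", data=session.vigor)
        d.attrs["dt"] = session.dt
        stim = f.create_group("stimulus")
        stim.create_dataset("v_stim", data=session.v_stim)
        stim.create_dataset("v_flow", data=session.v_flow)
        ep = epochs_table(session.trials)
        stim.create_dataset("epochs", data=_frame_to_struct(ep))
        st = f.create_group("state")
        st.create_dataset("s", data=session.state.s)
        st["s"].attrs["tau_a"] = session.state.tau_a
        st["s"].attrs["gain_k"] = session.state.gain_k
        neu = f.create_group("neural")
        d = neu.create_dataset("dff", data=session.dff)
        d.attrs["fs_img"] = session.fs_img
        neu.create_dataset("frame_t", data=session.frame_t)
        neu.create_dataset("regions",
                           data=np.array(session.regions, dtype="S16"))
        tr = f.create_group("truth")
        tr.create_dataset("bouts", data=np.array(
            [[b.onset, b.offset, b.vigor] for b in session.bouts]))
        tr.create_dataset("cell_class",
                          data=np.array(session.truth.cell_class, dtype="S16"))
        tr.create_dataset("cell_gain", data=session.truth.cell_gain)
        tr.create_dataset("latencies", data=session.truth.latencies)
        tr.create_dataset("censored",
                          data=session.truth.censored.astype(np.int8))
        tr.create_dataset("trial_types",
                          data=np.array(session.truth.trial_types, dtype="S16"))
    tmp.replace(path)


def _frame_to_struct(df: pd.DataFrame) -> np.ndarray:
    dt = np.dtype([("trial_id", "i8"), ("trial_type", "S16"),
                   ("epoch", "S16"), ("on", "f8"), ("off", "f8")])
    arr = np.empty(len(df), dtype=dt)
    arr["trial_id"] = df["trial_id"].to_numpy()
    arr["trial_type"] = df["trial_type"].astype(str).to_numpy().astype("S16")
    arr["epoch"] = df["epoch"].astype(str).to_numpy().astype("S16")
    arr["on"] = df["on"].to_numpy()
    arr["off"] = df["off"].to_numpy()
    return arr


class SessionView:
    """Validated read-only view of a session container.

    Arrays are loaded lazily via properties; :meth:`close` releases the file.
    """

    def __init__(self, path):
        self.path = Path(path)
        try:
            self._f = h5py.File(self.path, "r")
        except OSError as exc:
            raise SchemaError(f"cannot open {self.path}: {exc}") from exc
        version = self._f.attrs.get("schema_version")
        if version is None:
            raise SchemaError("container has no schema_version attribute")
        if str(version) != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {version!r} unsupported; expected "
                f"{SCHEMA_VERSION} (regenerate the session with this package)")
        for name in _REQUIRED:
            if name not in self._f:
                raise SchemaError(f"container missing dataset {name}")

    def close(self) -> None:
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    @property
    def config(self) -> dict:
        return json.loads(self._f.attrs["config"])

    @property
    def ephys(self) -> EphysTrace:
        d = self._f["/behavior/ephys"]
        return EphysTrace(y=d[...], fs=float(d.attrs["fs"]))

    @property
    def dt(self) -> float:
        return float(self._f["/behavior/vigor"].attrs["dt"])

    @property
    def vigor(self) -> np.ndarray:
        return self._f["/behavior/vigor"][...]

    @property
    def v_stim(self) -> np.ndarray:
        return self._f["/stimulus/v_stim"][...]

    @property
    def v_flow(self) -> np.ndarray:
        return self._f["/stimulus/v_flow"][...]

    @property
    def epochs(self) -> pd.DataFrame:
        arr = self._f["/stimulus/epochs"][...]
        df = pd.DataFrame(arr)
        for col in ("trial_type", "epoch"):
            df[col] = df[col].str.decode("utf-8")
        return df

    @property
    def state_s(self) -> np.ndarray:
        return self._f["/state/s"][...]

    @property
    def dff(self) -> np.ndarray:
        return self._f["/neural/dff"][...]

    @property
    def fs_img(self) -> float:
        return float(self._f["/neural/dff"].attrs["fs_img"])

    @property
    def frame_t(self) -> np.ndarray:
        return self._f["/neural/frame_t"][...]

    @property
    def regions(self) -> np.ndarray:
        return self._f["/neural/regions"][...].astype("U16")

    @property
    def truth_bouts(self) -> list[Bout]:
        arr = self._f["/truth/bouts"][...]
        return [Bout(onset=r[0], offset=r[1], vigor=r[2]) for r in arr]

    @property
    def truth_cell_class(self) -> np.ndarray:
        return self._f["/truth/cell_class"][...].astype("U16")

    @property
    def detected_bouts(self) -> list[Bout] | None:
        if "/behavior/bouts" not in self._f:
            return None
        arr = self._f["/behavior/bouts"][...]
        return [Bout(onset=r[0], offset=r[1], vigor=r[2]) for r in arr]


def read_session(path) -> SessionView:
    """Open and validate a session container."""
    return SessionView(path)


def append_bouts(path, bouts) -> None:
    """Append (or replace) the detected-bouts table in a container."""
    with h5py.File(path, "a") as f:
        if "/behavior/bouts" in f:
            del f["/behavior/bouts"]
        f.create_dataset("/behavior/bouts", data=np.array(
            [[b.onset, b.offset, b.vigor] for b in bouts]))
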