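"""CSV readers and writers for schedules, traces and trial records.

Dialects (all RFC-4180 compatible, comma separated, one header row):

* proportional schedule: ``time,u_f,u_e`` — strictly increasing times,
  excitations in [0, 1]; expanded to the simulation grid by zero-order hold;
* bang-bang schedule: ``t_on,t_off,side`` with side ``flexor``/``extensor``;
* envelope trace: ``time,volts``;
* trial record: one CSV per trial (``trial_<k>.csv``) with angles in
  degrees, plus a session-level ``summary.csv``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .control import ControlSample
from .errors import InputValidationError
from .task import TaskParams, TrialRecord, summarize_session

__all__ = [
    "read_control_schedule",
    "expand_proportional",
    "write_proportional_schedule",
    "write_bang_bang_schedule",
    "write_trial_csv",
    "read_trial_csv",
    "write_session",
]

DEG = math.pi / 180.0


def read_control_schedule(path, kind: str):
    """Read a control-schedule CSV.

    ``kind='proportional'`` returns a DataFrame ``time,u_f,u_e``;
    ``kind='bang_bang'`` returns a list of ``(t_on, t_off, side)`` tuples.
    Malformed rows raise :class:`InputValidationError` naming the row.
    """
    if kind == "proportional":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"time", "u_f", "u_e"}
        if not required.issubset(df.columns):
            raise InputValidationError(f"proportional schedule needs columns {sorted(required)}")
        times = df["time"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            row = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise InputValidationError(f"non-monotone time at row {row + 1} of {path}")
        for col in ("u_f", "u_e"):
            vals = df[col].to_numpy(dtype=float)
            bad = np.flatnonzero((vals < 0) | (vals > 1))
            if bad.size:
                raise InputValidationError(
                    f"{col} outside [0, 1] at row {int(bad[0]) + 1} of {path}"
                )
        return df
    if kind == "bang_bang":
        df = pd.read_csv(path)
        required = {"t_on", "t_off", "side"}
        if not required.issubset(df.columns):
            raise InputValidationError(f"bang-bang schedule needs columns {sorted(required)}")
        out = []
        for i, row in df.iterrows():
            side = str(row["side"]).strip()
            if side not in ("flexor", "extensor"):
                raise InputValidationError(f"bad side {side!r} at row {i + 1} of {path}")
            out.append((float(row["t_on"]), float(row["t_off"]), side))
        return out
    raise InputValidationError(f"unknown schedule kind {kind!r}")


def expand_proportional(df: pd.DataFrame, dt: float, duration: float) -> list[ControlSample]:
    """Zero-order-hold expansion of a sparse schedule to the dt grid.

    Each row takes effect at the nearest grid sample (half-step tolerance),
    so schedules recorded on the same grid replay sample-exactly.
    """
    n = round(duration / dt) + 1
    times = np.arange(n) * dt
    sched_t = df["time"].to_numpy(dtype=float)
    idx = np.clip(np.searchsorted(sched_t, times + dt / 2, side="right") - 1, 0, len(sched_t) - 1)
    u_f = df["u_f"].to_numpy(dtype=float)[idx]
    u_e = df["u_e"].to_numpy(dtype=float)[idx]
    # before the first scheduled time the stream is silent
    silent = times + dt / 2 < sched_t[0]
    u_f[silent] = 0.0
    u_e[silent] = 0.0
    return [ControlSample(u_f=float(f), u_e=float(e)) for f, e in zip(u_f, u_e)]


def write_proportional_schedule(samples: Sequence[ControlSample], dt: float, path) -> None:
    df = pd.DataFrame(
        {
            "time": np.arange(len(samples)) * dt,
            "u_f": [s.u_f for s in samples],
            "u_e": [s.u_e for s in samples],
        }
    )
    df.to_csv(path, index=False)


def write_bang_bang_schedule(schedule, path) -> None:
    df = pd.DataFrame(schedule, columns=["t_on", "t_off", "side"])
    df.to_csv(path, index=False)


def _record_frame(record: TrialRecord) -> pd.DataFrame:
    df = record.to_frame()
    df["theta"] = df["theta"] / DEG
    df["omega"] = df["omega"] / DEG
    return df.rename(columns={"theta": "theta_deg", "omega": "omega_deg_s"})


def write_trial_csv(record: TrialRecord, path) -> None:
    """Write one trial's full time series (angles in degrees) to CSV."""
    _record_frame(record).to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_session(records: Sequence[TrialRecord], out_dir, tp: TaskParams | None = None) -> Path:
    """Write per-trial CSVs plus ``summary.csv``; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, rec in enumerate(records, start=1):
        write_trial_csv(rec, out / f"trial_{k}.csv")
    summarize_session(records, tp).to_csv(out / "summary.csv", index=False)
    return out
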