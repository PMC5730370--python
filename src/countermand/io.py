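"""Plain-text session container.

One directory per session:

* ``trials.csv`` — the trial table (times in integer ms on the per-trial
  clock; the trigger stimulus defines time 0, so the instruction cue is
  negative).
* ``spikes/unitNNN.csv`` — ``trial_id, spike_time_ms`` rows per unit.
* ``emg/<muscle>.csv`` — ``trial_id, t_start, value`` long format at 1 kHz.
* ``eye.csv`` — ``trial_id, t, x, y`` at 240 Hz.
* ``meta.yaml`` — seed, generative parameters, ground-truth labels,
  chamber coordinates.

CSV dialect is RFC 4180, UTF-8, '.' decimal.  Reading validates structure
(known outcomes, monotone spike times, no dangling trial references) and
raises :class:`countermand.errors.ValidationError` naming the offending
file and row.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .session import (
    OUTCOMES,
    TRIAL_COLUMNS,
    ChamberCoords,
    ContinuousTrace,
    EyeTrace,
    Session,
    UnitData,
)

__all__ = ["write_session", "read_session"]


def write_session(session: Session, path) -> None:
    """Write a session directory (created if needed)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(root / "trials.csv", index=False)

    if session.units:
        (root / "spikes").mkdir(exist_ok=True)
    for unit in session.units:
        rows = [
            (tid, t)
            for tid in sorted(unit.spikes)
            for t in np.asarray(unit.spikes[tid], dtype=float)
        ]
        df = pd.DataFrame(rows, columns=["trial_id", "spike_time_ms"])
        df.to_csv(root / "spikes" / f"unit{unit.unit_id:03d}.csv", index=False,
                  float_format="%.3f")

    if session.emg:
        (root / "emg").mkdir(exist_ok=True)
    for muscle, traces in session.emg.items():
        parts = []
        for tid in sorted(traces):
            tr = traces[tid]
            parts.append(pd.DataFrame({
                "trial_id": tid,
                "t": tr.times.astype(int),
                "value": tr.values,
            }))
        pd.concat(parts, ignore_index=True).to_csv(
            root / "emg" / f"{muscle}.csv", index=False, float_format="%.4f")

    if session.eye:
        parts = []
        for tid in sorted(session.eye):
            tr = session.eye[tid]
            parts.append(pd.DataFrame({
                "trial_id": tid, "t": tr.times, "x": tr.x, "y": tr.y,
            }))
        pd.concat(parts, ignore_index=True).to_csv(root / "eye.csv", index=False,
                                                   float_format="%.4f")

    meta = dict(session.meta)
    meta["time_convention"] = "ms, per-trial clock, trigger stimulus at 0"
    meta["units"] = {
        int(u.unit_id): {
            "archetype": u.archetype,
            "coords": {
                "anterior_posterior": float(u.coords.anterior_posterior),
                "medial_lateral": float(u.coords.medial_lateral),
                "depth": float(u.coords.depth),
            },
        }
        for u in session.units
    }
    with open(root / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def _check_trials(trials: pd.DataFrame, path: Path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if trials["trial_id"].duplicated().any():
        dup = trials.loc[trials["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate trial_id {dup}")
    bad = ~trials["outcome"].isin(OUTCOMES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {row + 2}: unknown outcome {trials['outcome'].iloc[row]!r}"
        )
    switched = trials["has_switch"].astype(bool)
    if trials.loc[switched, "ssd"].isna().any() or \
            trials.loc[~switched, "ssd"].notna().any():
        raise ValidationError(f"{path}: ssd must be present iff has_switch")


def read_session(path) -> Session:
    """Read and validate a session directory."""
    root = Path(path)
    trials_path = root / "trials.csv"
    if not trials_path.exists():
        raise ValidationError(f"{trials_path} not found")
    trials = pd.read_csv(trials_path)
    trials["torque_direction"] = trials.get(
        "torque_direction", pd.Series([""] * len(trials))).fillna("")
    trials["has_switch"] = trials["has_switch"].astype(bool)
    _check_trials(trials, trials_path)
    ids = set(trials["trial_id"].astype(int))

    meta_path = root / "meta.yaml"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    unit_meta = meta.get("units", {})

    units = []
    spikes_dir = root / "spikes"
    if spikes_dir.exists():
        for f in sorted(spikes_dir.glob("unit*.csv")):
            m = re.match(r"unit(\d+)\.csv", f.name)
            if not m:
                raise ValidationError(f"{f}: unrecognized unit file name")
            uid = int(m.group(1))
            df = pd.read_csv(f)
            spikes: Dict[int, np.ndarray] = {}
            for row_offset, (tid, grp) in enumerate(df.groupby("trial_id", sort=True)):
                tid = int(tid)
                if tid not in ids:
                    first = int(grp.index[0]) + 2
                    raise ValidationError(
                        f"{f}: row {first}: spike references unknown trial {tid}"
                    )
                arr = grp["spike_time_ms"].to_numpy(dtype=float)
                if np.any(np.diff(arr) < 0):
                    bad = int(grp.index[int(np.flatnonzero(np.diff(arr) < 0)[0]) + 1]) + 2
                    raise ValidationError(
                        f"{f}: row {bad}: non-monotone spike times in trial {tid}"
                    )
                spikes[tid] = arr
            info = unit_meta.get(uid, {})
            coords = info.get("coords", {})
            units.append(UnitData(
                unit_id=uid,
                spikes=spikes,
                coords=ChamberCoords(
                    coords.get("anterior_posterior", 0.0),
                    coords.get("medial_lateral", 0.0),
                    coords.get("depth", 0.0),
                ),
                archetype=info.get("archetype"),
            ))

    emg: Dict[str, Dict[int, ContinuousTrace]] = {}
    emg_dir = root / "emg"
    if emg_dir.exists():
        for f in sorted(emg_dir.glob("*.csv")):
            muscle = f.stem
            df = pd.read_csv(f)
            traces: Dict[int, ContinuousTrace] = {}
            for tid, grp in df.groupby("trial_id", sort=True):
                tid = int(tid)
                if tid not in ids:
                    raise ValidationError(
                        f"{f}: EMG references unknown trial {tid}")
                traces[tid] = ContinuousTrace(
                    trial_id=tid, channel=muscle,
                    t_start=float(grp["t"].iloc[0]), fs=1000.0,
                    values=grp["value"].to_numpy(dtype=float),
                )
            emg[muscle] = traces

    eye: Dict[int, EyeTrace] = {}
    eye_path = root / "eye.csv"
    if eye_path.exists():
        df = pd.read_csv(eye_path)
        for tid, grp in df.groupby("trial_id", sort=True):
            tid = int(tid)
            if tid not in ids:
                raise ValidationError(f"{eye_path}: eye data references unknown trial {tid}")
            t = grp["t"].to_numpy(dtype=float)
            fs = 1000.0 / float(np.median(np.diff(t))) if t.size > 1 else 240.0
            eye[tid] = EyeTrace(trial_id=tid, t_start=float(t[0]), fs=fs,
                                x=grp["x"].to_numpy(dtype=float),
                                y=grp["y"].to_numpy(dtype=float))

    meta.pop("units", None)
    return Session(trials=trials, units=units, emg=emg, eye=eye, meta=meta)
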