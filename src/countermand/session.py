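"""In-memory containers for countermanding sessions.

A session bundles a trial table (one row per trial), per-unit spike
timestamps, optional EMG envelopes and eye-position traces, and free-form
metadata.  All times are milliseconds on a per-trial clock whose origin is
the go *trigger* stimulus (the event that starts the reaction-time race), so
the instruction cue sits at negative times and the switch signal, when
present, at ``t_switch == ssd``.

The trial table is a plain :class:`pandas.DataFrame` with the columns listed
in :data:`TRIAL_COLUMNS`; every analysis function in the package accepts it
directly so sessions loaded from disk and sessions built in memory are
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

#: Canonical trial-table columns.  Times are integer ms relative to the
#: trigger; absent events are NaN.
TRIAL_COLUMNS = [
    "trial_id",        # int, unique, ordered
    "instruction",     # "go" | "nogo"
    "has_switch",      # bool
    "ssd",             # switch-signal delay, ms (NaN when has_switch is False)
    "rt",              # reaction time, ms, from the effective go stimulus
    "outcome",         # see OUTCOMES
    "t_instruction",   # instruction-cue onset (< 0)
    "t_target",        # peripheral-target onset (< 0)
    "t_trigger",       # always 0 by convention
    "t_switch",        # == ssd when present
    "t_movement",      # movement onset (cursor exits start window)
    "t_outcome",       # reward or error signal
    "t_torque",        # torque-impulse onset (pre-instruction), NaN if none
    "torque_direction",  # "flexion" | "extension" | ""
    "t_start",         # first recorded ms of the trial
    "t_end",           # one past the last recorded ms
]

OUTCOMES = (
    "go_correct",
    "nogo_correct",
    "switch_stop_success",
    "stop_failure",
    "switch_go_correct",
    "other_error",
)

#: Outcomes that end with reward delivery.
REWARDED_OUTCOMES = frozenset(
    {"go_correct", "nogo_correct", "switch_stop_success", "switch_go_correct"}
)


@dataclass(frozen=True)
class ChamberCoords:
    """Recording-chamber coordinates of a unit, in millimetres."""

    anterior_posterior: float
    medial_lateral: float
    depth: float

    def __post_init__(self) -> None:
        for v in (self.anterior_posterior, self.medial_lateral, self.depth):
            if not np.isfinite(v):
                raise ValueError("chamber coordinates must be finite")


@dataclass
class UnitData:
    """Spike timestamps of one isolated unit, keyed by trial.

    ``spikes`` maps ``trial_id`` to a sorted float array of spike times on
    that trial's clock.  ``archetype`` carries the generative ground-truth
    label for synthetic units and is ``None`` for recorded data.
    """

    unit_id: int
    spikes: Dict[int, np.ndarray]
    coords: ChamberCoords
    archetype: Optional[str] = None

    def spike_trains(self, trial_ids) -> List[np.ndarray]:
        empty = np.empty(0)
        return [np.asarray(self.spikes.get(int(t), empty), dtype=float)
                for t in trial_ids]


@dataclass
class ContinuousTrace:
    """A uniformly sampled nonnegative envelope (e.g. rectified EMG)."""

    trial_id: int
    channel: str
    t_start: float          # time of values[0], trial clock, ms
    fs: float               # samples per second
    values: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.values.size) * 1000.0 / self.fs


@dataclass
class EyeTrace:
    """Horizontal/vertical eye position (degrees) sampled at ``fs`` Hz."""

    trial_id: int
    t_start: float
    fs: float
    x: np.ndarray
    y: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.x.size) * 1000.0 / self.fs

    def velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete-derivative velocity in deg/s (central differences)."""
        dt = 1.0 / self.fs
        return np.gradient(self.x, dt), np.gradient(self.y, dt)


@dataclass
class Session:
    """A complete behavioral + electrophysiological session."""

    trials: pd.DataFrame
    units: List[UnitData] = field(default_factory=list)
    emg: Dict[str, Dict[int, ContinuousTrace]] = field(default_factory=dict)
    eye: Dict[int, EyeTrace] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        """Cheap structural checks; raises ``ValueError`` on violation."""
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        ids = set(self.trials["trial_id"].astype(int))
        for unit in self.units:
            dangling = set(unit.spikes) - ids
            if dangling:
                raise ValueError(
                    f"unit {unit.unit_id} references unknown trials {sorted(dangling)[:5]}"
                )


def trial_group(trials: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Rows of ``trials`` with the given outcome."""
    return trials[trials["outcome"] == outcome]
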