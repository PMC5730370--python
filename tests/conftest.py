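"""Shared fixtures: one simulated session's trial table and unit builders.

Everything is generated programmatically at collection time from fixed
seeds; no data files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from countermand import (
    ChamberCoords,
    PipelineConfig,
    RaceModelParams,
    UnitData,
    simulate_race_trials,
)
from countermand.simulate import default_archetype, simulate_spike_train


@pytest.fixture(scope="session")
def race_params() -> RaceModelParams:
    return RaceModelParams()


@pytest.fixture(scope="session")
def trials(race_params):
    """One 600-trial session under the default race parameters."""
    return simulate_race_trials(race_params, seed=1)


@pytest.fixture(scope="session")
def trial_rows(trials):
    return [r._asdict() for r in trials.itertuples(index=False)]


@pytest.fixture()
def cfg_small() -> PipelineConfig:
    """Pipeline configuration at exploratory scale (fewer resamples)."""
    return PipelineConfig(n_shuffles=15, n_boot=20, n_null_resamples=10,
                          max_event_trials=80, eye_n_shuffle=100,
                          eye_step=25.0, seed=0)


@pytest.fixture(scope="session")
def unit_factory(trial_rows):
    """Build a synthetic unit of a given archetype over the shared session."""

    def build(kind: str, rng: np.random.Generator, unit_id: int = 0,
              **overrides) -> UnitData:
        arch = default_archetype(kind, **overrides)
        spikes = {
            int(r["trial_id"]): simulate_spike_train(arch, r, rng)
            for r in trial_rows
        }
        return UnitData(unit_id=unit_id, spikes=spikes,
                        coords=ChamberCoords(0.0, 0.0, 22.0), archetype=kind)

    return build
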