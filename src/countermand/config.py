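"""Pipeline configuration.

All tunables of the analysis chain live here with their standard defaults:
a 20 ms Gaussian kernel for spike density functions, a 60 ms ROC test window
stepped at 1 ms, a 500 ms pre-event control period with a two-tailed t-band
at alpha = 0.01, 1000 pseudo-SSD shuffles for latency matching, 1000
bootstrap replicates for cancellation-time confidence intervals, 28 ms SSD
bins with at most six retained for the quantile SSRT, a 200 ms latency bound
for torque responses, a 500 ms window for outcome responses, and a 50 ms
window stepped over -500..+1000 ms for the eye regression.

Analyses at exploratory scale can lower ``n_shuffles``, ``n_boot``,
``n_null_resamples`` and ``eye_n_shuffle`` without touching the statistical
machinery; estimates get noisier but remain unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    # spike density
    kernel_width: float = 20.0          # Gaussian sigma, ms

    # sliding-window ROC
    window: float = 60.0                # test-window width, ms
    step: float = 1.0                   # window step, ms
    control_span: float = 500.0         # control period preceding the event, ms
    alpha: float = 0.01                 # two-tailed threshold for the AUC band
    persistence_ms: float = 20.0        # sustained-excursion requirement
    post_window: float = 400.0          # post-switch search span, ms
    min_trials: int = 10                # minimum trials per ROC condition

    # latency matching / bootstrap
    n_shuffles: int = 1000              # pseudo-SSD shuffles
    n_boot: int = 1000                  # bootstrap replicates for the CI
    ssd_range: Tuple[float, float] = (200.0, 450.0)

    # behavior
    ssd_bin: float = 28.0               # inhibition-function bin width, ms
    max_bins: int = 6                   # SSD bins retained for the SSRT mean
    min_go_trials: int = 50

    # classification
    torque_latency_bound: float = 200.0
    outcome_window: float = 500.0
    n_null_resamples: int = 1000        # circular-shift resamples for torque/outcome nulls
    max_event_trials: int | None = None  # subsample cap per event-test condition
    delay_exclude: float = 100.0        # post-instruction transient excluded from Go/NoGo test
    delay_end: float = 1600.0           # end of Go/NoGo test interval, ms after instruction
    delay_persistence_ms: float = 100.0  # sustained requirement for the delay-period contrast
    stop_switch_margin: float = 100.0   # stop-vs-switch window is [0, SSRT + margin]

    # eye regression
    eye_window: float = 50.0
    eye_range: Tuple[float, float] = (-500.0, 1000.0)
    eye_step: float = 1.0
    eye_n_shuffle: int = 1000
    eye_min_trials: int = 30

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError("alpha must be in (0, 1]")
        if self.window <= 0 or self.step <= 0:
            raise ConfigurationError("window and step must be positive")
        if self.ssd_range[0] >= self.ssd_range[1]:
            raise ConfigurationError("ssd_range must be increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ssd_range"] = list(self.ssd_range)
        d["eye_range"] = list(self.eye_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("ssd_range", "eye_range"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)
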