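"""Synthetic Go/NoGo-countermanding sessions with known ground truth.

The generator reproduces the statistical structure the analysis chain
assumes, so that every downstream stage can be validated against generative
truth:

* **Behavior** follows the independent-race model.  On each go-instruction
  trial a go finish time (the would-be RT) is drawn from a shifted lognormal;
  on switch trials a stop finish time ``SSD + ssrt_true`` races it.  The
  response is emitted iff the go process finishes first, which yields the
  canonical signatures — fast stop-failure RTs and an inhibition function
  that rises with SSD.  Switch-go RTs carry an additive preparation cost.
* **Spiking** is an inhomogeneous Poisson process realised by thinning a
  per-trial rate function composed from a cell archetype: pre-movement ramps
  truncated at stopping (``movement``), phasic switch responses
  (``switch_stop`` / ``switch_nonselective``), tonic instruction-period
  offsets (``go_tonic`` / ``nogo_tonic``), short-latency proprioceptive
  responses (``torque``), reward-locked responses (``outcome``), and a flat
  ``null``.
* **EMG** envelopes emulate agonist relaxation and antagonist bursting
  around stopping; **eye** traces are saccadic position signals optionally
  coupled linearly to a unit's firing for regression power checks.

Trial event times are integer milliseconds on a per-trial clock with the
trigger stimulus at 0.  SSDs are drawn uniformly on a 1 ms grid over
200-450 ms and switch signals occur on 25% of trials of either instruction,
with >600 trials per session by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .session import (
    TRIAL_COLUMNS,
    ChamberCoords,
    ContinuousTrace,
    EyeTrace,
    Session,
    UnitData,
)

ARCHETYPE_KINDS = (
    "movement",
    "switch_stop",
    "switch_nonselective",
    "go_tonic",
    "nogo_tonic",
    "torque",
    "outcome",
    "null",
)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RTDistribution:
    """Go finish-time distribution.

    ``lognormal``: ``shift + LogNormal(ln(location), scale)`` so ``location``
    is the median of the unshifted part and the overall median is
    ``shift + location``.  ``point``: a point mass at ``location + shift``
    (useful for deterministic race fixtures).
    """

    family: str = "lognormal"
    location: float = 330.0   # ms; with shift 250 the overall median is 580
    scale: float = 0.25       # sigma in log units
    shift: float = 250.0      # ms

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "point"):
            raise ConfigurationError(f"unknown RT family {self.family!r}")
        if self.family == "lognormal" and (self.location <= 0 or self.scale <= 0):
            raise ConfigurationError("lognormal RT needs positive location and scale")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.location + self.shift)
        return self.shift + rng.lognormal(math.log(self.location), self.scale, size)

    @property
    def median(self) -> float:
        return self.location + self.shift


@dataclass(frozen=True)
class RaceModelParams:
    """Generative parameters of the behavioral race."""

    go_rt_dist: RTDistribution = RTDistribution()
    ssrt_true: float = 160.0
    ssd_range: Tuple[float, float] = (200.0, 450.0)
    ssd_resolution: float = 1.0
    p_switch: float = 0.25
    p_go_instruction: float = 0.5
    n_trials: int = 600
    prep_cost_true: float = 60.0
    p_torque: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.ssrt_true < 0:
            raise ConfigurationError("ssrt_true must be >= 0")
        if self.ssd_range[0] >= self.ssd_range[1]:
            raise ConfigurationError("ssd_range must satisfy min < max")
        for name in ("p_switch", "p_go_instruction", "p_torque"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be positive")
        if self.ssd_resolution <= 0:
            raise ConfigurationError("ssd_resolution must be positive")


@dataclass(frozen=True)
class CellArchetype:
    """Rate-function recipe for one synthetic unit.

    ``effect_onset`` is relative to the archetype's anchoring event (switch
    signal, instruction, torque impulse, reward, or movement onset for the
    ``movement`` kind, whose onset is negative: the ramp starts that many ms
    before movement).  ``effect_duration`` of ``None`` means "until the
    trigger" for the tonic kinds.
    """

    kind: str = "null"
    baseline_rate: float = 20.0       # spikes/s
    effect_amplitude: float = 40.0    # spikes/s above baseline
    effect_onset: float = 80.0        # ms relative to anchoring event
    effect_duration: Optional[float] = 120.0
    truncation_latency: float = 80.0  # movement kind: ramp cut this long after the switch

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPE_KINDS:
            raise ConfigurationError(f"unknown archetype kind {self.kind!r}")
        if self.baseline_rate < 0 or self.effect_amplitude < 0:
            raise ConfigurationError("rates must be nonnegative")


def default_archetype(kind: str, **overrides) -> CellArchetype:
    """A plausibly scaled archetype of the given kind."""
    presets = {
        "movement": dict(baseline_rate=20.0, effect_amplitude=40.0,
                         effect_onset=-400.0, effect_duration=100.0,
                         truncation_latency=80.0),
        "switch_stop": dict(baseline_rate=15.0, effect_amplitude=45.0,
                            effect_onset=80.0, effect_duration=120.0),
        "switch_nonselective": dict(baseline_rate=15.0, effect_amplitude=45.0,
                                    effect_onset=80.0, effect_duration=120.0),
        "go_tonic": dict(baseline_rate=20.0, effect_amplitude=15.0,
                         effect_onset=100.0, effect_duration=None),
        "nogo_tonic": dict(baseline_rate=20.0, effect_amplitude=15.0,
                           effect_onset=100.0, effect_duration=None),
        "torque": dict(baseline_rate=20.0, effect_amplitude=50.0,
                       effect_onset=40.0, effect_duration=80.0),
        "outcome": dict(baseline_rate=20.0, effect_amplitude=30.0,
                        effect_onset=150.0, effect_duration=250.0),
        "null": dict(baseline_rate=20.0, effect_amplitude=0.0),
    }
    kw = dict(presets[kind])
    kw.update(overrides)
    return CellArchetype(kind=kind, **kw)


# Chamber-coordinate clouds (mm) emulating the anatomical segregation of
# response types: switch-related cells ventromedial/anterior, movement- and
# torque-responsive cells dorso-postero-lateral, others diffuse.
_COORD_CLOUDS = {
    "switch_stop": ((2.0, 3.0, 24.0), 0.6),
    "switch_nonselective": ((2.0, 3.2, 24.0), 0.6),
    "movement": ((-1.5, 6.5, 21.0), 1.0),
    "torque": ((-2.0, 7.0, 20.5), 1.0),
    "go_tonic": ((0.0, 5.0, 22.0), 1.8),
    "nogo_tonic": ((0.0, 5.0, 22.0), 1.8),
    "outcome": ((0.5, 4.5, 22.5), 1.8),
    "null": ((0.0, 5.0, 22.0), 1.8),
}


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_race_trials(params: RaceModelParams, seed) -> pd.DataFrame:
    """Simulate the trial table of one session under the race model.

    Returns a DataFrame with :data:`countermand.session.TRIAL_COLUMNS`.
    Event times are integer ms, trigger at 0.  On switch-stop trials the
    response is emitted (``stop_failure``) iff the drawn go finish time beats
    the deterministic stop finish time ``SSD + ssrt_true``; otherwise the
    trial is a ``switch_stop_success`` with no RT.  Switch-go RTs (measured
    from the switch signal, the effective go stimulus on those trials) are
    prolonged by ``prep_cost_true``.
    """
    rng = np.random.default_rng(seed)
    n = params.n_trials

    instr_go = rng.random(n) < params.p_go_instruction
    has_switch = rng.random(n) < params.p_switch

    lo, hi = params.ssd_range
    n_grid = int(round((hi - lo) / params.ssd_resolution)) + 1
    ssd = lo + params.ssd_resolution * rng.integers(0, n_grid, n)
    ssd = np.where(has_switch, ssd, np.nan)

    rt_draw = np.round(params.go_rt_dist.sample(rng, n))

    # pre-trigger timeline: instruction (0.5 s) -> 0.7-1.3 s gap -> target ->
    # 0.5-1.5 s gap -> trigger at 0
    gap_target = rng.integers(700, 1301, n)
    gap_trigger = rng.integers(500, 1501, n)
    t_target = -gap_trigger.astype(float)
    t_instruction = t_target - gap_target - 500.0

    # torque impulses land between initial capture and the instruction cue
    has_torque = rng.random(n) < params.p_torque
    t_torque = t_instruction - rng.integers(200, 1101, n)
    t_torque = np.where(has_torque, t_torque, np.nan)
    torque_dir = np.where(
        has_torque, np.where(rng.random(n) < 0.5, "flexion", "extension"), ""
    )

    outcome = np.empty(n, dtype=object)
    rt = np.full(n, np.nan)
    t_movement = np.full(n, np.nan)

    go_plain = instr_go & ~has_switch
    outcome[go_plain] = "go_correct"
    rt[go_plain] = rt_draw[go_plain]
    t_movement[go_plain] = rt_draw[go_plain]

    sw_stop = instr_go & has_switch
    failed = sw_stop & (rt_draw < ssd + params.ssrt_true)
    outcome[failed] = "stop_failure"
    rt[failed] = rt_draw[failed]
    t_movement[failed] = rt_draw[failed]
    stopped = sw_stop & ~failed
    outcome[stopped] = "switch_stop_success"

    nogo_plain = ~instr_go & ~has_switch
    outcome[nogo_plain] = "nogo_correct"

    sw_go = ~instr_go & has_switch
    outcome[sw_go] = "switch_go_correct"
    rt[sw_go] = rt_draw[sw_go] + params.prep_cost_true
    t_movement[sw_go] = ssd[sw_go] + rt[sw_go]

    # reward/error signal
    t_outcome = np.full(n, np.nan)
    moved = ~np.isnan(t_movement)
    reward_after_move = rng.integers(700, 1301, n)
    hold_reward = rng.integers(1300, 1901, n)
    err_delay = rng.integers(150, 251, n)
    t_outcome[go_plain | sw_go] = (t_movement + reward_after_move)[go_plain | sw_go]
    t_outcome[failed] = (t_movement + err_delay)[failed]
    t_outcome[nogo_plain] = hold_reward[nogo_plain]
    t_outcome[stopped] = (ssd + hold_reward)[stopped]
    del moved

    t_start = t_instruction - 2000.0
    t_end = t_outcome + 800.0

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n, dtype=int),
            "instruction": np.where(instr_go, "go", "nogo"),
            "has_switch": has_switch,
            "ssd": ssd,
            "rt": rt,
            "outcome": outcome,
            "t_instruction": t_instruction,
            "t_target": t_target,
            "t_trigger": np.zeros(n),
            "t_switch": ssd,
            "t_movement": t_movement,
            "t_outcome": t_outcome,
            "t_torque": t_torque,
            "torque_direction": torque_dir,
            "t_start": t_start,
            "t_end": t_end,
        },
        columns=TRIAL_COLUMNS,
    )
    return trials


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

def _smooth_pulse(t: np.ndarray, onset: float, duration: float,
                  amplitude: float, edge: float = 10.0) -> np.ndarray:
    """Boxcar of height ``amplitude`` with raised-cosine edges."""
    out = np.zeros_like(t)
    if duration <= 0 or amplitude == 0:
        return out
    rise = np.clip((t - onset) / edge, 0.0, 1.0)
    fall = np.clip((onset + duration - t) / edge, 0.0, 1.0)
    up = 0.5 - 0.5 * np.cos(np.pi * rise)
    down = 0.5 - 0.5 * np.cos(np.pi * fall)
    return amplitude * np.minimum(up, down)


def archetype_rate(archetype: CellArchetype, trial, typical_rt: float = 580.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Composed firing-rate function (spikes/s) on the trial's 1 ms grid.

    ``trial`` is a trial-table row (anything with attribute/key access to the
    trial columns).  Returns ``(t, rate)``.  Raises ``RuntimeError`` if the
    composition ever goes negative — shapes are additive and nonnegative by
    construction, so a negative rate indicates a programming error rather
    than something to clip silently.
    """
    get = trial.__getitem__ if hasattr(trial, "__getitem__") else getattr
    tr = {c: get(c) for c in TRIAL_COLUMNS}

    t = np.arange(float(tr["t_start"]), float(tr["t_end"]))
    rate = np.full(t.shape, float(archetype.baseline_rate))
    kind = archetype.kind
    amp = archetype.effect_amplitude
    outcome = tr["outcome"]
    is_go = tr["instruction"] == "go"
    has_switch = bool(tr["has_switch"])
    t_switch = tr["t_switch"]

    if kind == "movement":
        # linear ramp toward movement onset, brief plateau, exponential decay;
        # on successful stops the ramp aims at the typical RT and is cut
        # truncation_latency ms after the switch signal.
        anchor = tr["t_movement"]
        truncate_at = None
        if outcome == "switch_stop_success":
            anchor = tr["t_trigger"] + typical_rt
            truncate_at = t_switch + archetype.truncation_latency
        if not np.isnan(anchor) and is_go or outcome == "switch_go_correct":
            ramp_start = anchor + archetype.effect_onset  # onset < 0
            ramp_len = max(-archetype.effect_onset, 1.0)
            profile = np.zeros_like(t)
            rising = (t >= ramp_start) & (t < anchor)
            profile[rising] = amp * (t[rising] - ramp_start) / ramp_len
            plateau = (t >= anchor) & (t < anchor + (archetype.effect_duration or 0.0))
            profile[plateau] = amp
            decay = t >= anchor + (archetype.effect_duration or 0.0)
            profile[decay] = amp * np.exp(
                -(t[decay] - anchor - (archetype.effect_duration or 0.0)) / 80.0
            )
            if truncate_at is not None:
                cut = t >= truncate_at
                profile[cut] = profile[cut][0] * np.exp(
                    -(t[cut] - truncate_at) / 20.0
                ) if cut.any() else profile[cut]
            rate += profile

    elif kind in ("switch_stop", "switch_nonselective"):
        applies = has_switch and (is_go or kind == "switch_nonselective")
        if applies and not np.isnan(t_switch):
            rate += _smooth_pulse(
                t, t_switch + archetype.effect_onset,
                archetype.effect_duration or 0.0, amp,
            )

    elif kind in ("go_tonic", "nogo_tonic"):
        wants_go = kind == "go_tonic"
        if is_go == wants_go:
            start = tr["t_instruction"] + archetype.effect_onset
            stop = tr["t_trigger"] if archetype.effect_duration is None \
                else start + archetype.effect_duration
            rate += _smooth_pulse(t, start, stop - start, amp, edge=30.0)

    elif kind == "torque":
        if not np.isnan(tr["t_torque"]):
            rate += _smooth_pulse(
                t, tr["t_torque"] + archetype.effect_onset,
                archetype.effect_duration or 0.0, amp,
            )

    elif kind == "outcome":
        from .session import REWARDED_OUTCOMES
        if outcome in REWARDED_OUTCOMES and not np.isnan(tr["t_outcome"]):
            rate += _smooth_pulse(
                t, tr["t_outcome"] + archetype.effect_onset,
                archetype.effect_duration or 0.0, amp,
            )

    elif kind == "null":
        pass

    if (rate < 0).any():
        raise RuntimeError("composed rate went negative; archetype misconfigured")
    return t, rate


def thin_poisson(t: np.ndarray, rate: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Exact inhomogeneous-Poisson sample by thinning a homogeneous one.

    ``rate`` is piecewise constant on the 1 ms grid ``t``, so acceptance with
    probability ``rate(u)/rate_max`` is exact.
    """
    rmax = float(rate.max(initial=0.0))
    if rmax <= 0.0:
        return np.empty(0)
    span = t[-1] + 1.0 - t[0]
    n_cand = rng.poisson(rmax * span / 1000.0)
    if n_cand == 0:
        return np.empty(0)
    times = rng.uniform(t[0], t[0] + span, n_cand)
    idx = np.minimum((times - t[0]).astype(int), rate.size - 1)
    keep = rng.random(n_cand) < rate[idx] / rmax
    return np.sort(times[keep])


def simulate_spike_train(archetype: CellArchetype, trial, seed,
                         typical_rt: float = 580.0) -> np.ndarray:
    """One trial's spike timestamps for the given archetype (sorted, ms)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, rate = archetype_rate(archetype, trial, typical_rt=typical_rt)
    return thin_poisson(t, rate, rng)


# ---------------------------------------------------------------------------
# EMG and eye
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EMGParams:
    baseline: float = 0.05
    amplitude: float = 1.0            # agonist peak
    burst_amplitude: float = 0.8      # antagonist stop burst
    burst_onset: float = 80.0         # ms after the switch
    burst_duration: float = 100.0
    relax_latency: float = 60.0       # agonist decay onset after the switch
    noise: float = 0.02


def simulate_emg(trial, role: str, seed, params: EMGParams = EMGParams(),
                 typical_rt: float = 580.0) -> ContinuousTrace:
    """Rectified-EMG-like envelope at 1 kHz for one trial.

    ``agonist``: ramps up before movement onset and, on successful stops,
    relaxes rapidly after the switch signal.  ``antagonist``: emits a brief
    burst after the switch on successful stops only.
    """
    if role not in ("agonist", "antagonist"):
        raise ConfigurationError(f"unknown EMG role {role!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    get = trial.__getitem__ if hasattr(trial, "__getitem__") else getattr
    t0, t1 = float(get("t_start")), float(get("t_end"))
    t = np.arange(t0, t1)
    env = np.full(t.shape, params.baseline)
    outcome = get("outcome")
    t_move = get("t_movement")
    t_switch = get("t_switch")

    if role == "agonist":
        anchor = t_move
        truncate_at = None
        if outcome == "switch_stop_success":
            anchor = float(get("t_trigger")) + typical_rt
            truncate_at = t_switch + params.relax_latency
        if not np.isnan(anchor):
            profile = np.zeros_like(t)
            ramp_start = anchor - 300.0
            rising = (t >= ramp_start) & (t < anchor)
            profile[rising] = params.amplitude * (t[rising] - ramp_start) / 300.0
            plateau = (t >= anchor) & (t < anchor + 200.0)
            profile[plateau] = params.amplitude
            decay = t >= anchor + 200.0
            profile[decay] = params.amplitude * np.exp(-(t[decay] - anchor - 200.0) / 150.0)
            if truncate_at is not None:
                cut = t >= truncate_at
                if cut.any():
                    profile[cut] = profile[cut][0] * np.exp(-(t[cut] - truncate_at) / 30.0)
            env += profile
    else:
        if outcome == "switch_stop_success" and not np.isnan(t_switch):
            env += _smooth_pulse(
                t, t_switch + params.burst_onset, params.burst_duration,
                params.burst_amplitude,
            )

    if params.noise > 0:
        env = env + rng.normal(0.0, params.noise, env.size)
    env = np.maximum(env, 0.0)
    return ContinuousTrace(trial_id=int(get("trial_id")), channel=role,
                           t_start=t0, fs=1000.0, values=env)


def simulate_eye(trial, coupling: str = "none", seed=None,
                 saccade_rate: float = 1.5, amplitude_deg: float = 12.0,
                 noise_deg: float = 0.1) -> EyeTrace:
    """Saccadic eye-position trace at 240 Hz over the trial span.

    The trace itself is the same for either ``coupling`` value; when a
    session is built with ``position_coupled`` eye data, a dedicated unit is
    generated whose firing follows the horizontal position linearly (see
    :func:`position_coupled_spikes`), which is what the regression-control
    analysis is meant to detect.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    get = trial.__getitem__ if hasattr(trial, "__getitem__") else getattr
    t0, t1 = float(get("t_start")), float(get("t_end"))
    fs = 240.0
    n = int((t1 - t0) * fs / 1000.0)
    t = t0 + np.arange(n) * 1000.0 / fs

    n_sacc = rng.poisson(saccade_rate * (t1 - t0) / 1000.0)
    sacc_times = np.sort(rng.uniform(t0, t1, n_sacc))
    x = np.zeros(n)
    y = np.zeros(n)
    cx = cy = 0.0
    for ts in sacc_times:
        nx, ny = rng.uniform(-amplitude_deg, amplitude_deg, 2)
        # 30 ms sigmoidal transition
        w = 1.0 / (1.0 + np.exp(-np.clip((t - ts) / 7.5, -50.0, 50.0)))
        x = x + (nx - cx) * w
        y = y + (ny - cy) * w
        cx, cy = nx, ny
    if noise_deg > 0:
        x = x + rng.normal(0.0, noise_deg, n)
        y = y + rng.normal(0.0, noise_deg, n)
    return EyeTrace(trial_id=int(get("trial_id")), t_start=t0, fs=fs, x=x, y=y)


def position_coupled_spikes(trial, eye: EyeTrace, baseline: float,
                            gain: float, rng: np.random.Generator) -> np.ndarray:
    """Spikes whose rate is ``baseline + gain * x(t)`` (clipped at 0)."""
    get = trial.__getitem__ if hasattr(trial, "__getitem__") else getattr
    t = np.arange(float(get("t_start")), float(get("t_end")))
    x = np.interp(t, eye.times, eye.x)
    rate = np.maximum(baseline + gain * x, 0.0)
    return thin_poisson(t, rate, rng)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Recipe for a full synthetic session."""

    race: RaceModelParams = field(default_factory=RaceModelParams)
    units: List[CellArchetype] = field(default_factory=list)
    muscles: Dict[str, str] = field(default_factory=dict)   # name -> agonist|antagonist
    eye_coupling: Optional[str] = None                      # None|"none"|"position_coupled"
    eye_gain: float = 2.0          # Hz/deg for the position-coupled unit
    emg: EMGParams = EMGParams()
    typical_rt: float = 580.0

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "race" in d:
            race = dict(d["race"])
            if "go_rt_dist" in race:
                race["go_rt_dist"] = RTDistribution(**race["go_rt_dist"])
            if "ssd_range" in race:
                race["ssd_range"] = tuple(race["ssd_range"])
            d["race"] = RaceModelParams(**race)
        if "units" in d:
            units = []
            for u in d["units"]:
                u = dict(u)
                count = u.pop("count", 1)
                kind = u.pop("kind")
                units.extend(default_archetype(kind, **u) for _ in range(count))
            d["units"] = units
        if "emg" in d:
            d["emg"] = EMGParams(**d["emg"])
        return cls(**d)


def _draw_coords(kind: str, rng: np.random.Generator) -> ChamberCoords:
    (ap, ml, depth), sd = _COORD_CLOUDS[kind]
    ap, ml, depth = rng.normal([ap, ml, depth], sd)
    return ChamberCoords(round(ap, 2), round(ml, 2), round(depth, 2))


def simulate_session(config: SessionConfig, seed) -> Session:
    """Generate a complete session; fully reproducible given ``seed``."""
    root = np.random.SeedSequence(seed)
    s_beh, s_units, s_emg, s_eye = root.spawn(4)

    trials = simulate_race_trials(config.race, np.random.default_rng(s_beh))
    rows = list(trials.itertuples(index=False))
    row_maps = [r._asdict() for r in rows]

    eye: Dict[int, EyeTrace] = {}
    if config.eye_coupling is not None:
        erng = np.random.default_rng(s_eye)
        for tr in row_maps:
            eye[int(tr["trial_id"])] = simulate_eye(tr, config.eye_coupling, erng)

    units: List[UnitData] = []
    urng = np.random.default_rng(s_units)
    archetypes = list(config.units)
    for uid, arch in enumerate(archetypes):
        spikes = {
            int(tr["trial_id"]): simulate_spike_train(
                arch, tr, urng, typical_rt=config.typical_rt)
            for tr in row_maps
        }
        units.append(UnitData(unit_id=uid, spikes=spikes,
                              coords=_draw_coords(arch.kind, urng),
                              archetype=arch.kind))
    if config.eye_coupling == "position_coupled":
        # baseline high enough that baseline + gain*x never clips at 0
        # over the +/-12 deg fixation range, keeping the coupling linear
        base = max(30.0, config.eye_gain * 13.0)
        spikes = {
            int(tr["trial_id"]): position_coupled_spikes(
                tr, eye[int(tr["trial_id"])], base, config.eye_gain, urng)
            for tr in row_maps
        }
        units.append(UnitData(unit_id=len(units), spikes=spikes,
                              coords=_draw_coords("null", urng),
                              archetype="eye_coupled"))

    emg: Dict[str, Dict[int, ContinuousTrace]] = {}
    mrng = np.random.default_rng(s_emg)
    for muscle, role in config.muscles.items():
        emg[muscle] = {}
        for tr in row_maps:
            trace = simulate_emg(tr, role, mrng, params=config.emg,
                                 typical_rt=config.typical_rt)
            trace.channel = muscle
            emg[muscle][int(tr["trial_id"])] = trace

    meta = {
        "seed": int(seed) if np.isscalar(seed) else None,
        "race_params": _jsonable(asdict(config.race)),
        "typical_rt": config.typical_rt,
        "unit_labels": {u.unit_id: u.archetype for u in units},
        "muscles": dict(config.muscles),
        "eye_coupling": config.eye_coupling,
    }
    return Session(trials=trials, units=units, emg=emg, eye=eye, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
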