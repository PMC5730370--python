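"""Single-unit taxonomy for the countermanding task.

Each unit is screened on several orthogonal axes, all built on the same
sliding-window ROC machinery:

* **Stop involvement** — successful switch-stop trials versus latency-matched
  go trials.  A unit qualifies iff its divergence (neural cancellation) time
  precedes the SSRT; the excursion direction separates *Movement* cells
  (AUC increase: a pre-movement buildup truncated by stopping) from
  *Switch-stop* cells (AUC decrease: a phasic response to the stop cue).
* **Stop vs Switch selectivity** — for Switch-stop cells only: the same
  comparison between switch-stop and switch-go responses.  A cell is *Stop*
  if its maximal post-switch AUC deviation shows the stop response exceeding
  the switch-go response beyond the control band, otherwise *Switch*
  (attention/behavioral-switching related).
* **Go/NoGo (proactive) set** — delay-period (instruction to trigger)
  activity contrasted between go and no-go trials.
* **Torque** responsiveness — a significant response within 200 ms of a
  proprioceptive torque impulse, for at least one direction, against a
  circular-shift shuffle null.
* **Outcome** responses — the same shuffle test within 500 ms of reward or
  error delivery.

Labels are not exclusive across axes (a Torque cell may also be a Movement
cell); ``stop_pattern`` itself is single-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import AnalysisError
from .roc import (
    AUCSeries,
    CancellationResult,
    cancellation_time,
    control_threshold,
    detect_divergence,
    relative_trains,
    sliding_auc,
    stop_vs_matched_go_auc,
    window_counts,
)
from .session import ChamberCoords, UnitData

__all__ = [
    "UnitClassification",
    "PopulationTable",
    "classify_stop_involvement",
    "classify_stop_vs_switch",
    "classify_go_nogo",
    "detect_torque_response",
    "detect_outcome_response",
    "classify_unit",
    "summarize_population",
    "chi_square_independence",
]


@dataclass
class UnitClassification:
    unit_id: int
    stop_qualified: bool = False
    stop_pattern: str = "none"              # movement | switch_stop | none
    selectivity: str = "not_applicable"     # stop | switch | not_applicable
    go_nogo: str = "none"                   # go | nogo | none
    torque: bool = False
    torque_latency: Optional[float] = None
    torque_direction: Optional[str] = None
    outcome_reward: Optional[bool] = None   # None = untested
    outcome_error: Optional[bool] = None
    cancellation: Optional[CancellationResult] = None
    coords: Optional[ChamberCoords] = None
    true_label: Optional[str] = None
    reasons: Dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# axis 1: stop involvement
# ---------------------------------------------------------------------------

def classify_stop_involvement(unit: UnitData, trials: pd.DataFrame, ssrt: float,
                              cfg: PipelineConfig, rng: np.random.Generator,
                              ) -> Tuple[bool, str, CancellationResult, AUCSeries]:
    """Stop-process qualification and Movement/Switch-stop pattern.

    Runs the stop-versus-latency-matched-go AUC, detects the cancellation
    time, and qualifies the unit iff that time falls within the SSRT.  The
    pattern follows the excursion direction: with latency-matched go as the
    positive class, an AUC decrease means stop-trial firing rose above go
    (Switch-stop cell) and an AUC increase means go firing kept building
    while stop firing was truncated (Movement cell).
    """
    series, _ = stop_vs_matched_go_auc(unit, trials, ssrt, cfg, rng)
    result = detect_divergence(series, ssrt, cfg)
    qualified = result.within_ssrt
    if qualified:
        pattern = "movement" if result.direction == "auc_increase" else "switch_stop"
    else:
        pattern = "none"
    return qualified, pattern, result, series


# ---------------------------------------------------------------------------
# axis 2: stop versus switch selectivity
# ---------------------------------------------------------------------------

def classify_stop_vs_switch(unit: UnitData, trials: pd.DataFrame, ssrt: float,
                            cfg: PipelineConfig) -> Tuple[str, Optional[str]]:
    """Stop/Switch categorization of a Switch-stop-pattern unit.

    Compares switch-stop and switch-go responses in the common post-switch
    window ``[0, SSRT + margin]``, each trial aligned on its own switch
    signal.  The maximum post-switch AUC deviation decides: if it lies below
    the control band (stop response larger) and is part of a sustained
    below-band excursion (the same persistence rule used for divergence
    detection, to suppress single-step noise dips), the unit is a *Stop*
    cell; if the switch-go response is equal or greater, a *Switch* cell.
    Returns ``(selectivity, reason)``.
    """
    stop = trials[trials["outcome"] == "switch_stop_success"]
    sw_go = trials[trials["outcome"] == "switch_go_correct"]
    if len(sw_go) < cfg.min_trials:
        return "not_applicable", f"only {len(sw_go)} switch-go trials"
    if len(stop) < cfg.min_trials:
        return "not_applicable", f"only {len(stop)} switch-stop trials"

    centers = np.arange(-cfg.control_span, ssrt + cfg.stop_switch_margin + cfg.step,
                        cfg.step)
    rel_go = relative_trains(unit.spikes, sw_go["trial_id"].to_numpy(int),
                             sw_go["t_switch"].to_numpy(float))
    rel_stop = relative_trains(unit.spikes, stop["trial_id"].to_numpy(int),
                               stop["t_switch"].to_numpy(float))
    series = sliding_auc(window_counts(rel_go, centers, cfg.window),
                         window_counts(rel_stop, centers, cfg.window),
                         centers, cfg.window, cfg.step, orientation="switch_go")
    band = control_threshold(series, (-cfg.control_span, 0.0), cfg.alpha)
    post = (series.times >= 0.0) & (series.times <= ssrt + cfg.stop_switch_margin)
    auc_post = series.auc[post]
    peak = auc_post[np.argmax(np.abs(auc_post - band.control_mean))]
    sustained = cancellation_time(series, band, ssrt=float("inf"),
                                  persistence_ms=cfg.persistence_ms,
                                  search_end=ssrt + cfg.stop_switch_margin,
                                  sides="decrease")
    if peak < band.lower and sustained.cancellation_time is not None:
        return "stop", None         # stop response exceeds switch-go response
    return "switch", None


# ---------------------------------------------------------------------------
# axis 3: proactive Go/NoGo set
# ---------------------------------------------------------------------------

def classify_go_nogo(unit: UnitData, trials: pd.DataFrame, cfg: PipelineConfig,
                     ) -> Tuple[str, Optional[str], AUCSeries]:
    """Go/NoGo categorization from instructed-delay activity.

    Spike counts aligned on the instruction cue are contrasted between go
    and no-go trials with the sliding AUC, thresholded against the 500 ms
    pre-instruction baseline period of the same series.  The test interval
    starts ``delay_exclude`` ms after the instruction (skipping the visual
    transient) and a sustained excursion above the band labels the unit
    *go* (go delay activity higher), below the band *nogo*.
    """
    go = trials[trials["instruction"] == "go"]
    nogo = trials[trials["instruction"] == "nogo"]
    if len(go) < cfg.min_trials or len(nogo) < cfg.min_trials:
        dummy = AUCSeries(np.empty(0), np.empty(0), cfg.window, cfg.step, "go", 0, 0)
        return "none", "insufficient trials per instruction", dummy

    centers = np.arange(-cfg.control_span, cfg.delay_end + cfg.step, cfg.step)
    rel_go = relative_trains(unit.spikes, go["trial_id"].to_numpy(int),
                             go["t_instruction"].to_numpy(float))
    rel_nogo = relative_trains(unit.spikes, nogo["trial_id"].to_numpy(int),
                               nogo["t_instruction"].to_numpy(float))
    series = sliding_auc(window_counts(rel_go, centers, cfg.window),
                         window_counts(rel_nogo, centers, cfg.window),
                         centers, cfg.window, cfg.step, orientation="go")
    band = control_threshold(series, (-cfg.control_span, 0.0), cfg.alpha)
    res = cancellation_time(series, band, ssrt=float("inf"),
                            persistence_ms=cfg.delay_persistence_ms,
                            search_start=cfg.delay_exclude,
                            search_end=cfg.delay_end)
    if res.cancellation_time is None:
        return "none", None, series
    return ("go" if res.direction == "auc_increase" else "nogo"), None, series


# ---------------------------------------------------------------------------
# axes 4-5: torque and outcome responses (shuffle-null ROC)
# ---------------------------------------------------------------------------

def _shuffled_null_trains(rel: List[np.ndarray], span: Tuple[float, float],
                          n_resamples: int, rng: np.random.Generator,
                          ) -> List[np.ndarray]:
    """Circularly shift each train within ``span``, ``n_resamples`` times.

    The shift preserves each trial's spike count and inter-spike-interval
    structure while destroying alignment to the event, giving a rate-matched
    null for the ROC comparison.
    """
    lo, hi = span
    width = hi - lo
    out = []
    for _ in range(n_resamples):
        for s in rel:
            in_span = s[(s >= lo) & (s < hi)]
            shift = rng.uniform(0.0, width)
            out.append(np.sort(lo + np.mod(in_span - lo + shift, width)))
    return out


def _event_response(unit: UnitData, trial_ids: np.ndarray,
                    event_times: np.ndarray, cfg: PipelineConfig,
                    rng: np.random.Generator, search_end: float,
                    ) -> Optional[float]:
    """Onset of a sustained event-locked activation vs a circular-shift null.

    Only AUC *increases* (observed counts exceeding the shuffled null) count
    as a response: a decrease against a circular-shift null is confounded by
    pre-event activity that the shuffle smears across the whole span, so it
    is not unambiguous evidence of an event-locked response.  Returns the
    onset time in ms, or ``None``.
    """
    if cfg.max_event_trials is not None and trial_ids.size > cfg.max_event_trials:
        pick = rng.choice(trial_ids.size, cfg.max_event_trials, replace=False)
        pick.sort()
        trial_ids, event_times = trial_ids[pick], event_times[pick]
    centers = np.arange(-cfg.control_span, search_end + cfg.window / 2 + cfg.step,
                        cfg.step)
    span = (centers[0] - cfg.window / 2, centers[-1] + cfg.window / 2)
    rel = relative_trains(unit.spikes, trial_ids, event_times)
    null = _shuffled_null_trains(rel, span, cfg.n_null_resamples, rng)
    series = sliding_auc(window_counts(rel, centers, cfg.window),
                         window_counts(null, centers, cfg.window),
                         centers, cfg.window, cfg.step, orientation="observed")
    band = control_threshold(series, (-cfg.control_span, 0.0), cfg.alpha)
    res = cancellation_time(series, band, ssrt=float("inf"),
                            persistence_ms=cfg.persistence_ms,
                            search_end=search_end, sides="increase")
    return res.cancellation_time


def detect_torque_response(unit: UnitData, trials: pd.DataFrame,
                           cfg: PipelineConfig, rng: np.random.Generator,
                           ) -> Tuple[bool, Optional[float], Optional[str], Optional[str]]:
    """Short-latency proprioceptive responsiveness.

    Per torque direction, spike counts after the impulse are compared
    against circularly time-shuffled counts; the unit is torque-related iff
    the first sustained significant time falls below the 200 ms latency
    bound in at least one direction.  Returns
    ``(flag, latency, direction, reason)``; missing torque trials yield an
    untested flag.
    """
    tq = trials[trials["t_torque"].notna()]
    if len(tq) == 0:
        return False, None, None, "untested: no torque trials"
    best: Tuple[float, str] | None = None
    for direction in ("flexion", "extension"):
        sub = tq[tq["torque_direction"] == direction]
        if len(sub) < cfg.min_trials:
            continue
        t = _event_response(
            unit, sub["trial_id"].to_numpy(int), sub["t_torque"].to_numpy(float),
            cfg, rng, search_end=cfg.torque_latency_bound,
        )
        if t is not None and t < cfg.torque_latency_bound:
            if best is None or t < best[0]:
                best = (t, direction)
    if best is None:
        return False, None, None, None
    return True, best[0], best[1], None


def detect_outcome_response(unit: UnitData, trials: pd.DataFrame,
                            cfg: PipelineConfig, rng: np.random.Generator,
                            ) -> Tuple[Optional[bool], Optional[bool], Dict[str, str]]:
    """Reward- and error-locked responsiveness within 500 ms of the signal.

    Reward events come from rewarded outcomes, error events from
    stop-failure trials; each is tested with the same shuffle-null ROC.
    A missing event type leaves the corresponding flag ``None`` (untested).
    """
    from .session import REWARDED_OUTCOMES

    reasons: Dict[str, str] = {}
    flags: Dict[str, Optional[bool]] = {}
    groups = {
        "reward": trials[trials["outcome"].isin(REWARDED_OUTCOMES)
                         & trials["t_outcome"].notna()],
        "error": trials[(trials["outcome"] == "stop_failure")
                        & trials["t_outcome"].notna()],
    }
    for name, sub in groups.items():
        if len(sub) < cfg.min_trials:
            flags[name] = None
            reasons[name] = f"untested: {len(sub)} {name} events"
            continue
        t = _event_response(
            unit, sub["trial_id"].to_numpy(int), sub["t_outcome"].to_numpy(float),
            cfg, rng, search_end=cfg.outcome_window,
        )
        flags[name] = t is not None and t < cfg.outcome_window
    return flags["reward"], flags["error"], reasons


# ---------------------------------------------------------------------------
# orchestration and population summary
# ---------------------------------------------------------------------------

def classify_unit(unit: UnitData, trials: pd.DataFrame, ssrt: float,
                  cfg: PipelineConfig, rng: np.random.Generator,
                  ) -> UnitClassification:
    """Run every classification axis on one unit."""
    cls = UnitClassification(unit_id=unit.unit_id, coords=unit.coords,
                             true_label=unit.archetype)
    try:
        qualified, pattern, cancel, _ = classify_stop_involvement(
            unit, trials, ssrt, cfg, rng)
        cls.stop_qualified, cls.stop_pattern, cls.cancellation = \
            qualified, pattern, cancel
    except AnalysisError as err:
        cls.reasons["stop"] = str(err)

    if cls.stop_pattern == "switch_stop":
        try:
            sel, reason = classify_stop_vs_switch(unit, trials, ssrt, cfg)
            cls.selectivity = sel
            if reason:
                cls.reasons["selectivity"] = reason
        except AnalysisError as err:
            cls.reasons["selectivity"] = str(err)

    try:
        label, reason, _ = classify_go_nogo(unit, trials, cfg)
        cls.go_nogo = label
        if reason:
            cls.reasons["go_nogo"] = reason
    except AnalysisError as err:
        cls.reasons["go_nogo"] = str(err)

    try:
        flag, latency, direction, reason = detect_torque_response(
            unit, trials, cfg, rng)
        cls.torque, cls.torque_latency, cls.torque_direction = \
            flag, latency, direction
        if reason:
            cls.reasons["torque"] = reason
    except AnalysisError as err:
        cls.reasons["torque"] = str(err)

    try:
        reward, error, reasons = detect_outcome_response(unit, trials, cfg, rng)
        cls.outcome_reward, cls.outcome_error = reward, error
        cls.reasons.update(reasons)
    except AnalysisError as err:
        cls.reasons["outcome"] = str(err)

    return cls


def chi_square_independence(table: np.ndarray) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns ``(statistic, df, p)`` with ``df = (r - 1)(c - 1)`` and no
    continuity correction.
    """
    table = np.asarray(table, dtype=float)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class PopulationTable:
    counts: Dict[str, Dict[str, int]]
    proportions: Dict[str, Dict[str, float]]
    crosstab: pd.DataFrame                  # stop_pattern x go_nogo
    chi2: float
    chi2_df: int
    chi2_p: float
    coord_summary: pd.DataFrame


def summarize_population(classifications: List[UnitClassification],
                         ) -> PopulationTable:
    """Counts and proportions per label, the reactive-by-proactive
    cross-tabulation with a chi-square independence test, and descriptive
    chamber-coordinate summaries per stop pattern."""
    if not classifications:
        raise AnalysisError("no classified units to summarize")
    n = len(classifications)
    df = pd.DataFrame([
        {
            "unit_id": c.unit_id,
            "stop_qualified": c.stop_qualified,
            "stop_pattern": c.stop_pattern,
            "selectivity": c.selectivity,
            "go_nogo": c.go_nogo,
            "torque": c.torque,
            "reward": bool(c.outcome_reward),
            "error": bool(c.outcome_error),
            "ap": c.coords.anterior_posterior if c.coords else np.nan,
            "ml": c.coords.medial_lateral if c.coords else np.nan,
            "depth": c.coords.depth if c.coords else np.nan,
        }
        for c in classifications
    ])

    counts = {
        "stop_pattern": df["stop_pattern"].value_counts().to_dict(),
        "selectivity": df["selectivity"].value_counts().to_dict(),
        "go_nogo": df["go_nogo"].value_counts().to_dict(),
        "torque": {"responsive": int(df["torque"].sum())},
        "outcome": {"reward": int(df["reward"].sum()),
                    "error": int(df["error"].sum())},
        "stop_qualified": {"qualified": int(df["stop_qualified"].sum())},
    }
    proportions = {
        axis: {k: v / n for k, v in d.items()} for axis, d in counts.items()
    }

    crosstab = pd.crosstab(df["stop_pattern"], df["go_nogo"])
    if crosstab.shape[0] >= 2 and crosstab.shape[1] >= 2:
        chi2, chi_df, chi_p = chi_square_independence(crosstab.to_numpy())
    else:
        chi2, chi_df, chi_p = float("nan"), 0, float("nan")

    coord_summary = (
        df.groupby("stop_pattern")[["ap", "ml", "depth"]]
        .agg(["mean", "min", "max"])
    )
    return PopulationTable(counts=counts, proportions=proportions,
                           crosstab=crosstab, chi2=chi2, chi2_df=chi_df,
                           chi2_p=chi_p, coord_summary=coord_summary)
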