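"""End-to-end session analysis.

``run_pipeline`` chains the full analysis for one session: behavioral race
statistics and the quantile SSRT, per-unit classification on every axis,
per-muscle EMG cancellation times, the optional eye regression control, and
a population summary.  All randomness (pseudo-SSD shuffles, circular-shift
nulls, ISI shuffles) derives from ``config.seed``, so the resulting JSON
bundle is byte-identical across runs with the same inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import behavior
from .classify import (
    PopulationTable,
    UnitClassification,
    classify_unit,
    summarize_population,
)
from .config import PipelineConfig
from .emg_eye import emg_cancellation_time, eye_regression
from .errors import AnalysisError
from .session import Session

__all__ = ["ResultsBundle", "run_pipeline", "results_to_json", "render_report"]

SCHEMA_VERSION = 1


@dataclass
class ResultsBundle:
    behavior: dict
    units: List[UnitClassification]
    emg: Dict[str, dict]
    eye: Optional[dict]
    population: Optional[PopulationTable]
    exclusions: Dict[str, str]
    config: dict
    auc_series: Dict[int, "object"] = field(default_factory=dict)


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(session: Session, cfg: PipelineConfig) -> ResultsBundle:
    """Run behavior, neural, EMG and eye analyses on one session."""
    rng = np.random.default_rng(cfg.seed)
    trials = session.trials
    exclusions: Dict[str, str] = {}

    # --- behavior ---------------------------------------------------------
    stats = behavior.rt_summary(trials)
    inhib = behavior.compute_inhibition_function(trials, cfg.ssd_bin)
    ssrt_est = behavior.estimate_ssrt_quantile(
        trials, cfg.ssd_bin, cfg.max_bins, cfg.min_go_trials)
    try:
        prep, prep_p = behavior.preparation_cost(trials)
    except AnalysisError as err:
        prep, prep_p = float("nan"), float("nan")
        exclusions["preparation_cost"] = str(err)
    beh = {
        "go_median_rt": stats.go_median,
        "stop_failure_median_rt": stats.stop_failure_median,
        "switch_go_median_rt": stats.switch_go_median,
        "stop_failure_vs_go_p": stats.comparison_p,
        "inhibition_slope_per_ms": inhib.slope,
        "inhibition_slope_p": inhib.slope_p,
        "inhibition_bins": inhib.bins.to_dict(orient="records"),
        "ssrt_ms": ssrt_est.ssrt_mean,
        "ssrt_n_bins": ssrt_est.n_bins_used,
        "preparation_cost_ms": prep,
        "preparation_cost_p": prep_p,
        "n_trials": int(len(trials)),
    }
    ssrt = ssrt_est.ssrt_mean

    # --- units ------------------------------------------------------------
    classifications: List[UnitClassification] = []
    for unit in session.units:
        cls = classify_unit(unit, trials, ssrt, cfg, rng)
        classifications.append(cls)
        for axis, reason in cls.reasons.items():
            exclusions[f"unit{unit.unit_id}/{axis}"] = reason

    population = summarize_population(classifications) if classifications else None

    # --- EMG --------------------------------------------------------------
    emg_results: Dict[str, dict] = {}
    for muscle, traces in session.emg.items():
        try:
            res, _ = emg_cancellation_time(traces, trials, ssrt, cfg, rng)
            emg_results[muscle] = {
                "cancellation_time_ms": res.cancellation_time,
                "direction": res.direction,
                "relative_to_ssrt_ms": res.relative_to_ssrt,
                "within_ssrt": res.within_ssrt,
            }
        except AnalysisError as err:
            exclusions[f"emg/{muscle}"] = str(err)

    # --- eye --------------------------------------------------------------
    eye_summary = None
    if session.eye:
        n_sig = 0
        per_unit = {}
        for unit in session.units:
            try:
                res = eye_regression(unit, session.eye, trials, cfg, rng)
            except AnalysisError as err:
                exclusions[f"eye/unit{unit.unit_id}"] = str(err)
                continue
            per_unit[unit.unit_id] = {
                "significant": bool(res.significant),
                "max_r2": float(res.r2.max()) if res.r2.size else 0.0,
                "degenerate": bool(res.degenerate),
            }
            n_sig += int(res.significant)
        eye_summary = {"n_units_significant": n_sig, "per_unit": per_unit}

    return ResultsBundle(
        behavior=beh,
        units=classifications,
        emg=emg_results,
        eye=eye_summary,
        population=population,
        exclusions=exclusions,
        config=cfg.to_dict(),
    )


def _unit_dict(c: UnitClassification) -> dict:
    d = {
        "unit_id": c.unit_id,
        "stop_qualified": c.stop_qualified,
        "stop_pattern": c.stop_pattern,
        "selectivity": c.selectivity,
        "go_nogo": c.go_nogo,
        "torque": c.torque,
        "torque_latency_ms": c.torque_latency,
        "torque_direction": c.torque_direction,
        "outcome_reward": c.outcome_reward,
        "outcome_error": c.outcome_error,
        "true_label": c.true_label,
    }
    if c.cancellation is not None:
        d["cancellation_time_ms"] = c.cancellation.cancellation_time
        d["cancellation_relative_to_ssrt_ms"] = c.cancellation.relative_to_ssrt
    if c.coords is not None:
        d["coords"] = {
            "anterior_posterior": c.coords.anterior_posterior,
            "medial_lateral": c.coords.medial_lateral,
            "depth": c.coords.depth,
        }
    return d


def results_to_json(bundle: ResultsBundle) -> str:
    """Deterministic JSON serialization of the results bundle."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "behavior": bundle.behavior,
        "units": [_unit_dict(c) for c in bundle.units],
        "emg": bundle.emg,
        "eye": bundle.eye,
        "exclusions": bundle.exclusions,
        "config": bundle.config,
    }
    if bundle.population is not None:
        pop = bundle.population
        doc["population"] = {
            "counts": pop.counts,
            "proportions": pop.proportions,
            "crosstab": {str(k): {str(kk): int(vv) for kk, vv in v.items()}
                         for k, v in pop.crosstab.to_dict().items()},
            "chi2": pop.chi2,
            "chi2_df": pop.chi2_df,
            "chi2_p": pop.chi2_p,
        }

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    def walk(x):
        if isinstance(x, dict):
            return {k: walk(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [walk(v) for v in x]
        if isinstance(x, float):
            if np.isnan(x):
                return None
            return round(x, 6)
        return x

    return json.dumps(walk(doc), sort_keys=True, indent=1, default=default)


def render_report(bundle: ResultsBundle) -> str:
    """Human-readable Markdown summary of one session's results."""
    b = bundle.behavior
    lines = [
        "# Countermanding session report",
        "",
        "## Behavior",
        "",
        f"- trials: {b['n_trials']}",
        f"- median RT, go: {b['go_median_rt']:.0f} ms; "
        f"stop-failure: {b['stop_failure_median_rt']:.0f} ms "
        f"(Mann-Whitney p = {b['stop_failure_vs_go_p']:.2g})",
        f"- inhibition-function slope: {b['inhibition_slope_per_ms']:.5f} /ms "
        f"(p = {b['inhibition_slope_p']:.2g})",
        f"- SSRT (quantile method, {b['ssrt_n_bins']} bins): {b['ssrt_ms']:.1f} ms",
        f"- preparation cost: {b['preparation_cost_ms']:.1f} ms "
        f"(p = {b['preparation_cost_p']:.2g})",
        "",
    ]
    if bundle.units:
        lines += ["## Units", "",
                  "| unit | stop pattern | selectivity | go/nogo | torque | "
                  "cancellation (ms) |",
                  "|---|---|---|---|---|---|"]
        for c in bundle.units:
            ct = (c.cancellation.cancellation_time
                  if c.cancellation is not None else None)
            lines.append(
                f"| {c.unit_id} | {c.stop_pattern} | {c.selectivity} | "
                f"{c.go_nogo} | {'yes' if c.torque else 'no'} | "
                f"{'-' if ct is None else f'{ct:.0f}'} |"
            )
        lines.append("")
    if bundle.population is not None:
        pop = bundle.population
        lines += ["## Population", ""]
        q = pop.counts["stop_qualified"].get("qualified", 0)
        lines.append(f"- units qualifying for stop involvement: {q} of "
                     f"{len(bundle.units)}")
        lines.append(f"- stop-pattern x go/nogo independence: chi2 = "
                     f"{pop.chi2:.2f} (df {pop.chi2_df}, p = {pop.chi2_p:.2g})")
        lines.append("")
    if bundle.emg:
        lines += ["## EMG", ""]
        for muscle, r in bundle.emg.items():
            ct = r["cancellation_time_ms"]
            lines.append(
                f"- {muscle}: cancellation at "
                f"{'-' if ct is None else f'{ct:.0f} ms'}"
                + ("" if ct is None else
                   f" ({r['relative_to_ssrt_ms']:+.0f} ms vs SSRT)")
            )
        lines.append("")
    if bundle.exclusions:
        lines += ["## Exclusions", ""]
        for key in sorted(bundle.exclusions):
            lines.append(f"- {key}: {bundle.exclusions[key]}")
        lines.append("")
    return "\n".join(lines)


def write_results(bundle: ResultsBundle, out_dir) -> None:
    """Write results.json, report.md and per-unit AUC CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(results_to_json(bundle))
    (out / "report.md").write_text(render_report(bundle))
    for uid, series in bundle.auc_series.items():
        df = pd.DataFrame({"time_ms": series.times, "auc": series.auc})
        df.to_csv(out / f"unit{uid:03d}_auc.csv", index=False)
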