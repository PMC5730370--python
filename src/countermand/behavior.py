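"""Behavioral analysis: RT statistics, inhibition functions, quantile SSRT.

Performance in a stop-signal task is summarized by the race model: an
independent go process (finish time = the would-be RT) races a stop process
(finish time = SSD + SSRT).  Two observable signatures follow — stop-failure
RTs are faster than go RTs (failures are the trials the go process won), and
the probability of failing to stop rises with the SSD (the *inhibition
function*).  The latent SSRT is estimated per session by the quantile
method: within each SSD bin, find the failure probability p, take the RT at
rank ``ceil(p * n_go)`` of the ascending correct-go RTs (nearest-rank, no
interpolation), subtract the bin's SSD, and average over the retained bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .session import trial_group

__all__ = [
    "InhibitionFunction",
    "SSRTEstimate",
    "RTStats",
    "compute_inhibition_function",
    "estimate_ssrt_quantile",
    "rt_summary",
    "preparation_cost",
]


@dataclass
class InhibitionFunction:
    """P(stop failure) per SSD bin, with a linear-trend test."""

    bins: pd.DataFrame      # ssd_lo, ssd_hi, midpoint, n_switch_stop, n_failures, p_failure
    slope: float            # OLS slope of p_failure on bin midpoint, per ms
    slope_p: float
    dropped_bins: List[Tuple[float, float]] = field(default_factory=list)


@dataclass
class SSRTEstimate:
    """Quantile-method stop-signal reaction time for one session."""

    per_bin: pd.DataFrame   # midpoint, p_failure, n, quantile_rt, ssrt, flagged
    ssrt_mean: float
    n_bins_used: int
    n_go_trials: int


@dataclass
class RTStats:
    go_median: float
    stop_failure_median: float
    switch_go_median: float
    go_mad: float
    stop_failure_mad: float
    switch_go_mad: float
    comparison_u: float     # Mann-Whitney U for stop-failure vs go RTs
    comparison_p: float


def _switch_stop_trials(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["outcome"].isin(["switch_stop_success", "stop_failure"])]


def compute_inhibition_function(trials: pd.DataFrame,
                                bin_width: float = 28.0) -> InhibitionFunction:
    """Proportion of stop failures as a function of SSD.

    Bins tile the observed SSD range at ``bin_width`` starting from the
    smallest observed SSD; half-open ``[lo, lo + w)`` except the last, which
    absorbs the maximum.  Empty bins are dropped and reported.  The slope is
    ordinary least squares of p(failure) on bin midpoints.
    """
    sw = _switch_stop_trials(trials)
    if len(sw) == 0:
        raise AnalysisError("no switch-stop trials; inhibition function undefined")
    ssd = sw["ssd"].to_numpy(dtype=float)
    failed = (sw["outcome"] == "stop_failure").to_numpy()

    lo = math.floor(ssd.min())
    n_bins = max(1, math.ceil((ssd.max() - lo) / bin_width + 1e-9))
    idx = np.minimum(((ssd - lo) // bin_width).astype(int), n_bins - 1)

    rows, dropped = [], []
    for b in range(n_bins):
        b_lo = lo + b * bin_width
        b_hi = b_lo + bin_width
        in_bin = idx == b
        n = int(in_bin.sum())
        if n == 0:
            dropped.append((b_lo, b_hi))
            continue
        n_fail = int(failed[in_bin].sum())
        rows.append({
            "ssd_lo": b_lo, "ssd_hi": b_hi, "midpoint": (b_lo + b_hi) / 2.0,
            "n_switch_stop": n, "n_failures": n_fail, "p_failure": n_fail / n,
        })
    bins = pd.DataFrame(rows)

    if len(bins) >= 3 and bins["p_failure"].nunique() > 1:
        reg = stats.linregress(bins["midpoint"], bins["p_failure"])
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    elif len(bins) >= 2 and bins["p_failure"].nunique() > 1:
        reg = stats.linregress(bins["midpoint"], bins["p_failure"])
        slope, slope_p = float(reg.slope), float("nan")
    else:
        slope, slope_p = 0.0, float("nan")
    return InhibitionFunction(bins=bins, slope=slope, slope_p=slope_p,
                              dropped_bins=dropped)


def estimate_ssrt_quantile(trials: pd.DataFrame, bin_width: float = 28.0,
                           max_bins: int = 6, min_go_trials: int = 50,
                           representative: str = "midpoint") -> SSRTEstimate:
    """Quantile-method SSRT.

    For each retained SSD bin the quantile RT is the nearest-rank order
    statistic of the ascending correct-go RTs at rank
    ``ceil(p_failure * n_go)``; the bin's representative SSD (midpoint by
    default, or the mean observed SSD with ``representative='mean'``) is
    subtracted, and the session SSRT is the arithmetic mean over the at most
    ``max_bins`` bins with the largest switch-stop trial counts.  Bins with
    p(failure) of exactly 0 or 1 are retained in the table but flagged; a
    p = 0 bin has no defined quantile and cannot enter the mean.  If every
    bin has p = 0 the estimate is undefined and an error is raised.
    """
    if representative not in ("midpoint", "mean"):
        raise AnalysisError(f"unknown representative SSD rule {representative!r}")
    go_rts = np.sort(trial_group(trials, "go_correct")["rt"].to_numpy(dtype=float))
    n_go = go_rts.size
    if n_go < min_go_trials:
        raise AnalysisError(f"only {n_go} correct go trials (< {min_go_trials})")

    inhib = compute_inhibition_function(trials, bin_width)
    # largest switch-stop counts first; among count ties prefer bins with
    # failures, since a p = 0 bin has no quantile and cannot inform the mean
    bins = inhib.bins.sort_values(
        ["n_switch_stop", "n_failures", "midpoint"],
        ascending=[False, False, True],
    ).head(max_bins).sort_values("midpoint")

    if (bins["p_failure"] == 0).all():
        raise AnalysisError("p(failure) is 0 in every retained bin; SSRT undefined")

    sw = _switch_stop_trials(trials)
    rows = []
    for _, b in bins.iterrows():
        p = b["p_failure"]
        flagged = p in (0.0, 1.0)
        if p > 0:
            rank = min(math.ceil(p * n_go), n_go)
            q_rt = float(go_rts[rank - 1])
        else:
            q_rt = float("nan")
        if representative == "midpoint":
            rep = b["midpoint"]
        else:
            in_bin = (sw["ssd"] >= b["ssd_lo"]) & (sw["ssd"] < b["ssd_hi"])
            rep = float(sw.loc[in_bin, "ssd"].mean())
        rows.append({
            "midpoint": b["midpoint"], "ssd_representative": rep,
            "p_failure": p, "n_switch_stop": b["n_switch_stop"],
            "quantile_rt": q_rt, "ssrt": q_rt - rep, "flagged": flagged,
        })
    per_bin = pd.DataFrame(rows)
    usable = per_bin["ssrt"].dropna()
    return SSRTEstimate(per_bin=per_bin, ssrt_mean=float(usable.mean()),
                        n_bins_used=int(usable.size), n_go_trials=n_go)


def _rts(trials: pd.DataFrame, outcome: str) -> np.ndarray:
    g = trial_group(trials, outcome)
    return g["rt"].dropna().to_numpy(dtype=float)


def _mad(x: np.ndarray) -> float:
    return float(stats.median_abs_deviation(x)) if x.size else float("nan")


def rt_summary(trials: pd.DataFrame,
               alternative: str = "two-sided") -> RTStats:
    """Group RT medians/dispersion and the stop-failure vs go comparison.

    The race model predicts stop-failure RTs (responses that escaped the
    stop process) are the fast tail of the go distribution, so their median
    should fall below the go median; the Mann-Whitney test quantifies that
    shift.  ``alternative`` is passed through (e.g. ``'less'`` tests
    failure < go one-sided).
    """
    go = _rts(trials, "go_correct")
    fail = _rts(trials, "stop_failure")
    for name, arr in (("go_correct", go), ("stop_failure", fail)):
        if arr.size == 0:
            raise AnalysisError(f"RT group {name!r} is empty")
    sw_go = _rts(trials, "switch_go_correct")
    u, p = stats.mannwhitneyu(fail, go, alternative=alternative)
    return RTStats(
        go_median=float(np.median(go)),
        stop_failure_median=float(np.median(fail)),
        switch_go_median=float(np.median(sw_go)) if sw_go.size else float("nan"),
        go_mad=_mad(go),
        stop_failure_mad=_mad(fail),
        switch_go_mad=_mad(sw_go),
        comparison_u=float(u),
        comparison_p=float(p),
    )


def preparation_cost(trials: pd.DataFrame) -> Tuple[float, float]:
    """Median switch-go RT minus median go RT, with a Mann-Whitney p.

    A positive cost indicates a proactive "do not respond" set induced by
    the NoGo instruction: movements triggered unexpectedly by the switch
    signal start slower than ordinary go responses.
    """
    go = _rts(trials, "go_correct")
    sw_go = _rts(trials, "switch_go_correct")
    for name, arr in (("go_correct", go), ("switch_go_correct", sw_go)):
        if arr.size == 0:
            raise AnalysisError(f"RT group {name!r} is empty")
    _, p = stats.mannwhitneyu(sw_go, go, alternative="two-sided")
    return float(np.median(sw_go) - np.median(go)), float(p)
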