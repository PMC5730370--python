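"""Sliding-window ROC machinery for divergence detection.

This is the statistical heart of the package.  Two trial conditions (e.g.
successful switch-stop trials versus latency-matched go trials) are compared
by sliding a 60 ms test window in 1 ms steps over event-aligned activity,
computing at each step the area under the ROC curve (AUC) between the two
per-trial value distributions.  The AUC equals the Mann-Whitney statistic
``U / (n_A * n_B)`` with ties counted one half, i.e. ``P(a > b) + P(a = b)/2``
over all cross-condition pairs; 0.5 means the distributions overlap
completely.

A significance band is derived from a control period preceding the event:
mean +/- t-critical * SD of the control AUC values, two-tailed, with degrees
of freedom taken from the number of *independent* windows in the control
span (span / window width) rather than the heavily autocorrelated 1 ms-step
count.  The divergence ("cancellation") time is the first post-event window
center whose AUC leaves the band and stays out for a sustained run.

The same code path serves spike counts and windowed EMG envelope values —
``sliding_auc`` never looks at what the per-trial numbers mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import AnalysisError
from .session import UnitData, trial_group

__all__ = [
    "SDF",
    "AlignedGoSet",
    "AUCSeries",
    "ThresholdBand",
    "CancellationResult",
    "spike_density",
    "relative_trains",
    "window_counts",
    "sample_latency_matched_go",
    "sliding_auc",
    "control_threshold",
    "cancellation_time",
    "stop_vs_matched_go_auc",
    "detect_divergence",
    "bootstrap_cancellation_ci",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SDF:
    """Trial-averaged spike density function on a 1 ms grid."""

    times: np.ndarray          # ms relative to the alignment event
    rate: np.ndarray           # spikes/s
    kernel_width: float        # Gaussian sigma, ms
    alignment_event: str
    n_trials: int


@dataclass
class AlignedGoSet:
    """Latency-matched go trials with their pseudo-switch alignment times.

    One entry per retained (trial, shuffle) pair.  A go trial survives a
    shuffle iff its RT is at least the pseudo-SSD plus the SSRT — i.e. the
    response would have been stopped had a switch signal occurred there.
    """

    trial_ids: np.ndarray          # int, one per retained pair
    alignment_times: np.ndarray    # trial-clock ms (trigger + pseudo-SSD)
    shuffle_ids: np.ndarray
    n_shuffles: int
    ssrt_used: float
    survival_rate: float           # retained pairs / candidate pairs


@dataclass
class AUCSeries:
    """Time-indexed AUC values; each value sits at its window center."""

    times: np.ndarray
    auc: np.ndarray
    window_width: float
    step: float
    orientation: str               # label of the positive (A) condition
    n_a: int
    n_b: int


@dataclass
class ThresholdBand:
    control_mean: float
    upper: float
    lower: float
    alpha: float
    control_window: Tuple[float, float]
    n_effective: int
    degenerate: bool = False


@dataclass
class CancellationResult:
    """Detected divergence time relative to the aligning event.

    ``within_ssrt`` is true iff a time was detected and it precedes the
    SSRT boundary — the causality requirement for involvement in stopping.
    """

    cancellation_time: Optional[float]
    direction: Optional[str]           # "auc_increase" | "auc_decrease"
    relative_to_ssrt: Optional[float]
    within_ssrt: bool
    ci95: Optional[Tuple[float, float]] = None
    ci_width: Optional[float] = None


# ---------------------------------------------------------------------------
# spike density
# ---------------------------------------------------------------------------

def spike_density(trains: Sequence[np.ndarray], window: Tuple[float, float],
                  kernel_width: float = 20.0,
                  alignment_event: str = "event") -> SDF:
    """Gaussian-kernel spike density function averaged over trials.

    ``trains`` holds event-relative spike times per trial.  The kernel is
    truncated at +/- 4 sigma and renormalized so each spike contributes unit
    area; the rate is reported in spikes/s on a 1 ms grid of ``window``.
    An empty spike set yields a zero-rate SDF.
    """
    if len(trains) == 0:
        raise AnalysisError("spike_density needs at least one trial")
    t0, t1 = window
    times = np.arange(t0, t1)
    sigma = float(kernel_width)
    half = int(np.ceil(4 * sigma))
    k = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    kernel /= kernel.sum()                     # unit mass on the 1 ms grid

    edges = np.arange(t0 - half, t1 + half + 1)
    counts = np.zeros(edges.size - 1)
    for s in trains:
        s = np.asarray(s, dtype=float)
        if s.size:
            counts += np.histogram(s, bins=edges)[0]
    smoothed = np.convolve(counts, kernel, mode="same")[half:half + times.size]
    rate = smoothed / len(trains) * 1000.0     # per-ms -> spikes/s
    return SDF(times=times, rate=rate, kernel_width=sigma,
               alignment_event=alignment_event, n_trials=len(trains))


# ---------------------------------------------------------------------------
# alignment and counting
# ---------------------------------------------------------------------------

def relative_trains(spikes_by_trial: dict, trial_ids: np.ndarray,
                    alignment_times: np.ndarray) -> List[np.ndarray]:
    """Event-relative spike trains, one array per (trial, alignment)."""
    empty = np.empty(0)
    return [
        np.asarray(spikes_by_trial.get(int(tid), empty), dtype=float) - align
        for tid, align in zip(trial_ids, alignment_times)
    ]


def window_counts(rel_trains: Sequence[np.ndarray], centers: np.ndarray,
                  width: float) -> np.ndarray:
    """Spike counts in half-open windows ``[c - w/2, c + w/2)``.

    Returns an ``(n_trains, n_centers)`` integer matrix.
    """
    half = width / 2.0
    lo = centers - half
    hi = centers + half
    out = np.empty((len(rel_trains), centers.size), dtype=np.int64)
    for i, s in enumerate(rel_trains):
        out[i] = np.searchsorted(s, hi, side="left") - np.searchsorted(s, lo, side="left")
    return out


def sample_latency_matched_go(trials: pd.DataFrame, ssrt: float,
                              n_shuffles: int, rng: np.random.Generator,
                              ssd_range: Tuple[float, float] = (200.0, 450.0),
                              ) -> AlignedGoSet:
    """Assign pseudo-SSDs to correct go trials and keep the stoppable ones.

    Per shuffle, every correct go trial receives a pseudo-SSD drawn uniformly
    on the integer ms grid of ``ssd_range``; trials with ``RT < SSD + SSRT``
    are excluded for that shuffle (they would have escaped stopping).  The
    pseudo-alignment time is ``trigger + pseudo-SSD`` on the trial clock.
    """
    if ssrt <= 0:
        raise AnalysisError("ssrt must be positive for latency matching")
    go = trial_group(trials, "go_correct")
    if len(go) == 0:
        raise AnalysisError("no correct go trials to latency-match")
    rts = go["rt"].to_numpy(dtype=float)
    tids = go["trial_id"].to_numpy(dtype=int)
    trig = go["t_trigger"].to_numpy(dtype=float)
    lo, hi = int(ssd_range[0]), int(ssd_range[1])

    all_tid, all_align, all_shuf = [], [], []
    n_candidates = n_shuffles * len(go)
    for s in range(n_shuffles):
        pseudo = rng.integers(lo, hi + 1, len(go)).astype(float)
        keep = rts >= pseudo + ssrt
        if not keep.any():
            rate = sum(len(a) for a in all_tid) / max((s * len(go)), 1)
            raise AnalysisError(
                f"shuffle {s}: no go trial survives latency matching "
                f"(survival rate so far {rate:.3f})"
            )
        all_tid.append(tids[keep])
        all_align.append((trig + pseudo)[keep])
        all_shuf.append(np.full(int(keep.sum()), s))
    trial_ids = np.concatenate(all_tid)
    return AlignedGoSet(
        trial_ids=trial_ids,
        alignment_times=np.concatenate(all_align),
        shuffle_ids=np.concatenate(all_shuf),
        n_shuffles=n_shuffles,
        ssrt_used=float(ssrt),
        survival_rate=trial_ids.size / n_candidates,
    )


# ---------------------------------------------------------------------------
# AUC, threshold band, detection
# ---------------------------------------------------------------------------

def sliding_auc(values_a: np.ndarray, values_b: np.ndarray,
                times: np.ndarray, window_width: float, step: float,
                orientation: str = "A") -> AUCSeries:
    """AUC between two per-trial value matrices at every time step.

    ``values_a``/``values_b`` are ``(n_trials, n_times)``; the AUC at each
    column is ``P(a > b) + P(a = b)/2`` over all cross-condition pairs,
    computed exactly via midranks (the Mann-Whitney identity).  Condition A
    is the positive class: values of A exceeding B push the AUC above 0.5.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise AnalysisError(
            f"sliding_auc needs >= 2 trials per condition (got {n_a}, {n_b})"
        )
    if a.shape[1] != b.shape[1] or a.shape[1] != len(times):
        raise AnalysisError("condition matrices and time grid disagree")

    n_times = a.shape[1]
    auc = np.empty(n_times)
    # chunk over time columns to bound the rank matrix at ~5e6 entries
    chunk = max(1, int(5_000_000 // max(n_a + n_b, 1)))
    for j0 in range(0, n_times, chunk):
        j1 = min(j0 + chunk, n_times)
        combined = np.concatenate([a[:, j0:j1], b[:, j0:j1]], axis=0)
        ranks = stats.rankdata(combined, axis=0)
        rank_sum_a = ranks[:n_a].sum(axis=0)
        u_a = rank_sum_a - n_a * (n_a + 1) / 2.0
        auc[j0:j1] = u_a / (n_a * n_b)
    return AUCSeries(times=np.asarray(times, dtype=float), auc=auc,
                     window_width=window_width, step=step,
                     orientation=orientation, n_a=n_a, n_b=n_b)


def control_threshold(series: AUCSeries, control_span: Tuple[float, float],
                      alpha: float = 0.01) -> ThresholdBand:
    """Two-tailed t-band around the control-period AUC mean.

    The band is ``mean +/- t_{1-alpha/2, df} * SD`` of the control AUC
    values.  Because 1 ms-stepped values from a 60 ms window are strongly
    autocorrelated, the effective number of independent observations is the
    number of non-overlapping windows the span holds
    (``span / window_width``), not the raw sample count: the t quantile uses
    ``df = n_eff - 1`` and Bessel's correction is applied at ``n_eff``
    (the raw-count correction would leave the SD biased low).
    """
    lo, hi = control_span
    mask = (series.times >= lo) & (series.times < hi)
    vals = series.auc[mask]
    if vals.size < 2:
        raise AnalysisError("control span holds fewer than 2 AUC values")
    n_eff = max(int(round((hi - lo) / series.window_width)), 2)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0)) * math.sqrt(n_eff / (n_eff - 1))
    degenerate = sd < 1e-12
    if alpha >= 1.0 or degenerate:
        half = 0.0
    else:
        half = stats.t.ppf(1.0 - alpha / 2.0, df=n_eff - 1) * sd
    return ThresholdBand(control_mean=mean, upper=mean + half,
                         lower=mean - half, alpha=alpha,
                         control_window=(lo, hi), n_effective=n_eff,
                         degenerate=degenerate)


def cancellation_time(series: AUCSeries, band: ThresholdBand, ssrt: float,
                      persistence_ms: float = 20.0,
                      search_start: float = 0.0,
                      search_end: Optional[float] = None,
                      sides: str = "both") -> CancellationResult:
    """First sustained excursion of the AUC outside the control band.

    The detected time is the first post-event window center whose AUC exits
    the band on one side and stays on that side for at least
    ``persistence_ms`` of consecutive steps, suppressing single-step noise
    crossings.  With a degenerate (zero-variance) band any deviation from
    the control mean counts as an exit.  ``sides`` restricts which exit
    directions are eligible (``"both"``, ``"increase"``, ``"decrease"``).
    """
    mask = series.times >= search_start
    if search_end is not None:
        mask &= series.times <= search_end
    times = series.times[mask]
    auc = series.auc[mask]
    if times.size == 0:
        raise AnalysisError("no AUC values in the search range")

    if band.degenerate:
        above = auc > band.control_mean + 1e-9
        below = auc < band.control_mean - 1e-9
    else:
        above = auc > band.upper
        below = auc < band.lower

    need = max(1, int(round(persistence_ms / series.step)))
    candidates = []
    if sides in ("both", "increase"):
        candidates.append((above, "auc_increase"))
    if sides in ("both", "decrease"):
        candidates.append((below, "auc_decrease"))
    t_hit, direction = None, None
    for side, label in candidates:
        idx = _first_run(side, need)
        if idx is not None and (t_hit is None or times[idx] < t_hit):
            t_hit, direction = float(times[idx]), label

    if t_hit is None:
        return CancellationResult(None, None, None, False)
    return CancellationResult(
        cancellation_time=t_hit,
        direction=direction,
        relative_to_ssrt=t_hit - ssrt,
        within_ssrt=t_hit < ssrt,
    )


def _first_run(flags: np.ndarray, need: int) -> Optional[int]:
    """Index of the first position starting ``need`` consecutive True."""
    if flags.size < need:
        return None
    if need == 1:
        hits = np.flatnonzero(flags)
        return int(hits[0]) if hits.size else None
    window = np.convolve(flags.astype(int), np.ones(need, dtype=int), "valid")
    hits = np.flatnonzero(window == need)
    return int(hits[0]) if hits.size else None


# ---------------------------------------------------------------------------
# the standard stop-versus-latency-matched-go comparison
# ---------------------------------------------------------------------------

def stop_vs_matched_go_auc(unit: UnitData, trials: pd.DataFrame, ssrt: float,
                           cfg: PipelineConfig, rng: np.random.Generator,
                           ) -> Tuple[AUCSeries, AlignedGoSet]:
    """Sliding AUC of latency-matched go (A) versus successful stop (B) trials.

    Both conditions are aligned on their (pseudo-)switch signal.  All
    retained trial-shuffle alignments are pooled into the go-condition count
    distribution with equal weight.  With go as the positive class a
    stop-related *increase* in firing drives the AUC below 0.5.
    """
    stop = trial_group(trials, "switch_stop_success")
    if len(stop) < cfg.min_trials:
        raise AnalysisError(
            f"only {len(stop)} successful switch-stop trials (< {cfg.min_trials})"
        )
    matched = sample_latency_matched_go(
        trials, ssrt, cfg.n_shuffles, rng, ssd_range=cfg.ssd_range
    )
    centers = np.arange(-cfg.control_span, cfg.post_window + cfg.step, cfg.step)

    go_rel = relative_trains(unit.spikes, matched.trial_ids, matched.alignment_times)
    stop_rel = relative_trains(
        unit.spikes,
        stop["trial_id"].to_numpy(dtype=int),
        stop["t_switch"].to_numpy(dtype=float),
    )
    counts_go = window_counts(go_rel, centers, cfg.window)
    counts_stop = window_counts(stop_rel, centers, cfg.window)
    series = sliding_auc(counts_go, counts_stop, centers, cfg.window, cfg.step,
                         orientation="latency_matched_go")
    return series, matched


def detect_divergence(series: AUCSeries, ssrt: float, cfg: PipelineConfig,
                      search_end: Optional[float] = None) -> CancellationResult:
    """Control band plus sustained-excursion detection in one call."""
    band = control_threshold(series, (-cfg.control_span, 0.0), cfg.alpha)
    return cancellation_time(series, band, ssrt,
                             persistence_ms=cfg.persistence_ms,
                             search_end=search_end)


def bootstrap_cancellation_ci(unit: UnitData, trials: pd.DataFrame,
                              ssrt: float, cfg: PipelineConfig,
                              rng: np.random.Generator,
                              n_boot: Optional[int] = None) -> CancellationResult:
    """Re-run alignment + AUC + detection ``n_boot`` times for a 95% CI.

    Each replicate redraws the pseudo-SSD shuffles, so the CI reflects the
    variability contributed by the latency-matching procedure.  If detection
    fails in more than half of the replicates the CI is undefined and the
    result carries ``ci95 = None``.
    """
    n_boot = cfg.n_boot if n_boot is None else n_boot
    point_series, _ = stop_vs_matched_go_auc(unit, trials, ssrt, cfg, rng)
    point = detect_divergence(point_series, ssrt, cfg)
    times = []
    for _ in range(n_boot):
        series, _ = stop_vs_matched_go_auc(unit, trials, ssrt, cfg, rng)
        res = detect_divergence(series, ssrt, cfg)
        if res.cancellation_time is not None:
            times.append(res.cancellation_time)
    if len(times) <= n_boot / 2 or point.cancellation_time is None:
        return point
    lo, hi = np.percentile(times, [2.5, 97.5])
    point.ci95 = (float(lo), float(hi))
    point.ci_width = float(hi - lo)
    return point
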