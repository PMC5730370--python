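"""EMG cancellation times and the eye-movement regression control.

EMG envelopes are pushed through exactly the same sliding-AUC machinery as
spike counts — the per-trial statistic fed to :func:`countermand.roc.sliding_auc`
is the mean rectified envelope in each 60 ms window instead of a spike
count.  This yields, per muscle, the time at which activity on successful
switch-stop trials diverges from latency-matched go activity, reported
relative to the SSRT just as for neurons.

The eye control fits, at every time step around the switch signal, the
linear model

    f(t) = b0 + b1*x(t) + b2*y(t) + b3*vx(t) + b4*vy(t) + e

where ``f`` is the spike count in a 50 ms window and ``x, y`` (``vx, vy``)
are eye position (velocity).  Significance of the R-squared at a step is
judged against the 99th percentile of R-squared values obtained after
shuffling inter-spike intervals within each trial — a null that preserves
each train's rate and ISI statistics while destroying its temporal relation
to gaze.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import AnalysisError
from .roc import (
    AlignedGoSet,
    CancellationResult,
    control_threshold,
    cancellation_time,
    sample_latency_matched_go,
    sliding_auc,
)
from .session import ContinuousTrace, EyeTrace, UnitData, trial_group

__all__ = [
    "EyeRegressionResult",
    "emg_cancellation_time",
    "eye_regression",
    "shuffle_isis",
]


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def _window_means(trace: ContinuousTrace, align: float, centers: np.ndarray,
                  width: float) -> np.ndarray:
    """Mean envelope value in each half-open window around ``align``."""
    if trace.fs != 1000.0:
        raise AnalysisError("EMG traces must be sampled at 1 kHz")
    v = trace.values
    csum = np.concatenate([[0.0], np.cumsum(v)])
    half = width / 2.0
    lo = np.clip((align + centers - half - trace.t_start).astype(int), 0, v.size)
    hi = np.clip((align + centers + half - trace.t_start).astype(int), 0, v.size)
    n = np.maximum(hi - lo, 1)
    return (csum[hi] - csum[lo]) / n


def emg_cancellation_time(emg_by_trial: Dict[int, ContinuousTrace],
                          trials: pd.DataFrame, ssrt: float,
                          cfg: PipelineConfig, rng: np.random.Generator,
                          ) -> Tuple[CancellationResult, "object"]:
    """Divergence time of one muscle's stop-trial envelope.

    Windowed mean envelopes on successful switch-stop trials are compared
    against latency-matched go trials (pooled over pseudo-SSD shuffles) with
    the shared sliding-AUC/threshold-band/persistence code path; the result
    is reported relative to the SSRT.  An agonist that keeps rising on go
    trials while relaxing on stops exits as an AUC increase; an antagonist
    burst on stops exits as a decrease.
    """
    stop = trial_group(trials, "switch_stop_success")
    if len(stop) < cfg.min_trials:
        raise AnalysisError(
            f"only {len(stop)} successful switch-stop trials (< {cfg.min_trials})"
        )
    matched = sample_latency_matched_go(trials, ssrt, cfg.n_shuffles, rng,
                                        ssd_range=cfg.ssd_range)
    centers = np.arange(-cfg.control_span, cfg.post_window + cfg.step, cfg.step)

    missing = [int(t) for t in stop["trial_id"] if int(t) not in emg_by_trial]
    if missing:
        raise AnalysisError(f"EMG missing for trials {missing[:5]}")

    go_vals = np.stack([
        _window_means(emg_by_trial[int(tid)], align, centers, cfg.window)
        for tid, align in zip(matched.trial_ids, matched.alignment_times)
    ])
    stop_vals = np.stack([
        _window_means(emg_by_trial[int(tid)], float(align), centers, cfg.window)
        for tid, align in zip(stop["trial_id"], stop["t_switch"])
    ])
    series = sliding_auc(go_vals, stop_vals, centers, cfg.window, cfg.step,
                         orientation="latency_matched_go")
    band = control_threshold(series, (-cfg.control_span, 0.0), cfg.alpha)
    result = cancellation_time(series, band, ssrt,
                               persistence_ms=cfg.persistence_ms)
    return result, series


# ---------------------------------------------------------------------------
# eye regression
# ---------------------------------------------------------------------------

@dataclass
class EyeRegressionResult:
    times: np.ndarray              # step times, ms relative to the switch
    r2: np.ndarray
    coefficients: np.ndarray       # (n_steps, 5): b0, b1 (x), b2 (y), b3 (vx), b4 (vy)
    coef_se: np.ndarray            # (n_steps, 5) OLS standard errors
    null_q99: np.ndarray           # per-step 99th percentile of shuffled R2
    significant_steps: np.ndarray  # bool per step
    significant: bool
    degenerate: bool = False
    n_trials: int = 0


def shuffle_isis(train: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute inter-spike intervals, anchoring the first spike.

    Preserves the spike count and the ISI multiset of the train exactly
    (hence its mean rate), while scrambling when in the trial each interval
    occurs.
    """
    train = np.asarray(train, dtype=float)
    if train.size < 3:
        return train.copy()
    isis = np.diff(train)
    return np.concatenate([[train[0]], train[0] + np.cumsum(rng.permutation(isis))])


def _regressors(eye: EyeTrace, align: float, step_times: np.ndarray,
                smooth_ms: float = 50.0) -> np.ndarray:
    """Position and velocity at each step center, resampled to 1 kHz.

    The trace is linearly interpolated to 1 ms, velocity taken by central
    differences and smoothed with a boxcar of ``smooth_ms``.
    """
    t_grid = align + step_times
    src_t = eye.times
    x = np.interp(t_grid, src_t, eye.x)
    y = np.interp(t_grid, src_t, eye.y)
    # velocity on a dense local grid for stable differentiation
    dense = np.arange(src_t[0], src_t[-1], 1.0)
    xd = np.interp(dense, src_t, eye.x)
    yd = np.interp(dense, src_t, eye.y)
    vx = np.gradient(xd, 1e-3)      # deg/s on the 1 ms grid
    vy = np.gradient(yd, 1e-3)
    k = max(int(smooth_ms), 1)
    box = np.ones(k) / k
    vx = np.convolve(vx, box, mode="same")
    vy = np.convolve(vy, box, mode="same")
    vxs = np.interp(t_grid, dense, vx)
    vys = np.interp(t_grid, dense, vy)
    return np.column_stack([x, y, vxs, vys])


def eye_regression(unit: UnitData, eye: Dict[int, EyeTrace],
                   trials: pd.DataFrame, cfg: PipelineConfig,
                   rng: np.random.Generator,
                   n_shuffle: Optional[int] = None) -> EyeRegressionResult:
    """Per-time-step OLS of spike counts on eye position and velocity.

    Uses switch trials aligned on the switch signal; spike counts are taken
    in ``eye_window`` ms windows stepped by ``eye_step`` over ``eye_range``.
    A step is significant iff the observed R-squared exceeds the 99th
    percentile of the ISI-shuffle null at that step.  Frozen gaze (no
    positional variance) flags the result degenerate.
    """
    n_shuffle = cfg.eye_n_shuffle if n_shuffle is None else n_shuffle
    sw = trials[trials["has_switch"]]
    sw = sw[sw["trial_id"].astype(int).isin(eye.keys())]
    if len(sw) < cfg.eye_min_trials:
        raise AnalysisError(f"only {len(sw)} switch trials with eye data "
                            f"(< {cfg.eye_min_trials})")
    tids = sw["trial_id"].to_numpy(int)
    aligns = sw["t_switch"].to_numpy(float)
    lo, hi = cfg.eye_range
    steps = np.arange(lo, hi + cfg.eye_step, cfg.eye_step)
    n_steps, n_trials = steps.size, len(sw)
    half = cfg.eye_window / 2.0

    # regressors: (n_trials, n_steps, 4)
    regs = np.stack([
        _regressors(eye[int(tid)], a, steps) for tid, a in zip(tids, aligns)
    ])
    if regs[:, :, :2].std() < 1e-9:
        return EyeRegressionResult(
            times=steps, r2=np.zeros(n_steps),
            coefficients=np.zeros((n_steps, 5)),
            coef_se=np.full((n_steps, 5), np.nan),
            null_q99=np.zeros(n_steps),
            significant_steps=np.zeros(n_steps, dtype=bool),
            significant=False, degenerate=True, n_trials=n_trials,
        )

    rel = [np.asarray(unit.spikes.get(int(t), np.empty(0)), float) - a
           for t, a in zip(tids, aligns)]

    def counts_matrix(trains: List[np.ndarray]) -> np.ndarray:
        out = np.empty((n_trials, n_steps))
        for i, s in enumerate(trains):
            out[i] = (np.searchsorted(s, steps + half)
                      - np.searchsorted(s, steps - half))
        return out

    y_obs = counts_matrix(rel)

    # Per-step orthonormal basis of [1, regressors]; residual sums then come
    # from projections, which lets the shuffle null reuse the factorization.
    q_bases = []
    r2 = np.empty(n_steps)
    coefs = np.empty((n_steps, 5))
    coef_se = np.empty((n_steps, 5))
    for j in range(n_steps):
        X = np.column_stack([np.ones(n_trials), regs[:, j, :]])
        q, _ = np.linalg.qr(X)
        q_bases.append(q)
        yj = y_obs[:, j]
        beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
        coefs[j] = beta
        sst = float(((yj - yj.mean()) ** 2).sum())
        ssr = float((yj ** 2).sum() - (q.T @ yj) @ (q.T @ yj))
        r2[j] = max(0.0, 1.0 - ssr / sst) if sst > 0 else 0.0
        dof = max(n_trials - 5, 1)
        try:
            xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
            coef_se[j] = np.sqrt(np.maximum(xtx_inv_diag, 0.0) * max(ssr, 0.0) / dof)
        except np.linalg.LinAlgError:
            coef_se[j] = np.nan

    null_r2 = np.empty((n_shuffle, n_steps))
    for s in range(n_shuffle):
        shuffled = [shuffle_isis(tr, rng) for tr in rel]
        y_null = counts_matrix(shuffled)
        for j in range(n_steps):
            yj = y_null[:, j]
            sst = float(((yj - yj.mean()) ** 2).sum())
            if sst <= 0:
                null_r2[s, j] = 0.0
            else:
                proj = q_bases[j].T @ yj
                ssr = float((yj ** 2).sum() - proj @ proj)
                null_r2[s, j] = max(0.0, 1.0 - ssr / sst)

    q99 = np.percentile(null_r2, 99.0, axis=0)
    sig = r2 > q99
    return EyeRegressionResult(
        times=steps, r2=r2, coefficients=coefs, coef_se=coef_se, null_q99=q99,
        significant_steps=sig, significant=bool(sig.any()),
        degenerate=False, n_trials=n_trials,
    )
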