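"""Sliding-window ROC core: AUC, threshold band, divergence detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from countermand import (
    PipelineConfig,
    cancellation_time,
    control_threshold,
    sample_latency_matched_go,
    sliding_auc,
    spike_density,
)
from countermand.errors import AnalysisError
from countermand.roc import (
    AUCSeries,
    detect_divergence,
    stop_vs_matched_go_auc,
    window_counts,
)


def brute_force_auc(a, b):
    """Exhaustive pair enumeration: P(a > b) + P(a = b)/2."""
    wins = sum(1.0 for x in a for y in b if x > y)
    ties = sum(1.0 for x in a for y in b if x == y)
    return (wins + 0.5 * ties) / (len(a) * len(b))


def series_of(values_a, values_b, window=60.0, step=1.0):
    a = np.asarray(values_a, float).reshape(-1, 1)
    b = np.asarray(values_b, float).reshape(-1, 1)
    return sliding_auc(a, b, np.array([0.0]), window, step)


class TestSlidingAUC:
    def test_identical_multisets_give_half(self):
        s = series_of([2, 3, 3, 5], [3, 2, 5, 3])
        assert s.auc[0] == pytest.approx(0.5)

    def test_complete_separation_gives_one(self):
        s = series_of([5, 6], [1, 2])
        assert s.auc[0] == pytest.approx(1.0)

    def test_ties_counted_half_matches_enumeration(self):
        a, b = [2, 3, 3], [3, 1, 4]
        s = series_of(a, b)
        assert s.auc[0] == pytest.approx(brute_force_auc(a, b))  # = 4/9

    def test_too_few_trials_is_an_error(self):
        with pytest.raises(AnalysisError):
            series_of([1.0], [2, 3])

    @settings(max_examples=150, deadline=None)
    @given(
        a=st.lists(st.integers(0, 8), min_size=2, max_size=12),
        b=st.lists(st.integers(0, 8), min_size=2, max_size=12),
    )
    def test_matches_brute_force_enumeration(self, a, b):
        s = series_of(a, b)
        assert s.auc[0] == pytest.approx(brute_force_auc(a, b), abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.lists(st.integers(0, 8), min_size=2, max_size=10),
        b=st.lists(st.integers(0, 8), min_size=2, max_size=10),
    )
    def test_antisymmetry_under_condition_swap(self, a, b):
        assert series_of(a, b).auc[0] == pytest.approx(
            1.0 - series_of(b, a).auc[0], abs=1e-12)


class TestControlThreshold:
    @staticmethod
    def eight_window_series(values):
        # eight non-overlapping 60 ms windows spanning [0, 480)
        times = 30.0 + 60.0 * np.arange(8)
        return AUCSeries(times=times, auc=np.asarray(values, float),
                         window_width=60.0, step=60.0, orientation="A",
                         n_a=10, n_b=10)

    def test_hand_computed_t_band(self):
        # mean .5, sample sd .026726 over 8 independent windows:
        # band = .5 +/- t(.995, 7) * sd = .5 +/- .0936
        s = self.eight_window_series([0.45, 0.5, 0.55, 0.5, 0.5, 0.5, 0.5, 0.5])
        band = control_threshold(s, (0.0, 480.0), alpha=0.01)
        assert band.control_mean == pytest.approx(0.5)
        assert band.upper - band.control_mean == pytest.approx(0.0935, abs=2e-3)
        assert band.lower == pytest.approx(2 * band.control_mean - band.upper)

    def test_alpha_one_collapses_to_mean(self):
        s = self.eight_window_series([0.4, 0.5, 0.6, 0.5, 0.5, 0.5, 0.5, 0.5])
        band = control_threshold(s, (0.0, 480.0), alpha=1.0)
        assert band.upper == band.lower == band.control_mean

    def test_constant_control_is_degenerate(self):
        s = self.eight_window_series([0.5] * 8)
        band = control_threshold(s, (0.0, 480.0), alpha=0.01)
        assert band.degenerate
        assert band.upper == band.lower == 0.5


class TestCancellationTime:
    @staticmethod
    def flat_plus_step(t_step, level, n=400, base=0.5):
        times = np.arange(-500.0, float(n))
        auc = np.full(times.size, base)
        auc += 0.001 * np.sin(times)          # sub-threshold wiggle
        auc[times >= t_step] = level
        return AUCSeries(times=times, auc=auc, window_width=60.0, step=1.0,
                         orientation="A", n_a=20, n_b=20)

    def test_flat_series_yields_no_detection(self):
        s = self.flat_plus_step(10_000.0, 0.5)     # step never happens
        band = control_threshold(s, (-500.0, 0.0))
        res = cancellation_time(s, band, ssrt=160.0)
        assert res.cancellation_time is None
        assert not res.within_ssrt

    def test_step_detected_at_onset_with_direction(self):
        s = self.flat_plus_step(120.0, 0.9)
        band = control_threshold(s, (-500.0, 0.0))
        res = cancellation_time(s, band, ssrt=160.0)
        assert res.direction == "auc_increase"
        assert abs(res.cancellation_time - 120.0) <= 30.0
        assert res.within_ssrt
        assert res.relative_to_ssrt == pytest.approx(res.cancellation_time - 160.0)

    def test_downward_step_is_a_decrease(self):
        s = self.flat_plus_step(200.0, 0.1)
        band = control_threshold(s, (-500.0, 0.0))
        res = cancellation_time(s, band, ssrt=160.0)
        assert res.direction == "auc_decrease"
        assert not res.within_ssrt           # 200 ms > SSRT

    def test_sides_restriction_ignores_wrong_direction(self):
        s = self.flat_plus_step(120.0, 0.9)
        band = control_threshold(s, (-500.0, 0.0))
        res = cancellation_time(s, band, ssrt=160.0, sides="decrease")
        assert res.cancellation_time is None

    def test_brief_excursion_is_suppressed_by_persistence(self):
        s = self.flat_plus_step(10_000.0, 0.5)
        idx = np.flatnonzero(s.times == 100.0)[0]
        s.auc[idx:idx + 5] = 0.95            # 5 ms blip < 20 ms persistence
        band = control_threshold(s, (-500.0, 0.0))
        res = cancellation_time(s, band, ssrt=160.0, persistence_ms=20.0)
        assert res.cancellation_time is None


class TestLatencyMatching:
    def test_no_exclusions_when_all_rts_are_slow(self, trials):
        slow = trials.copy()
        mask = slow["outcome"] == "go_correct"
        slow.loc[mask, "rt"] = 2000.0
        rng = np.random.default_rng(0)
        m = sample_latency_matched_go(slow, 160.0, 50, rng)
        assert m.survival_rate == 1.0

    def test_survival_probability_of_borderline_trial(self, trials):
        """RT = 400, SSRT = 160: survives iff pseudo-SSD <= 240,
        i.e. 41 of the 251 admissible integer delays."""
        fixed = trials.copy()
        mask = fixed["outcome"] == "go_correct"
        fixed.loc[mask, "rt"] = 400.0
        n_go = int(mask.sum())
        rng = np.random.default_rng(1)
        m = sample_latency_matched_go(fixed, 160.0, 200, rng)
        expected = 41.0 / 251.0
        se = math.sqrt(expected * (1 - expected) / (200 * n_go))
        assert m.survival_rate == pytest.approx(expected, abs=4 * se)

    def test_retained_pairs_satisfy_race_inequality(self, trials):
        rng = np.random.default_rng(2)
        m = sample_latency_matched_go(trials, 160.0, 20, rng)
        go = trials.set_index("trial_id")
        rts = go.loc[m.trial_ids, "rt"].to_numpy()
        pseudo_ssd = m.alignment_times - go.loc[m.trial_ids, "t_trigger"].to_numpy()
        assert (rts >= pseudo_ssd + 160.0).all()
        assert ((pseudo_ssd >= 200) & (pseudo_ssd <= 450)).all()

    def test_deterministic_under_fixed_seed(self, trials):
        a = sample_latency_matched_go(trials, 160.0, 10, np.random.default_rng(9))
        b = sample_latency_matched_go(trials, 160.0, 10, np.random.default_rng(9))
        assert np.array_equal(a.trial_ids, b.trial_ids)
        assert np.array_equal(a.alignment_times, b.alignment_times)

    def test_impossible_matching_raises_with_rate(self, trials):
        fast = trials.copy()
        mask = fast["outcome"] == "go_correct"
        fast.loc[mask, "rt"] = 100.0         # nothing can survive
        with pytest.raises(AnalysisError, match="survival"):
            sample_latency_matched_go(fast, 160.0, 5, np.random.default_rng(0))


class TestSpikeDensity:
    def test_no_spikes_gives_zero_rate(self):
        sdf = spike_density([np.empty(0)], (-100.0, 100.0))
        assert np.all(sdf.rate == 0.0)

    def test_single_spike_gaussian_bump(self):
        sdf = spike_density([np.array([0.0])], (-200.0, 200.0), kernel_width=20.0)
        peak = 1000.0 / (20.0 * math.sqrt(2 * math.pi))   # ~19.95 spikes/s
        assert sdf.rate.max() == pytest.approx(peak, rel=0.01)
        # unit area: one spike
        assert sdf.rate.sum() / 1000.0 == pytest.approx(1.0, rel=0.01)

    def test_recovers_stationary_poisson_rate(self):
        rng = np.random.default_rng(4)
        trains = [np.sort(rng.uniform(-500, 500, rng.poisson(20.0)))
                  for _ in range(1000)]
        sdf = spike_density(trains, (-400.0, 400.0), kernel_width=20.0)
        assert sdf.rate.mean() == pytest.approx(20.0, abs=1.0)


class TestWindowCounts:
    def test_half_open_window_convention(self):
        train = np.array([-30.0, 0.0, 29.9, 30.0])
        counts = window_counts([train], np.array([0.0]), 60.0)
        # [-30, 30): includes -30, 0, 29.9; excludes 30
        assert counts[0, 0] == 3
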