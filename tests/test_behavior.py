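"""Behavioral analysis: inhibition function, quantile SSRT, RT statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countermand import (
    RaceModelParams,
    RTDistribution,
    compute_inhibition_function,
    estimate_ssrt_quantile,
    preparation_cost,
    rt_summary,
    simulate_race_trials,
)
from countermand.errors import AnalysisError
from countermand.session import TRIAL_COLUMNS


def make_trials(records):
    """Minimal trial table from (instruction, has_switch, ssd, rt, outcome)."""
    rows = []
    for i, (instr, sw, ssd, rt, outcome) in enumerate(records):
        row = {c: np.nan for c in TRIAL_COLUMNS}
        row.update(trial_id=i, instruction=instr, has_switch=sw, ssd=ssd,
                   rt=rt, outcome=outcome, t_trigger=0.0,
                   t_instruction=-2000.0, t_target=-1000.0,
                   torque_direction="", t_start=-4000.0, t_end=3000.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def switch_stop_bin(ssd, n_fail, n_success, rt_fail=400.0):
    recs = []
    recs += [("go", True, ssd, rt_fail, "stop_failure")] * n_fail
    recs += [("go", True, ssd, np.nan, "switch_stop_success")] * n_success
    return recs


class TestInhibitionFunction:
    def test_three_point_ols_slope(self):
        # failures/totals 1/10, 3/10, 5/10 in consecutive 28 ms bins anchored
        # at SSD 200: p = .1/.3/.5 on midpoints 214/242/270, a perfect line
        # of slope .4/56 per ms
        recs = (
            [("go", True, 200.0, 400.0, "stop_failure")]
            + switch_stop_bin(214.0, 0, 9)
            + switch_stop_bin(230.0, 3, 0) + switch_stop_bin(242.0, 0, 7)
            + switch_stop_bin(260.0, 5, 0) + switch_stop_bin(270.0, 0, 5)
        )
        inh = compute_inhibition_function(make_trials(recs), bin_width=28.0)
        assert list(inh.bins["p_failure"]) == [0.1, 0.3, 0.5]
        assert list(inh.bins["midpoint"]) == [214.0, 242.0, 270.0]
        assert inh.slope == pytest.approx(0.4 / 56.0)
        assert inh.slope_p < 0.05

    def test_all_failures_gives_flat_function(self):
        recs = switch_stop_bin(220.0, 5, 0) + switch_stop_bin(300.0, 5, 0)
        inh = compute_inhibition_function(make_trials(recs), bin_width=28.0)
        assert (inh.bins["p_failure"] == 1.0).all()
        assert inh.slope == pytest.approx(0.0)

    def test_no_switch_stop_trials_is_an_error(self):
        trials = make_trials([("go", False, np.nan, 500.0, "go_correct")] * 5)
        with pytest.raises(AnalysisError):
            compute_inhibition_function(trials)

    def test_invariant_under_trial_permutation(self, trials):
        shuffled = trials.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = compute_inhibition_function(trials)
        b = compute_inhibition_function(shuffled)
        pd.testing.assert_frame_equal(a.bins, b.bins)
        assert a.slope == pytest.approx(b.slope)

    def test_race_fixture_matches_deterministic_threshold(self):
        # point-mass go RT at 500 ms, SSRT 150: failure iff SSD > 350
        params = RaceModelParams(
            go_rt_dist=RTDistribution(family="point", location=500.0, shift=0.0),
            ssrt_true=150.0, n_trials=4000,
        )
        trials = simulate_race_trials(params, seed=3)
        inh = compute_inhibition_function(trials, bin_width=28.0)
        for _, b in inh.bins.iterrows():
            if b["ssd_hi"] <= 350.0:
                assert b["p_failure"] == 0.0
            elif b["ssd_lo"] > 350.0:
                assert b["p_failure"] == 1.0


class TestQuantileSSRT:
    def test_single_bin_nearest_rank(self):
        # go RTs {400..480}, p(failure) 0.4 at SSD ~250:
        # rank ceil(.4*5) = 2 -> 420; SSRT = 420 - 250 = 170
        recs = [("go", False, np.nan, rt, "go_correct")
                for rt in (400.0, 420.0, 440.0, 460.0, 480.0)]
        recs += switch_stop_bin(250.0, 4, 6)
        est = estimate_ssrt_quantile(make_trials(recs), bin_width=28.0,
                                     min_go_trials=5)
        row = est.per_bin.iloc[0]
        assert row["quantile_rt"] == 420.0
        assert est.ssrt_mean == pytest.approx(420.0 - row["ssd_representative"])

    def test_p_failure_one_uses_max_go_rt(self):
        recs = [("go", False, np.nan, rt, "go_correct")
                for rt in (400.0, 450.0, 500.0)]
        recs += switch_stop_bin(250.0, 5, 0)
        est = estimate_ssrt_quantile(make_trials(recs), min_go_trials=3)
        assert est.per_bin.iloc[0]["quantile_rt"] == 500.0
        assert bool(est.per_bin.iloc[0]["flagged"])

    def test_all_zero_failure_bins_is_an_error(self):
        recs = [("go", False, np.nan, 500.0, "go_correct")] * 60
        recs += switch_stop_bin(250.0, 0, 10)
        with pytest.raises(AnalysisError):
            estimate_ssrt_quantile(make_trials(recs))

    def test_too_few_go_trials_is_an_error(self):
        recs = [("go", False, np.nan, 500.0, "go_correct")] * 10
        recs += switch_stop_bin(250.0, 3, 7)
        with pytest.raises(AnalysisError):
            estimate_ssrt_quantile(make_trials(recs), min_go_trials=50)

    @settings(max_examples=60, deadline=None)
    @given(
        rts=st.lists(st.integers(300, 700), min_size=1, max_size=10),
        n_fail=st.integers(1, 8),
        n_tot=st.integers(8, 12),
    )
    def test_nearest_rank_matches_empirical_cdf_bruteforce(self, rts, n_fail, n_tot):
        """Nearest-rank quantile equals the smallest RT whose empirical CDF
        reaches p, for every toy go-RT list."""
        p = n_fail / n_tot
        recs = [("go", False, np.nan, float(rt), "go_correct") for rt in rts]
        recs += switch_stop_bin(250.0, n_fail, n_tot - n_fail)
        est = estimate_ssrt_quantile(make_trials(recs), min_go_trials=1)
        got = est.per_bin.iloc[0]["quantile_rt"]
        srt = sorted(rts)
        brute = next(v for i, v in enumerate(srt) if (i + 1) / len(srt) >= p - 1e-12)
        assert got == brute

    def test_estimator_bias_shrinks_with_session_length(self):
        """Consistency: absolute bias decreases monotonically with n."""
        biases = []
        for n in (600, 2400, 9600):
            params = RaceModelParams(n_trials=n)
            ests = [estimate_ssrt_quantile(simulate_race_trials(params, seed=s)).ssrt_mean
                    for s in range(20)]
            biases.append(abs(np.mean(ests) - params.ssrt_true))
        assert biases[2] < biases[0] + 2.0  # strictly smaller up to tiny noise
        assert biases[2] < 10.0


class TestRTSummary:
    def test_identical_groups_are_indistinguishable(self):
        rts = [400.0, 450.0, 500.0, 550.0]
        recs = [("go", False, np.nan, rt, "go_correct") for rt in rts]
        recs += [("go", True, 250.0, rt, "stop_failure") for rt in rts]
        stats = rt_summary(make_trials(recs))
        assert stats.comparison_p > 0.99
        assert stats.go_median == stats.stop_failure_median

    def test_complete_separation_exact_p(self):
        # failure {1,2,3} vs go {5,6,7}: U = 0, one-sided p = 1/C(6,3) = 1/20
        recs = [("go", False, np.nan, rt, "go_correct") for rt in (5.0, 6.0, 7.0)]
        recs += [("go", True, 250.0, rt, "stop_failure") for rt in (1.0, 2.0, 3.0)]
        stats = rt_summary(make_trials(recs), alternative="less")
        assert stats.comparison_u == 0.0
        assert stats.comparison_p == pytest.approx(1.0 / 20.0)

    def test_empty_group_is_named_in_error(self):
        recs = [("go", False, np.nan, 500.0, "go_correct")] * 3
        with pytest.raises(AnalysisError, match="stop_failure"):
            rt_summary(make_trials(recs))

    def test_race_fixture_failures_are_faster(self, trials):
        stats = rt_summary(trials)
        assert stats.stop_failure_median < stats.go_median


class TestPreparationCost:
    def test_zero_cost_fixture(self):
        params = RaceModelParams(prep_cost_true=0.0, n_trials=2000)
        cost, p = preparation_cost(simulate_race_trials(params, seed=5))
        assert abs(cost) < 20.0
        assert p > 0.05

    def test_recovers_generative_cost(self):
        costs = [preparation_cost(
            simulate_race_trials(RaceModelParams(prep_cost_true=60.0), seed=s))[0]
            for s in range(30)]
        assert np.mean(costs) == pytest.approx(60.0, abs=10.0)

    def test_single_trial_groups_still_defined(self):
        recs = [("go", False, np.nan, 500.0, "go_correct"),
                ("nogo", True, 250.0, 560.0, "switch_go_correct")]
        cost, p = preparation_cost(make_trials(recs))
        assert cost == 60.0
        assert p >= 0.5
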