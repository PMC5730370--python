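"""Synthetic-session generator: race structure, Poisson spiking, EMG, eye."""

import numpy as np
import pytest
from scipy import stats as sps

from countermand import (
    CellArchetype,
    RaceModelParams,
    RTDistribution,
    simulate_emg,
    simulate_eye,
    simulate_race_trials,
    simulate_session,
    simulate_spike_train,
)
from countermand.errors import ConfigurationError
from countermand.simulate import (
    EMGParams,
    SessionConfig,
    _smooth_pulse,
    archetype_rate,
    default_archetype,
)


class TestRaceTrials:
    def test_stop_always_wins_with_zero_ssrt_and_slow_go(self):
        params = RaceModelParams(
            go_rt_dist=RTDistribution(family="point", location=800.0, shift=0.0),
            ssrt_true=0.0, n_trials=2000,
        )
        trials = simulate_race_trials(params, seed=0)
        assert (trials["outcome"] != "stop_failure").all()

    def test_deterministic_race_with_point_mass_rt(self):
        # RT 500, SSRT 150: SSD 400 -> 500 < 550 fails; SSD 300 -> 500 >= 450 stops
        params = RaceModelParams(
            go_rt_dist=RTDistribution(family="point", location=500.0, shift=0.0),
            ssrt_true=150.0, n_trials=3000,
        )
        trials = simulate_race_trials(params, seed=2)
        sw = trials[trials["outcome"].isin(["stop_failure", "switch_stop_success"])]
        fails = sw["outcome"] == "stop_failure"
        assert (sw.loc[fails, "ssd"] > 350.0).all()
        assert (sw.loc[~fails, "ssd"] <= 350.0).all()

    def test_failure_rate_matches_analytic_race_probability(self):
        """Per SSD bin, the empirical failure rate matches the closed-form
        P(RT < SSD + SSRT) of the shifted lognormal within binomial bounds."""
        params = RaceModelParams(n_trials=20_000)
        trials = simulate_race_trials(params, seed=11)
        d = params.go_rt_dist
        sw = trials[trials["outcome"].isin(["stop_failure", "switch_stop_success"])]
        for lo in range(200, 450, 50):
            sub = sw[(sw["ssd"] >= lo) & (sw["ssd"] < lo + 50)]
            n = len(sub)
            p_emp = (sub["outcome"] == "stop_failure").mean()
            mid = lo + 25.0
            # oracle: lognormal CDF evaluated independently via scipy
            p_true = sps.lognorm.cdf(mid + params.ssrt_true - d.shift,
                                     s=d.scale, scale=d.location)
            se = np.sqrt(max(p_true * (1 - p_true), 1e-4) / n)
            assert p_emp == pytest.approx(p_true, abs=3.5 * se + 0.01)

    def test_trial_record_invariants(self, trials):
        sw = trials["has_switch"]
        assert trials.loc[sw, "ssd"].notna().all()
        assert trials.loc[~sw, "ssd"].isna().all()
        fails = trials["outcome"] == "stop_failure"
        assert trials.loc[fails, "rt"].notna().all()
        assert (trials.loc[fails, "instruction"] == "go").all()
        stops = trials["outcome"] == "switch_stop_success"
        assert trials.loc[stops, "rt"].isna().all()
        assert ((trials.loc[sw, "ssd"] >= 200) & (trials.loc[sw, "ssd"] <= 450)).all()

    def test_invalid_params_raise_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            RaceModelParams(ssd_range=(450.0, 200.0))
        with pytest.raises(ConfigurationError):
            RaceModelParams(p_switch=1.5)
        with pytest.raises(ConfigurationError):
            RTDistribution(family="weibull")

    def test_median_structure_across_sessions(self):
        """Race consistency: stop-failure median < go median, per session."""
        params = RaceModelParams()
        for s in range(25):
            t = simulate_race_trials(params, seed=100 + s)
            fail = t.loc[t["outcome"] == "stop_failure", "rt"]
            go = t.loc[t["outcome"] == "go_correct", "rt"]
            assert fail.median() < go.median()


class TestSpikeTrains:
    def test_null_archetype_is_homogeneous_poisson(self, trial_rows):
        """Mean count ~ rate x time and Fano factor ~ 1 in a fixed window."""
        arch = default_archetype("null", baseline_rate=20.0)
        rng = np.random.default_rng(8)
        counts = []
        for i in range(1000):
            tr = trial_rows[i % len(trial_rows)]
            s = simulate_spike_train(arch, tr, rng)
            counts.append(np.sum((s >= -1000.0) & (s < 0.0)))
        counts = np.asarray(counts, float)
        assert counts.mean() == pytest.approx(20.0, abs=0.6)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.15)

    def test_zero_amplitude_equals_null(self, trial_rows):
        tr = trial_rows[0]
        t1, r1 = archetype_rate(default_archetype("switch_stop", effect_amplitude=0.0,
                                                  baseline_rate=20.0), tr)
        t2, r2 = archetype_rate(default_archetype("null", baseline_rate=20.0), tr)
        assert np.array_equal(r1, r2)

    def test_counts_match_programmed_rate_integral(self, trial_rows):
        """Thinning oracle: mean counts equal the integral of the composed
        rate function over any window (switch-locked response window here)."""
        arch = default_archetype("switch_stop")
        rng = np.random.default_rng(12)
        stops = [r for r in trial_rows if r["outcome"] == "switch_stop_success"]
        tr = stops[0]
        t, rate = archetype_rate(arch, tr)
        w0, w1 = tr["t_switch"] + 80.0, tr["t_switch"] + 200.0
        expected = rate[(t >= w0) & (t < w1)].sum() / 1000.0
        counts = []
        for _ in range(400):
            s = simulate_spike_train(arch, tr, rng)
            counts.append(np.sum((s >= w0) & (s < w1)))
        got = np.mean(counts)
        assert got == pytest.approx(expected, abs=4 * np.sqrt(expected / 400))

    def test_smooth_pulse_area(self):
        t = np.arange(0.0, 1000.0)
        pulse = _smooth_pulse(t, 100.0, 120.0, 45.0, edge=10.0)
        # raised-cosine edges: area = amp * (duration - edge)
        assert pulse.sum() == pytest.approx(45.0 * 110.0, rel=0.02)
        assert pulse.min() >= 0.0

    def test_movement_ramp_truncated_on_successful_stop(self, trial_rows):
        arch = default_archetype("movement")
        stop = next(r for r in trial_rows if r["outcome"] == "switch_stop_success")
        t, rate = archetype_rate(arch, stop)
        cut = stop["t_switch"] + arch.truncation_latency
        after = rate[(t >= cut + 60) & (t < cut + 200)]
        assert after.max() <= arch.baseline_rate + 1.0   # decayed to baseline
        go = next(r for r in trial_rows if r["outcome"] == "go_correct")
        tg, rg = archetype_rate(arch, go)
        assert rg.max() > arch.baseline_rate + 0.9 * arch.effect_amplitude

    def test_switch_selectivity_of_transient(self, trial_rows):
        sel = default_archetype("switch_stop")
        nonsel = default_archetype("switch_nonselective")
        sw_go = next(r for r in trial_rows if r["outcome"] == "switch_go_correct")
        _, r_sel = archetype_rate(sel, sw_go)
        _, r_nonsel = archetype_rate(nonsel, sw_go)
        assert r_sel.max() == sel.baseline_rate          # no response on switch-go
        assert r_nonsel.max() > nonsel.baseline_rate + 40.0


class TestSessionDeterminism:
    def test_same_seed_same_session(self):
        cfg = SessionConfig(race=RaceModelParams(n_trials=120),
                            units=[default_archetype("switch_stop"),
                                   default_archetype("null")],
                            muscles={"biceps": "agonist"},
                            eye_coupling="none")
        a = simulate_session(cfg, 77)
        b = simulate_session(cfg, 77)
        assert a.trials.equals(b.trials)
        for ua, ub in zip(a.units, b.units):
            assert set(ua.spikes) == set(ub.spikes)
            for tid in ua.spikes:
                assert np.array_equal(ua.spikes[tid], ub.spikes[tid])
        for tid in a.emg["biceps"]:
            assert np.array_equal(a.emg["biceps"][tid].values,
                                  b.emg["biceps"][tid].values)
        for tid in a.eye:
            assert np.array_equal(a.eye[tid].x, b.eye[tid].x)

    def test_zero_units_gives_behavior_only_session(self):
        cfg = SessionConfig(race=RaceModelParams(n_trials=80))
        sess = simulate_session(cfg, 1)
        assert sess.units == [] and sess.emg == {} and sess.eye == {}
        assert sess.n_trials == 80

    def test_ground_truth_labels_in_meta(self):
        cfg = SessionConfig(race=RaceModelParams(n_trials=80),
                            units=[default_archetype("movement")])
        sess = simulate_session(cfg, 1)
        assert sess.meta["unit_labels"][0] == "movement"


class TestEMG:
    def test_noise_free_agonist_flat_on_nogo(self, trial_rows):
        tr = next(r for r in trial_rows if r["outcome"] == "nogo_correct")
        trace = simulate_emg(tr, "agonist", 0, params=EMGParams(noise=0.0))
        assert np.allclose(trace.values, trace.values[0])

    def test_antagonist_burst_area_matches_programmed_envelope(self, trial_rows):
        tr = next(r for r in trial_rows if r["outcome"] == "switch_stop_success")
        p = EMGParams(noise=0.0)
        trace = simulate_emg(tr, "antagonist", 0, params=p)
        area = (trace.values - p.baseline).sum()
        assert area == pytest.approx(p.burst_amplitude * (p.burst_duration - 10.0),
                                     rel=0.02)

    def test_agonist_full_burst_on_stop_failure(self, trial_rows):
        tr = next(r for r in trial_rows if r["outcome"] == "stop_failure")
        p = EMGParams(noise=0.0)
        trace = simulate_emg(tr, "agonist", 0, params=p)
        assert trace.values.max() == pytest.approx(p.baseline + p.amplitude, rel=0.01)


class TestEye:
    def test_trace_is_nonpathological(self, trial_rows):
        tr = trial_rows[0]
        eye = simulate_eye(tr, "none", 3)
        assert eye.fs == 240.0
        assert np.isfinite(eye.x).all() and np.isfinite(eye.y).all()
        assert abs(eye.x).max() < 30.0

    def test_velocity_is_discrete_derivative(self, trial_rows):
        eye = simulate_eye(trial_rows[0], "none", 3)
        vx, _ = eye.velocity()
        dt = 1.0 / eye.fs
        assert vx[5] == pytest.approx((eye.x[6] - eye.x[4]) / (2 * dt))
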