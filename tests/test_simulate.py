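"""Generator: minimum-jerk kernel, design conservation, generative laws."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tapjump as tj
from tapjump.simulate import PEAK_ACCEL_COEFF

from conftest import make_meta


class TestMinimumJerkCorrection:
    def test_endpoints_and_midpoint(self):
        assert tj.minimum_jerk_correction(0.026, 0.2, 0.0) == 0.0
        assert tj.minimum_jerk_correction(0.026, 0.2, 0.2) == pytest.approx(0.026)
        # the fifth-order polynomial is antisymmetric about its midpoint
        assert tj.minimum_jerk_correction(0.026, 0.2, 0.1) == pytest.approx(0.013)

    def test_peak_acceleration_matches_closed_form(self):
        """Dense numeric scan of the second derivative against the
        analytic peak (10/sqrt(3)) * amplitude / duration**2."""
        amplitude, duration = 0.026, 0.2
        t = np.linspace(0, duration, 200_001)
        x = tj.minimum_jerk_correction(amplitude, duration, t)
        accel = np.gradient(np.gradient(x, t), t)
        expected = PEAK_ACCEL_COEFF * amplitude / duration ** 2
        assert np.max(accel) == pytest.approx(expected, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tj.minimum_jerk_correction(0.026, 0.0, 0.0)
        with pytest.raises(ValueError):
            tj.minimum_jerk_correction(0.026, 0.2, 0.3)

    @given(st.floats(0.05, 0.5), st.floats(-0.05, 0.05))
    def test_velocity_and_acceleration_vanish_at_ends(self, duration, amplitude):
        eps = duration * 1e-4
        t = np.array([0.0, eps, duration - eps, duration])
        x = tj.minimum_jerk_correction(amplitude, duration, t)
        # displacement grows as t^3 near the start, so v, a -> 0 at both ends
        assert abs(x[1] - x[0]) <= abs(amplitude) * 2e-11
        assert abs(x[3] - x[2]) <= abs(amplitude) * 2e-11


class TestDesign:
    def test_design_counts_and_alternation(self):
        plan = tj.ExperimentPlan(n_participants=2)
        metas = tj.build_design(plan, tj.SimulationConfig(seed=5))
        assert len(metas) == 2 * 2 * 12 * 20
        for m in metas:
            expected = tj.STAY if m.block_index % 2 == 0 else tj.JUMP_BACK
            assert m.condition == expected
            assert m.analysed == (m.block_index >= 2)
        per_p = sum(m.analysed for m in metas) // 2
        assert per_p == plan.analysed_trials_per_participant == 400

    def test_each_block_balanced_and_pair_index_bijective(self):
        plan = tj.ExperimentPlan(n_participants=1)
        metas = tj.build_design(plan, tj.SimulationConfig(seed=5))
        from collections import defaultdict
        blocks = defaultdict(list)
        for m in metas:
            blocks[(m.session, m.block_index)].append(m)
        for trials in blocks.values():
            lefts = [m.pair_index for m in trials if m.jump_direction == tj.LEFT]
            rights = [m.pair_index for m in trials if m.jump_direction == tj.RIGHT]
            assert sorted(lefts) == list(range(1, 11))
            assert sorted(rights) == list(range(1, 11))

    def test_counterbalancing(self):
        plan = tj.ExperimentPlan(n_participants=2)
        assert plan.session_diameters(1) == (0.03, 0.015)
        assert plan.session_diameters(2) == (0.015, 0.03)

    def test_invalid_config_names_field(self):
        cfg = tj.SimulationConfig(dropout_probability=1.5)
        with pytest.raises(tj.ConfigError, match="dropout_probability"):
            cfg.validate()
        with pytest.raises(tj.ConfigError, match="trials_per_block"):
            tj.ExperimentPlan(trials_per_block=21).validate()


class TestTrialGeneration:
    def test_deterministic_given_seed(self):
        cfg = tj.SimulationConfig(seed=9)
        meta = make_meta()
        s1, t1 = tj.simulate_trial(meta, cfg)
        s2, t2 = tj.simulate_trial(make_meta(), cfg)
        np.testing.assert_array_equal(s1.x, s2.x)
        np.testing.assert_array_equal(s1.valid, s2.valid)
        assert t1.to_dict() == t2.to_dict()

    def test_noise_free_stay_trial_reaches_jump_magnitude(self, noise_free_config):
        """With gain 1 the final lateral displacement equals the signed jump."""
        s, truth = tj.simulate_trial(make_meta(direction=tj.RIGHT), noise_free_config)
        assert s.x[-1] == pytest.approx(0.026, rel=1e-9)
        s, _ = tj.simulate_trial(make_meta(direction=tj.LEFT), noise_free_config)
        assert s.x[-1] == pytest.approx(-0.026, rel=1e-9)
        assert truth.onset is not None and truth.tap > truth.onset

    def test_zero_gain_gives_flat_lateral_channel(self):
        cfg = tj.noise_free(first_response_gain={tj.STAY: 0.0, tj.JUMP_BACK: 0.0})
        s, _ = tj.simulate_trial(make_meta(), cfg)
        assert np.allclose(s.x, 0.0)

    def test_jump_back_returns_to_zero(self, noise_free_config):
        s, truth = tj.simulate_trial(
            make_meta(condition=tj.JUMP_BACK, block=3), noise_free_config)
        assert truth.return_start == pytest.approx(truth.jump + 0.250)
        assert abs(s.x[-1]) < 1e-9

    def test_latency_law_first_differing_sample(self, noise_free_config):
        """Left and right x-traces separate one visuomotor latency after
        the jump, within one sample period."""
        sl, tl = tj.simulate_trial(make_meta("L", direction=tj.LEFT), noise_free_config)
        sr, _ = tj.simulate_trial(make_meta("R", index=1, direction=tj.RIGHT),
                                  noise_free_config)
        n = min(sl.n, sr.n)
        differ = np.flatnonzero(np.abs(sr.x[:n] - sl.x[:n]) > 1e-12)
        t_diverge = sl.t[differ[0]]
        expected = tl.jump + noise_free_config.visuomotor_latency
        assert abs(t_diverge - expected) <= sl.dt + 1e-9

    def test_vigour_law_peak_scales_with_inverse_square_duration(self, noise_free_config):
        """Peak second derivative of the simulated correction follows
        amplitude / duration^2 with the minimum-jerk constant."""
        for mt in (0.36, 0.42, 0.48):
            cfg = tj.noise_free(noise_free_config, movement_time_mean={
                tj.STAY: {"large": mt, "small": mt},
                tj.JUMP_BACK: {"large": mt, "small": mt}})
            s, truth = tj.simulate_trial(make_meta(), cfg)
            a = np.gradient(np.gradient(s.x, s.t), s.t)
            sel = (s.t > truth.correction_start + 0.01) \
                & (s.t < truth.correction_start + truth.correction_duration - 0.01)
            expected = PEAK_ACCEL_COEFF * truth.amplitude / truth.correction_duration ** 2
            assert np.max(a[sel]) == pytest.approx(expected, rel=0.01)

    def test_no_move_trial_never_leaves_screen(self):
        cfg = tj.noise_free(no_move_probability=1.0)
        meta = make_meta()
        s, truth = tj.simulate_trial(meta, cfg)
        assert truth.no_move and truth.onset is None
        assert np.all(s.z < 0.005) and meta.hit is False

    def test_gentle_tap_has_no_spike_but_truth_time(self):
        cfg = tj.noise_free(gentle_tap_probability=1.0)
        s, truth = tj.simulate_trial(make_meta(), cfg)
        assert truth.gentle and truth.tap is not None
        assert tj.detect_tap(s, truth.onset) is None


class TestExperiment:
    def test_experiment_counts_and_determinism(self):
        plan = tj.ExperimentPlan(n_participants=1)
        cfg = tj.SimulationConfig(seed=21)
        s1, m1, t1 = tj.simulate_experiment(plan, cfg)
        assert len(m1) == 480 and sum(m.analysed for m in m1) == 400
        s2, m2, t2 = tj.simulate_experiment(plan, cfg)
        tid = m1[37].trial_id
        np.testing.assert_array_equal(s1[tid].x, s2[tid].x)
        assert [m.jump_direction for m in m1] == [m.jump_direction for m in m2]
        assert t1[tid].to_dict() == t2[tid].to_dict()

    def test_clean_config_yields_all_detected_taps(self):
        """With every nuisance off, every trial ends in a detectable tap."""
        plan = tj.ExperimentPlan(n_participants=1, blocks_per_session=2,
                                 sessions_per_participant=1,
                                 warmup_blocks_per_session=0)
        cfg = tj.noise_free(seed=3)
        series, metas, truths = tj.simulate_experiment(plan, cfg)
        for m in metas:
            ev = tj.compute_events(series[m.trial_id], m.condition)
            assert ev.tap_quality == "detected"
            assert ev.tap == pytest.approx(truths[m.trial_id].tap, abs=1.5 * 0.002)
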