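"""Pairing, difference traces, and the vigour statistic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tapjump as tj
from tapjump.simulate import PEAK_ACCEL_COEFF

from conftest import make_meta


def block_metas(order, participant=1, session=1, block=2, condition=tj.STAY):
    """Build a block's metadata from a left/right character string."""
    metas, counts = [], {"L": 0, "R": 0}
    for i, ch in enumerate(order):
        counts[ch] += 1
        metas.append(tj.TrialMeta(
            f"B{block}T{i:02d}", participant, session, block, i, condition,
            0.03, tj.LEFT if ch == "L" else tj.RIGHT, counts[ch], True))
    return metas


def pair_tools(pair_fixture, condition=tj.STAY):
    series = pair_fixture["series"]
    events = {tid: tj.compute_events(s, condition) for tid, s in series.items()}
    traces = {tid: tj.acceleration_trace(s) for tid, s in series.items()}
    return series, events, traces


class TestPairing:
    def test_pairs_by_occurrence_rank(self):
        metas = block_metas("LRLRLRLRLR" * 2)
        pairs = tj.pair_trials(metas)
        assert len(pairs) == 10
        for k, p in enumerate(pairs, start=1):
            assert p.pair_index == k
            assert p.left_trial == metas[2 * (k - 1)].trial_id
            assert p.right_trial == metas[2 * k - 1].trial_id

    @given(st.randoms(use_true_random=False))
    def test_pairing_invariant_to_trial_positions(self, rnd):
        """Pairing depends only on the occurrence rank of each direction:
        a brute-force re-ranking oracle agrees for any interleaving."""
        order = list("L" * 10 + "R" * 10)
        rnd.shuffle(order)
        metas = block_metas("".join(order))
        pairs = tj.pair_trials(metas)
        lefts = [m.trial_id for m in metas if m.jump_direction == tj.LEFT]
        rights = [m.trial_id for m in metas if m.jump_direction == tj.RIGHT]
        for k, p in enumerate(pairs):
            assert (p.left_trial, p.right_trial) == (lefts[k], rights[k])

    def test_unbalanced_block_raises(self):
        with pytest.raises(tj.pairs.PairingError, match="B2"):
            tj.pair_trials(block_metas("L" * 11 + "R" * 9))

    def test_no_move_member_disables_pair(self, small_cohort):
        led = small_cohort["ledger"]
        measures = small_cohort["measures"]
        assert (measures.usable_for_acceleration.sum()
                == len(measures) - (~measures.usable_for_acceleration).sum())
        no_move_ids = set(led.index[led.no_move])
        if no_move_ids:
            assert (~measures.usable_for_acceleration).sum() >= 1


class TestAccelerationDifference:
    def test_identical_traces_cancel(self, noise_free_pair):
        """Jump-independent curvature is identical in both members and
        subtracts out: differencing a trial against itself gives zero."""
        series, events, traces = pair_tools(noise_free_pair)
        pair = tj.TrialPair(1, 1, 2, tj.STAY, 0.03, 1, "L", "L")
        d = tj.acceleration_difference(pair, traces, events)
        np.testing.assert_allclose(d.delta_accel[d.accel_valid], 0.0, atol=1e-12)

    def test_antisymmetry_under_relabeling(self, noise_free_pair):
        series, events, traces = pair_tools(noise_free_pair)
        fwd = tj.TrialPair(1, 1, 2, tj.STAY, 0.03, 1, "L", "R")
        rev = tj.TrialPair(1, 1, 2, tj.STAY, 0.03, 1, "R", "L")
        df = tj.acceleration_difference(fwd, traces, events)
        dr = tj.acceleration_difference(rev, traces, events)
        both = df.accel_valid & dr.accel_valid
        np.testing.assert_allclose(df.delta_accel[both], -dr.delta_accel[both],
                                   atol=1e-12)

    def test_peak_matches_doubled_minimum_jerk_law(self, noise_free_pair):
        """Both members respond, so the difference peak is twice the
        single-trial closed-form peak (within filter attenuation)."""
        series, events, traces = pair_tools(noise_free_pair)
        truth = noise_free_pair["truths"]["R"]
        pair = tj.TrialPair(1, 1, 2, tj.STAY, 0.03, 1, "L", "R")
        d = tj.acceleration_difference(pair, traces, events)
        vm = tj.vigour(d, events, pair, traces)
        expected = 2 * PEAK_ACCEL_COEFF * truth.amplitude / truth.correction_duration ** 2
        assert vm.vigour == pytest.approx(expected, rel=0.03)
        assert vm.remaining_time == pytest.approx(truth.tap - truth.jump, abs=0.01)


class TestPositionHalfDifference:
    def test_full_compensation_converges_to_jump_magnitude(self, noise_free_pair):
        """Stay pairs with gain 1 end displaced by exactly one 2.6 cm jump."""
        series, events, traces = pair_tools(noise_free_pair)
        pair = tj.TrialPair(1, 1, 2, tj.STAY, 0.03, 1, "L", "R")
        d = tj.position_half_difference(pair, series, events)
        assert d.half_delta_pos[0] == pytest.approx(0.026, rel=0.01)
        # early in the movement (long before the tap) there is no response yet
        assert abs(d.half_delta_pos[d.pos_valid][-1]) < 0.002

    def test_zero_gain_trace_is_flat(self):
        cfg = tj.noise_free(first_response_gain={tj.STAY: 0.0, tj.JUMP_BACK: 0.0})
        sl, _ = tj.simulate_trial(make_meta("L", direction=tj.LEFT), cfg)
        sr, _ = tj.simulate_trial(make_meta("R", index=1, direction=tj.RIGHT), cfg)
        series = {"L": sl, "R": sr}
        events = {tid: tj.compute_events(s, tj.STAY) for tid, s in series.items()}
        pair = tj.TrialPair(1, 1, 2, tj.STAY, 0.03, 1, "L", "R")
        d = tj.position_half_difference(pair, series, events)
        np.testing.assert_allclose(d.half_delta_pos[d.pos_valid], 0.0, atol=1e-9)

    def test_jump_back_returns_to_zero(self):
        cfg = tj.noise_free()
        ml = make_meta("L", condition=tj.JUMP_BACK, block=3, direction=tj.LEFT)
        mr = make_meta("R", condition=tj.JUMP_BACK, block=3, index=1,
                       direction=tj.RIGHT)
        sl, _ = tj.simulate_trial(ml, cfg)
        sr, _ = tj.simulate_trial(mr, cfg)
        series = {"L": sl, "R": sr}
        events = {tid: tj.compute_events(s, tj.JUMP_BACK) for tid, s in series.items()}
        pair = tj.TrialPair(1, 1, 3, tj.JUMP_BACK, 0.03, 1, "L", "R")
        d = tj.position_half_difference(pair, series, events)
        assert abs(d.half_delta_pos[0]) < 0.002


class TestVigour:
    def test_tie_break_earliest_peak(self):
        t = np.arange(50) * 0.002
        delta = np.zeros(50)
        delta[[20, 30]] = 5.0  # two equal maxima
        diff = tj.ResponseDifference(t_from_jump=t, delta_accel=delta,
                                     accel_valid=np.ones(50, bool))
        ev = tj.EventTimes(onset=0.0, jump=0.0, tap=0.098, tap_quality="detected")
        tr = tj.AccelerationTrace(t, delta, delta, np.ones(50, bool))
        pair = tj.TrialPair(1, 1, 2, tj.STAY, 0.03, 1, "L", "R")
        vm = tj.vigour(diff, {"L": ev, "R": ev}, pair, {"L": tr, "R": tr})
        assert vm.peak_time == pytest.approx(t[20])

    def test_vigour_decreases_with_remaining_time(self):
        """Noise-free generative law: shorter remaining time, more
        vigorous correction (strict monotonicity)."""
        vig = []
        for mt in (0.32, 0.38, 0.44, 0.50):
            cfg = tj.noise_free(movement_time_mean={
                tj.STAY: {"large": mt, "small": mt},
                tj.JUMP_BACK: {"large": mt, "small": mt}},
                deadline_after_onset=0.6)
            sl, _ = tj.simulate_trial(make_meta("L", direction=tj.LEFT), cfg)
            sr, truth = tj.simulate_trial(make_meta("R", index=1,
                                                    direction=tj.RIGHT), cfg)
            series = {"L": sl, "R": sr}
            events = {tid: tj.compute_events(s, tj.STAY)
                      for tid, s in series.items()}
            traces = {tid: tj.acceleration_trace(s) for tid, s in series.items()}
            pair = tj.TrialPair(1, 1, 2, tj.STAY, 0.03, 1, "L", "R")
            d = tj.acceleration_difference(pair, traces, events)
            vig.append(tj.vigour(d, events, pair, traces).vigour)
        assert all(a > b for a, b in zip(vig, vig[1:]))

    def test_null_response_difference_traces_average_to_zero(self):
        """With gain 0 there is no systematic left/right difference: the
        across-pair mean of the difference trace vanishes within
        Monte-Carlo error.  (The vigour *peak* itself carries the
        positive bias of any extremum statistic under noise, so the
        calibration check lives at the trace level; the mean peak must
        still sit far below real-response vigour.)"""
        cfg = tj.SimulationConfig(
            seed=17, first_response_gain={tj.STAY: 0.0, tj.JUMP_BACK: 0.0},
            gentle_tap_probability=0.0, no_move_probability=0.0,
            dropout_probability=0.0)
        plan = tj.ExperimentPlan(n_participants=1)
        art_cfg = tj.PipelineConfig(seed=17, plan=plan, simulation=cfg)
        art = tj.run_pipeline(art_cfg, "scratch/test_null", write_raw=False)
        metas, events, traces = art["metas"], art["events"], art["traces"]
        by_block = {}
        for m in metas:
            by_block.setdefault((m.participant, m.session, m.block_index),
                                []).append(m)
        stacks = []
        for block in by_block.values():
            for pair in tj.pair_trials(block, art["ledger"]):
                d = tj.acceleration_difference(pair, traces, events)
                if d is not None:
                    stacks.append(d.delta_accel[:100])
        mean_trace = np.nanmean(np.vstack(stacks), axis=0)
        assert np.sqrt(np.nanmean(mean_trace ** 2)) < 0.3  # m/s^2, ~2 SE
        v = art["measures"].vigour.dropna()
        assert 0 < v.mean() < 2.5  # extremum bias only, well below real ~4-5

    def test_per_block_conservation(self, small_cohort):
        m = small_cohort["measures"]
        per_block = m.groupby(["participant", "session", "block_index"]).size()
        assert (per_block == 10).all()


class TestMeanTraces:
    def test_cell_mean_traces_shapes_and_asymptote(self, small_cohort):
        """The long-format cell-mean traces carry both trace kinds; the
        stay-condition position half-difference at time-before-tap 0
        sits near the 2.6 cm jump (full compensation, noisy mean)."""
        df = tj.mean_difference_traces(
            small_cohort["metas"], small_cohort["series"],
            small_cohort["events"], small_cohort["traces"],
            small_cohort["ledger"])
        assert set(df.kind) == {"delta_accel", "half_delta_pos"}
        assert df.n_pairs.max() <= 15  # 3 participants x 5 replications
        stay0 = df[(df.kind == "half_delta_pos") & (df.condition == tj.STAY)
                   & (df.t == 0.0)]
        assert len(stay0) == 20  # 2 sizes x 10 pair indices
        assert 0.020 < stay0.value.mean() < 0.032
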