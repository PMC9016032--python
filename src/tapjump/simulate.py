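"""Synthetic tapping-task experiments with known generative structure.

The generator is phenomenological, not biomechanical.  Each trial is
composed of three smooth ingredients on a uniform 500 Hz grid:

* a perpendicular (``z``) lift-and-tap profile — minimum-jerk rise off
  the screen, then either a constant-velocity final descent ending in a
  contact kink (a firm tap, detectable through the > 50 m/s^2
  away-from-screen deceleration it produces after filtering) or a
  minimum-jerk landing with zero contact velocity (a "gentle" tap that
  the deceleration criterion cannot see);
* a main-direction (``y``) minimum-jerk transport from the start point
  to the target's interception height, optionally time-warped by a
  random exponent so that peak transport acceleration varies across
  trials the way repeated reaches do;
* a lateral (``x``) channel that is flat until one visuomotor latency
  after the target jump, then follows a minimum-jerk correction of
  amplitude ``gain x jump`` signed by the jump direction, completing at
  the *planned* tap time.  In jump-back trials a second, opposite
  correction starts one latency after the jump back and returns the net
  lateral displacement to zero by the actual tap time.

The vigour statistic downstream is driven by the closed-form peak
acceleration of the minimum-jerk correction,
``a_peak = (10/sqrt(3)) * amplitude / duration**2``,
so vigour is, by construction, a function of the (planned) remaining
time only.  Measurement noise, contiguous marker dropout, gentle taps
and no-move trials are applied last, as independent nuisances.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .config import (
    ConfigError, ExperimentPlan, SimulationConfig,
    LEFT, RIGHT, STAY, JUMP_BACK, size_label,
)
from .types import SampleSeries, TrialMeta, TrialTruth

#: peak acceleration of a minimum-jerk displacement of unit amplitude and
#: unit duration: max of 60 s - 180 s^2 + 120 s^3 over [0, 1] = 10 / sqrt(3)
PEAK_ACCEL_COEFF = 10.0 / math.sqrt(3.0)

#: generative lift threshold; kept equal to the detector's default so the
#: recorded jump time is self-consistent with onset detection
LIFT_THRESHOLD = 0.005


def minimum_jerk(s):
    """Normalized minimum-jerk displacement, ``s`` in [0, 1]."""
    s = np.asarray(s, dtype=float)
    return s ** 3 * (10.0 - 15.0 * s + 6.0 * s ** 2)


def minimum_jerk_correction(amplitude: float, duration: float, t):
    """Displacement of a minimum-jerk correction at time ``t`` from its start.

    Starts and ends at rest (zero velocity and acceleration at both
    endpoints); reaches ``amplitude`` at ``t == duration``.  Its peak
    acceleration is ``PEAK_ACCEL_COEFF * amplitude / duration**2``.

    Raises
    ------
    ValueError
        If ``duration <= 0`` or any ``t`` lies outside ``[0, duration]``.
    """
    if duration <= 0:
        raise ValueError("duration must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > duration):
        raise ValueError("t must lie within [0, duration]")
    out = amplitude * minimum_jerk(t / duration)
    return float(out) if out.ndim == 0 else out


def _ramp(t: np.ndarray, start: float, duration: float, amplitude: float) -> np.ndarray:
    """Minimum-jerk ramp evaluated on a whole grid: 0 before, held after."""
    s = np.clip((t - start) / duration, 0.0, 1.0)
    return amplitude * minimum_jerk(s)


def _lift_crossing_fraction(ratio: float) -> float:
    """Phase s* of a minimum-jerk rise at which it reaches ``ratio`` of its
    amplitude (used to place the lift start so the 5 mm crossing lands on
    the drawn onset time)."""
    return brentq(lambda s: float(minimum_jerk(s)) - ratio, 0.0, 1.0, xtol=1e-12)


def trial_rng(config: SimulationConfig, meta: TrialMeta) -> np.random.Generator:
    """Per-trial random stream keyed by the trial's design address, so a
    single trial can be regenerated without replaying the experiment."""
    key = [int(config.seed), meta.participant, meta.session,
           meta.block_index, meta.trial_index]
    return np.random.default_rng(np.random.SeedSequence(key))


def build_design(plan: ExperimentPlan, config: SimulationConfig) -> list[TrialMeta]:
    """Expand the plan into per-trial metadata (no trajectories).

    Each block receives a random interleaving of 10 leftward and 10
    rightward jumps; ``pair_index`` is the occurrence rank of the
    direction within the block (1-based).
    """
    plan.validate()
    config.validate()
    metas: list[TrialMeta] = []
    half = plan.trials_per_block // 2
    for p in range(1, plan.n_participants + 1):
        diameters = plan.session_diameters(p)
        for s_idx, diameter in enumerate(diameters, start=1):
            for b in range(plan.blocks_per_session):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(config.seed), p, s_idx, b, 104729]))
                directions = np.array([LEFT] * half + [RIGHT] * half)
                rng.shuffle(directions)
                counts = {LEFT: 0, RIGHT: 0}
                for i, direction in enumerate(directions):
                    counts[direction] += 1
                    metas.append(TrialMeta(
                        trial_id=f"P{p:02d}S{s_idx}B{b:02d}T{i:02d}",
                        participant=p, session=s_idx, block_index=b,
                        trial_index=i,
                        condition=plan.condition_of_block(b),
                        target_diameter=float(diameter),
                        jump_direction=str(direction),
                        pair_index=counts[direction],
                        analysed=b >= plan.warmup_blocks_per_session,
                    ))
    return metas


def _planned_movement_time(meta: TrialMeta, config: SimulationConfig,
                           rng: np.random.Generator) -> float:
    base = config.movement_time_mean[meta.condition][size_label(meta.target_diameter)]
    # within-block trend: stay blocks start slow and speed up; jump-back
    # blocks start fast and slow down (the study's time-per-tap pattern)
    trend_sign = 1.0 if meta.condition == STAY else -1.0
    trend = trend_sign * config.block_trend_s * (10 - meta.pair_index) / 9.0
    mt = rng.normal(base + trend, config.movement_time_sd)
    return max(0.15, float(mt))


def simulate_trial(meta: TrialMeta, config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[SampleSeries, TrialTruth]:
    """Generate one trial's sample series and its generative truth record.

    The returned :class:`TrialTruth` carries the exact onset/jump/tap
    times and correction parameters used, so detection and measurement
    stages can be tested for recovery.  ``meta.hit`` is filled in.
    """
    config.validate()
    if rng is None:
        rng = trial_rng(config, meta)
    dt = config.dt
    sign = 1.0 if meta.jump_direction == RIGHT else -1.0

    # draw all behavioural quantities up front, in a fixed order
    no_move = rng.random() < config.no_move_probability
    onset_nom = max(0.08, float(rng.normal(config.onset_time_mean, config.onset_time_sd)))
    mt = _planned_movement_time(meta, config, rng)
    gentle = rng.random() < config.gentle_tap_probability
    prolong = 0.0
    if meta.condition == JUMP_BACK:
        prolong = max(0.0, float(rng.normal(config.jump_back_prolongation_mean,
                                            config.jump_back_prolongation_sd)))
    aim_x, aim_y = rng.normal(0.0, config.aim_error_sd, size=2)
    gamma = float(np.exp(rng.normal(0.0, config.main_accel_cv)))

    truth = TrialTruth(no_move=no_move, gentle=gentle)

    if no_move:
        n = int(round(1.2 / dt)) + 1
        t = np.arange(n) * dt
        x = np.zeros(n)
        y = np.zeros(n)
        z = np.zeros(n)
        series = _measure(meta.trial_id, t, x, y, z, config, rng)
        meta.hit = False
        return series, truth

    tc = onset_nom + mt + prolong              # actual contact time
    planned_tap = tc - prolong                 # what the first response expects
    recorded = tc <= onset_nom + config.deadline_after_onset
    t_end = (tc + config.post_tap_record) if recorded \
        else (onset_nom + config.deadline_after_onset)
    n = int(math.floor(t_end / dt)) + 1
    t = np.arange(n) * dt

    # ---- perpendicular channel ------------------------------------------
    height = config.lift_height
    descent = (config.gentle_contact_duration if gentle
               else height / config.contact_speed)
    s_star = _lift_crossing_fraction(LIFT_THRESHOLD / height)
    t0 = (onset_nom - s_star * (tc - descent)) / (1.0 - s_star)
    t0 = min(t0, tc - descent - 0.05)          # keep a real rise phase
    t0 = max(t0, dt)
    rise = (tc - descent) - t0
    z = np.zeros(n)
    in_rise = (t >= t0) & (t < t0 + rise)
    z[in_rise] = height * minimum_jerk((t[in_rise] - t0) / rise)
    in_desc = (t >= t0 + rise) & (t < tc)
    u = (t[in_desc] - (t0 + rise)) / descent
    if gentle:
        z[in_desc] = height * (1.0 - minimum_jerk(u))
    else:
        z[in_desc] = height * (1.0 - u)

    cross = np.flatnonzero(z > LIFT_THRESHOLD)
    if cross.size == 0:  # cannot happen for sane configs, but fail soft
        truth.degenerate = True
        series = _measure(meta.trial_id, t, np.zeros(n), np.zeros(n), z, config, rng)
        meta.hit = False
        return series, truth
    onset = float(t[cross[0]])                 # the target jumps on this sample
    truth.onset = truth.jump = onset
    truth.tap = tc
    truth.tap_recorded = bool(recorded)
    truth.planned_tap = planned_tap
    if meta.condition == JUMP_BACK:
        truth.jump_back = onset + config.jump_back_delay

    # ---- main-direction channel -----------------------------------------
    y_end = config.appearance_distance - config.target_speed * tc + aim_y
    uy = np.clip((t - t0) / (tc - t0), 0.0, 1.0)
    y = y_end * minimum_jerk(uy ** gamma)

    # ---- lateral channel -------------------------------------------------
    x = _ramp(t, t0, tc - t0, float(aim_x))    # slow idiosyncratic drift
    gain = config.first_response_gain[meta.condition]
    amplitude = sign * gain * config.jump_magnitude
    c1 = onset + config.visuomotor_latency
    d1 = planned_tap - c1
    if d1 >= 2 * dt and gain != 0.0:
        x = x + _ramp(t, c1, d1, amplitude)
        truth.correction_start, truth.correction_duration = c1, d1
        truth.amplitude = amplitude
        if meta.condition == JUMP_BACK:
            c2 = onset + config.jump_back_delay + config.visuomotor_latency
            d2 = tc - c2
            if d2 >= 2 * dt:
                x = x - _ramp(t, c2, d2, amplitude)
                truth.return_start, truth.return_duration = c2, d2
    elif gain != 0.0:
        truth.degenerate = True

    # ---- hit determination (true positions, online tap detection) -------
    hit = False
    if recorded and not gentle:
        x_target = sign * config.jump_magnitude if meta.condition == STAY else 0.0
        y_target = config.appearance_distance - config.target_speed * tc
        xf = float(np.interp(tc, t, x))
        yf = float(np.interp(tc, t, y))
        miss = math.hypot(xf - x_target, yf - y_target)
        hit = miss <= meta.target_diameter / 2.0
    meta.hit = hit

    series = _measure(meta.trial_id, t, x, y, z, config, rng)
    return series, truth


def _measure(trial_id: str, t: np.ndarray, x: np.ndarray, y: np.ndarray,
             z: np.ndarray, config: SimulationConfig,
             rng: np.random.Generator) -> SampleSeries:
    """Apply marker noise and contiguous dropout; invalid samples get NaN."""
    n = len(t)
    sd = config.position_noise_sd
    if sd > 0:
        x = x + rng.normal(0.0, sd, n)
        y = y + rng.normal(0.0, sd, n)
        z = np.clip(z + rng.normal(0.0, sd, n), 0.0, None)
    else:
        x, y, z = x.copy(), y.copy(), z.copy()
    valid = np.ones(n, dtype=bool)
    if config.dropout_probability > 0:
        p_start = config.dropout_probability / config.dropout_mean_run
        starts = np.flatnonzero(rng.random(n) < p_start)
        if starts.size:
            lengths = rng.geometric(1.0 / config.dropout_mean_run, size=starts.size)
            for s, length in zip(starts, lengths):
                valid[s:s + int(length)] = False
    x[~valid] = np.nan
    y[~valid] = np.nan
    z[~valid] = np.nan
    return SampleSeries(trial_id=trial_id, t=t, x=x, y=y, z=z, valid=valid)


def simulate_experiment(plan: ExperimentPlan, config: SimulationConfig,
                        ) -> tuple[dict[str, SampleSeries], list[TrialMeta],
                                   dict[str, TrialTruth]]:
    """Generate a full experiment: one series + meta + truth per trial.

    Deterministic given ``config.seed``: every trial draws from its own
    substream keyed by (seed, participant, session, block, trial).
    """
    metas = build_design(plan, config)
    series: dict[str, SampleSeries] = {}
    truths: dict[str, TrialTruth] = {}
    for meta in metas:
        s, truth = simulate_trial(meta, config)
        series[meta.trial_id] = s
        truths[meta.trial_id] = truth
    return series, metas, truths
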