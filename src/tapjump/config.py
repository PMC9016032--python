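"""Experiment design, task geometry and generator configuration.

The task being modelled: a participant rests a finger on a start point at
the bottom of a slanted screen; a disk-shaped target appears 48 cm above
the start point and moves straight down at 10 cm/s; the participant must
tap it before its leading edge reaches a horizontal line 800 ms later.
The moment the finger lifts more than 5 mm off the screen the target
jumps 2.6 cm to the left or right.  In alternating blocks of 20 trials
the target either stays on its displaced path or jumps back to the
original path 150 ms later.  Two sessions are run per participant, one
per target size (3 cm and 1.5 cm diameter), order counterbalanced.

Everything downstream (event detection thresholds, pairing, vigour,
fits) keys off the constants collected here.  Units are SI throughout
(metres, seconds); report writers convert to cm / ms where the field's
conventional figures use those.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

# condition / direction labels used across all tables
STAY = "stay"
JUMP_BACK = "jump_back"
LEFT = "left"
RIGHT = "right"

LARGE_DIAMETER = 0.03  # m
SMALL_DIAMETER = 0.015  # m

#: time after appearance at which the target's leading edge reaches the line
TIME_TO_LINE = 0.800  # s


class ConfigError(ValueError):
    """A configuration value is out of its legal range (names the field)."""


def line_offset(diameter: float, target_speed: float = 0.10,
                time_to_line: float = TIME_TO_LINE) -> float:
    """Distance below the appearance point at which the horizontal line sits.

    The line is placed so the target's *leading edge* (centre + radius)
    reaches it ``time_to_line`` after appearance: 9.5 cm for the 3 cm
    target, 8.75 cm for the 1.5 cm target at 10 cm/s.
    """
    if diameter <= 0:
        raise ConfigError("diameter must be positive")
    return target_speed * time_to_line + diameter / 2.0


def size_label(diameter: float) -> str:
    """Map a target diameter to the ``large`` / ``small`` label."""
    return "large" if diameter >= 0.02 else "small"


@dataclass
class ExperimentPlan:
    """The block/session structure of the experiment.

    Defaults reproduce the study design: 10 participants x 2 sessions x
    12 blocks x 20 trials, conditions alternating between blocks, every
    session starting with a stay block, the first two blocks of each
    session treated as warm-up and excluded from analysis, and one
    target size per session (order counterbalanced across participants).
    """

    n_participants: int = 10
    sessions_per_participant: int = 2
    blocks_per_session: int = 12
    trials_per_block: int = 20
    warmup_blocks_per_session: int = 2
    first_block_condition: str = STAY
    target_diameters: tuple[float, float] = (LARGE_DIAMETER, SMALL_DIAMETER)
    counterbalance_sessions: bool = True

    def validate(self) -> None:
        for name in ("n_participants", "sessions_per_participant",
                     "blocks_per_session", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if self.trials_per_block % 2:
            raise ConfigError("trials_per_block must be even (10 left + 10 right jumps)")
        if not 0 <= self.warmup_blocks_per_session < self.blocks_per_session:
            raise ConfigError("warmup_blocks_per_session must be in [0, blocks_per_session)")
        if self.first_block_condition not in (STAY, JUMP_BACK):
            raise ConfigError("first_block_condition must be 'stay' or 'jump_back'")
        for d in self.target_diameters:
            if d <= 0:
                raise ConfigError("target_diameters must be positive")

    def condition_of_block(self, block_index: int) -> str:
        """Condition of a 0-based block index; conditions alternate."""
        first = self.first_block_condition
        other = JUMP_BACK if first == STAY else STAY
        return first if block_index % 2 == 0 else other

    def session_diameters(self, participant: int) -> tuple[float, ...]:
        """Target diameter per session for a 1-based participant id."""
        d = tuple(self.target_diameters)
        if self.counterbalance_sessions and participant % 2 == 0:
            d = d[::-1]
        return d[: self.sessions_per_participant]

    @property
    def analysed_trials_per_participant(self) -> int:
        per_session = (self.blocks_per_session - self.warmup_blocks_per_session) \
            * self.trials_per_block
        return per_session * self.sessions_per_participant

    @property
    def replications_per_condition(self) -> int:
        """Analysed blocks of each condition within a session (5 by default)."""
        return (self.blocks_per_session - self.warmup_blocks_per_session) // 2


@dataclass
class SimulationConfig:
    """Parameters of the phenomenological trajectory generator.

    Task constants (sample rate, jump size, jump-back delay, target
    speed, appearance distance, response deadline) default to the
    experiment's stated values.  Behavioural distributions that the
    study did not print (onset times, movement times) default to values
    consistent with its reported tap times (~0.55-0.75 s after target
    appearance) and ~400 ms movement times; see docs/methods.md.
    """

    seed: int = 0
    sample_rate: float = 500.0            # Hz
    jump_magnitude: float = 0.026         # m, lateral target jump
    jump_back_delay: float = 0.150        # s, first jump -> jump back
    target_speed: float = 0.10            # m/s downward
    appearance_distance: float = 0.48     # m above the start point
    deadline_after_onset: float = 0.500   # s, recording/target timeout
    visuomotor_latency: float = 0.100     # s, jump -> correction onset

    # behavioural distributions (not printed in the study; configurable)
    onset_time_mean: float = 0.25         # s after appearance, N(mean, sd)
    onset_time_sd: float = 0.04
    movement_time_mean: dict[str, dict[str, float]] = field(default_factory=lambda: {
        STAY: {"large": 0.38, "small": 0.42},
        JUMP_BACK: {"large": 0.38, "small": 0.42},
    })
    movement_time_sd: float = 0.03
    #: within-block linear trend of planned movement time (s): stay blocks
    #: start slow and speed up, jump-back blocks the reverse (Fig 2C/D style)
    block_trend_s: float = 0.03
    #: extra movement duration caused by responding to the jump back; the
    #: first response is planned for the *pre-prolongation* tap time
    jump_back_prolongation_mean: float = 0.04
    jump_back_prolongation_sd: float = 0.02

    #: fraction of the target jump compensated by the first correction
    first_response_gain: dict[str, float] = field(default_factory=lambda: {
        STAY: 1.0, JUMP_BACK: 0.8,
    })

    # movement shape
    lift_height: float = 0.05             # m, peak finger height above screen
    contact_speed: float = 1.3            # m/s, approach speed at a firm tap
    gentle_contact_duration: float = 0.10  # s, smooth landing of a gentle tap
    aim_error_sd: float = 0.005           # m, endpoint scatter (x and y)
    main_accel_cv: float = 0.2            # lognormal sd of transport time-warp

    # measurement imperfections
    position_noise_sd: float = 0.0002     # m, additive marker noise
    dropout_probability: float = 0.005    # per-sample marginal dropout rate
    dropout_mean_run: float = 8.0         # mean dropout run length (samples)
    gentle_tap_probability: float = 0.04  # per trial
    no_move_probability: float = 0.00125  # per trial (5 / 4000)
    post_tap_record: float = 0.060        # s of recording kept after the tap

    def validate(self) -> None:
        positive = ("sample_rate", "jump_magnitude", "jump_back_delay",
                    "target_speed", "appearance_distance", "deadline_after_onset",
                    "visuomotor_latency", "onset_time_mean",
                    "lift_height", "contact_speed", "gentle_contact_duration",
                    "dropout_mean_run", "post_tap_record")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        nonneg = ("onset_time_sd", "movement_time_sd", "block_trend_s",
                  "jump_back_prolongation_mean",
                  "jump_back_prolongation_sd", "aim_error_sd", "main_accel_cv",
                  "position_noise_sd")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        probs = ("dropout_probability", "gentle_tap_probability", "no_move_probability")
        for name in probs:
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        for cond in (STAY, JUMP_BACK):
            if cond not in self.movement_time_mean:
                raise ConfigError(f"movement_time_mean missing condition '{cond}'")
            for size in ("large", "small"):
                if size not in self.movement_time_mean[cond]:
                    raise ConfigError(f"movement_time_mean[{cond!r}] missing size '{size}'")
                if self.movement_time_mean[cond][size] <= 0:
                    raise ConfigError("movement_time_mean values must be strictly positive")
            if cond not in self.first_response_gain:
                raise ConfigError(f"first_response_gain missing condition '{cond}'")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        return cls(**d)


def noise_free(config: SimulationConfig | None = None, **overrides: Any) -> SimulationConfig:
    """A copy of ``config`` with every stochastic nuisance switched off.

    Deterministic onset and movement times, no marker noise, no dropout,
    no gentle taps, no no-move trials, no aim error, no transport-shape
    jitter, no within-block trend and no jump-back prolongation.  Useful
    for closed-form checks of the generative laws.
    """
    base = (config.to_dict() if config is not None else SimulationConfig().to_dict())
    base.update(dict(
        onset_time_sd=0.0, movement_time_sd=0.0, block_trend_s=0.0,
        jump_back_prolongation_mean=0.0, jump_back_prolongation_sd=0.0,
        aim_error_sd=0.0, main_accel_cv=0.0, position_noise_sd=0.0,
        dropout_probability=0.0, gentle_tap_probability=0.0,
        no_move_probability=0.0,
    ))
    base.update(overrides)
    cfg = SimulationConfig.from_dict(base)
    cfg.validate()
    return cfg


@dataclass
class KinematicsConfig:
    """Thresholds of the event-detection stage (experiment defaults)."""

    lift_threshold: float = 0.005        # m; movement onset / target jump
    tap_accel_threshold: float = 50.0    # m/s^2 away from the screen
    sg_half_window: float = 0.020        # s; 21 samples at 500 Hz
    stop_gate: float = 0.010             # m; gate for "stopped moving" estimate
    #: |z-velocity| below this counts as "stopped"; ~3x the filtered
    #: velocity noise at 0.2 mm marker noise, so a resting finger is
    #: recognised even when correlated noise keeps the estimate slightly
    #: negative
    stop_velocity_tol: float = 0.010     # m/s
    extrap_max_gap: float = 0.050        # s; reject longer extrapolations
    extrap_tail_samples: int = 10        # final samples used for extrapolation
    tap_search_margin: float = 0.050     # s past the deadline

    def validate(self) -> None:
        for name in ("lift_threshold", "tap_accel_threshold", "sg_half_window",
                     "stop_gate", "extrap_max_gap", "tap_search_margin"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.extrap_tail_samples < 2:
            raise ConfigError("extrap_tail_samples must be at least 2")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "KinematicsConfig":
        return cls(**d)
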