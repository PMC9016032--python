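"""Shared record types passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np


@dataclass
class SampleSeries:
    """One trial's finger-marker positions on a uniform 500 Hz grid.

    ``t`` is seconds since target appearance; ``x`` lateral (rightward
    positive), ``y`` up-screen from the start point, ``z`` perpendicular
    distance from the screen (non-negative).  Samples flagged invalid
    (marker dropout) carry NaN positions.
    """

    trial_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "z", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{self.trial_id}: channel {name} length mismatch")
        if n >= 2:
            steps = np.diff(self.t)
            if steps.min() <= 0 or np.ptp(steps) > 1e-9:
                raise ValueError(
                    f"{self.trial_id}: sample times must be uniform and increasing")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.n >= 2 else float("nan")


@dataclass
class TrialMeta:
    """Design-level description of a trial."""

    trial_id: str
    participant: int
    session: int
    block_index: int        # 0-based within session
    trial_index: int        # 0-based within block
    condition: str          # stay | jump_back
    target_diameter: float  # m
    jump_direction: str     # left | right
    pair_index: int         # 1..10, i-th occurrence of that direction in block
    analysed: bool          # False for warm-up blocks
    hit: bool | None = None


@dataclass
class TrialTruth:
    """Generative ground truth recorded alongside a simulated trial."""

    onset: float | None = None          # first sample with z > 5 mm
    jump: float | None = None           # equals onset (target jumps on lift)
    jump_back: float | None = None
    tap: float | None = None            # contact time (recorded or not)
    tap_recorded: bool = False          # contact lies inside the recording
    planned_tap: float | None = None    # onset + planned movement time
    correction_start: float | None = None
    correction_duration: float | None = None
    return_start: float | None = None
    return_duration: float | None = None
    amplitude: float | None = None      # signed first-correction amplitude, m
    gentle: bool = False
    no_move: bool = False
    degenerate: bool = False            # correction window < one sample

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrialTruth":
        return cls(**d)


TAP_DETECTED = "detected"
TAP_STOP_ESTIMATED = "stop_estimated"
TAP_EXTRAPOLATED = "extrapolated"
TAP_MISSING = "missing"

TAP_QUALITIES = (TAP_DETECTED, TAP_STOP_ESTIMATED, TAP_EXTRAPOLATED, TAP_MISSING)


@dataclass
class EventTimes:
    """Per-trial landmark times (s since target appearance)."""

    appearance: float = 0.0
    onset: float | None = None
    jump: float | None = None
    jump_back: float | None = None
    tap: float | None = None
    tap_quality: str = TAP_MISSING
    #: why no usable tap time exists (e.g. rejected extrapolation)
    tap_note: str = ""
    hit: bool | None = None

    def __post_init__(self) -> None:
        if self.tap_quality not in TAP_QUALITIES:
            raise ValueError(f"unknown tap quality {self.tap_quality!r}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
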