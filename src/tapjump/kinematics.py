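"""Event detection and filtered kinematics for raw sample series.

Acceleration (and velocity) traces come from a second-order
Savitzky-Golay filter over a +/-20 ms window (21 samples at 500 Hz):
the second derivative assigned to each sample is twice the quadratic
coefficient of the least-squares parabola over its window, i.e. the
filter is exact for polynomials of degree <= 2.  Windows touching any
invalid (dropped) sample yield an invalid output sample — no curvature
is fabricated across marker occlusions — so the first and last 10
samples of every contiguous valid run are always invalid.

Event logic mirrors the experiment:

* movement onset — first valid sample with z > 5 mm; the target jump is
  simultaneous with it by design;
* tap — first away-from-screen z-acceleration excursion above 50 m/s^2
  after onset; the reported tap time is the peak of that excursion;
* when no excursion exists, the tap time is estimated, first from the
  moment the finger stops moving towards the screen near the surface,
  otherwise by linearly extrapolating the final valid samples to z = 0,
  accepted only when the extrapolated contact lies within 50 ms of the
  last valid recording.  Trials with no acceptable estimate keep a +inf
  sentinel for their time measures (legal only inside medians).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .config import KinematicsConfig, JUMP_BACK
from .types import (
    SampleSeries, TrialMeta, EventTimes,
    TAP_DETECTED, TAP_STOP_ESTIMATED, TAP_EXTRAPOLATED, TAP_MISSING,
)


@dataclass
class DerivativeTrace:
    """A filtered derivative of one position channel on the sample grid."""

    t: np.ndarray
    value: np.ndarray
    valid: np.ndarray
    axis: str
    deriv: int


@dataclass
class AccelerationTrace:
    """Lateral and main-direction acceleration; valid where both are."""

    t: np.ndarray
    a_x: np.ndarray
    a_y: np.ndarray
    valid: np.ndarray


def _window_length(half_window: float, dt: float) -> int:
    half = int(round(half_window / dt))
    if abs(half * dt - half_window) > 1e-9:
        raise ValueError("half_window must be a multiple of the sample period")
    return 2 * half + 1


def savgol_derivative(series: SampleSeries, axis: str = "x", deriv: int = 2,
                      half_window: float = 0.020) -> DerivativeTrace:
    """Savitzky-Golay derivative of one channel, invalid-aware.

    The filter runs independently over each contiguous run of valid
    samples; runs shorter than the window produce no valid output.
    """
    if axis not in ("x", "y", "z"):
        raise ValueError(f"unknown axis {axis!r}")
    pos = np.asarray(getattr(series, axis), dtype=float)
    dt = series.dt
    window = _window_length(half_window, dt)
    half = window // 2
    out = np.full(series.n, np.nan)
    out_valid = np.zeros(series.n, dtype=bool)
    ok = series.valid & np.isfinite(pos)
    if series.n < window or not ok.any():
        if series.n < window:
            warnings.warn(
                f"{series.trial_id}: fewer than {window} samples; "
                "derivative trace is all-invalid", stacklevel=2)
        return DerivativeTrace(series.t, out, out_valid, axis, deriv)
    # contiguous valid runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < window:
            continue
        vals = savgol_filter(pos[start:stop], window, polyorder=2,
                             deriv=deriv, delta=dt)
        out[start + half:stop - half] = vals[half:-half]
        out_valid[start + half:stop - half] = True
    out[~out_valid] = np.nan
    return DerivativeTrace(series.t, out, out_valid, axis, deriv)


def savitzky_golay_acceleration(series: SampleSeries, axis: str = "x",
                                half_window: float = 0.020) -> DerivativeTrace:
    """Acceleration of one channel (m/s^2), the pipeline's only smoother."""
    return savgol_derivative(series, axis=axis, deriv=2, half_window=half_window)


def acceleration_trace(series: SampleSeries,
                       half_window: float = 0.020) -> AccelerationTrace:
    """Lateral and main-direction acceleration on a shared validity mask."""
    ax = savgol_derivative(series, "x", 2, half_window)
    ay = savgol_derivative(series, "y", 2, half_window)
    return AccelerationTrace(series.t, ax.value, ay.value, ax.valid & ay.valid)


def detect_movement_onset(series: SampleSeries,
                          lift_threshold: float = 0.005) -> float | None:
    """Time of the first valid sample with z above the lift threshold."""
    above = series.valid & np.isfinite(series.z) & (series.z > lift_threshold)
    idx = np.flatnonzero(above)
    return float(series.t[idx[0]]) if idx.size else None


def detect_tap(series: SampleSeries, onset: float,
               config: KinematicsConfig | None = None,
               ) -> tuple[float, str] | None:
    """Detect the tap from the away-from-screen deceleration spike.

    Returns ``(time, "detected")`` using the peak of the first
    supra-threshold excursion of the filtered z-acceleration after
    onset, or ``None`` when no excursion exists in the search window
    (onset to onset + deadline + margin).
    """
    cfg = config or KinematicsConfig()
    az = savgol_derivative(series, "z", 2, cfg.sg_half_window)
    window_end = onset + 0.5 + cfg.tap_search_margin
    cand = az.valid & (series.t > onset) & (series.t <= window_end) \
        & (az.value > cfg.tap_accel_threshold)
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return None
    # walk the first contiguous excursion and take its peak
    first = idx[0]
    stop = first
    while stop + 1 < series.n and cand[stop + 1]:
        stop += 1
    peak = first + int(np.nanargmax(az.value[first:stop + 1]))
    return float(series.t[peak]), TAP_DETECTED


def estimate_tap_time(series: SampleSeries, onset: float,
                      config: KinematicsConfig | None = None,
                      ) -> tuple[float | None, str, str]:
    """Estimate the tap time when no deceleration spike was detected.

    Preferred: the moment the finger stops moving towards the screen
    (first non-negative filtered z-velocity after descending below the
    10 mm gate).  Fallback: a least-squares line over the final valid
    samples extrapolated to z = 0, accepted only when the extrapolated
    contact is at most 50 ms past the last valid sample.  Returns
    ``(time, quality, note)``; time is None when no estimate survives.
    """
    cfg = config or KinematicsConfig()
    ok = series.valid & np.isfinite(series.z)
    after = ok & (series.t > onset)
    if after.sum() < 2:
        return None, TAP_MISSING, "too_few_valid_samples"

    # --- "stopped moving towards the screen" ------------------------------
    vz = savgol_derivative(series, "z", 1, cfg.sg_half_window)
    t_peak = series.t[np.nanargmax(np.where(after, series.z, -np.inf))]
    near = vz.valid & after & (series.t > t_peak) & (series.z < cfg.stop_gate)
    idx = np.flatnonzero(near & (vz.value >= -cfg.stop_velocity_tol))
    if idx.size:
        return float(series.t[idx[0]]), TAP_STOP_ESTIMATED, ""

    # --- linear extrapolation of the final descent ------------------------
    tail = np.flatnonzero(after)[-cfg.extrap_tail_samples:]
    if tail.size < 2:
        return None, TAP_MISSING, "too_few_valid_samples"
    tt, zz = series.t[tail], series.z[tail]
    slope, intercept = np.polyfit(tt, zz, 1)
    if slope >= 0:
        return None, TAP_MISSING, "extrapolation_rejected"
    t_hit = -intercept / slope
    gap = t_hit - float(tt[-1])
    if -0.01 <= gap <= cfg.extrap_max_gap:
        return float(t_hit), TAP_EXTRAPOLATED, ""
    return None, TAP_MISSING, "extrapolation_rejected"


def compute_events(series: SampleSeries, condition: str,
                   config: KinematicsConfig | None = None,
                   jump_back_delay: float = 0.150,
                   hit: bool | None = None) -> EventTimes:
    """Full event extraction for one trial."""
    cfg = config or KinematicsConfig()
    onset = detect_movement_onset(series, cfg.lift_threshold)
    if onset is None:
        return EventTimes(onset=None, jump=None, tap=None,
                          tap_quality=TAP_MISSING, tap_note="no_move", hit=hit)
    jump_back = onset + jump_back_delay if condition == JUMP_BACK else None
    det = detect_tap(series, onset, cfg)
    if det is not None:
        tap, quality = det
        note = ""
    else:
        tap, quality, note = estimate_tap_time(series, onset, cfg)
    return EventTimes(onset=onset, jump=onset, jump_back=jump_back,
                      tap=tap, tap_quality=quality, tap_note=note, hit=hit)


def build_exclusion_ledger(events: dict[str, EventTimes],
                           metas: list[TrialMeta]) -> pd.DataFrame:
    """Per-trial usability flags, mirroring the study's data accounting.

    ``usable_for_acceleration``: everything except no-move trials (only
    the jump time is needed).  ``usable_for_time_before_tap``: a usable
    tap time exists (detected or estimated); others carry the +inf
    sentinel.  ``usable_for_position_trace``: the tap was *detected* —
    position-against-time-before-tap needs the precise contact moment.
    """
    rows = []
    for meta in metas:
        ev = events[meta.trial_id]
        no_move = ev.onset is None
        quality = ev.tap_quality
        usable_time = quality in (TAP_DETECTED, TAP_STOP_ESTIMATED, TAP_EXTRAPOLATED)
        rows.append({
            "trial_id": meta.trial_id,
            "no_move": no_move,
            "tap_undetected": quality != TAP_DETECTED,
            "tap_estimated_by_stop": quality == TAP_STOP_ESTIMATED,
            "tap_extrapolated": quality == TAP_EXTRAPOLATED,
            "extrapolation_rejected": ev.tap_note == "extrapolation_rejected",
            "assigned_extreme_time": not usable_time,
            "usable_for_acceleration": not no_move,
            "usable_for_time_before_tap": usable_time,
            "usable_for_position_trace": quality == TAP_DETECTED,
        })
    ledger = pd.DataFrame(rows).set_index("trial_id")
    # structural invariants of the accounting
    bad = ledger.no_move & (ledger.usable_for_acceleration
                            | ledger.usable_for_time_before_tap)
    if bad.any():
        raise RuntimeError("ledger invariant violated: no-move trial marked usable")
    return ledger


def events_table(events: dict[str, EventTimes],
                 metas: list[TrialMeta]) -> pd.DataFrame:
    """Events as a tidy one-row-per-trial table (for the events CSV)."""
    rows = []
    for meta in metas:
        d = events[meta.trial_id].to_dict()
        d["trial_id"] = meta.trial_id
        rows.append(d)
    cols = ["trial_id", "appearance", "onset", "jump", "jump_back",
            "tap", "tap_quality", "tap_note", "hit"]
    return pd.DataFrame(rows)[cols]
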