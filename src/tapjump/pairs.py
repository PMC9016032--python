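"""Left/right trial pairing and the paired response measures.

Because movements curve idiosyncratically even without a target jump,
the response to the jump is isolated by differencing trials: within
each block the i-th leftward-jump trial is paired with the i-th
rightward-jump trial, and the right-minus-left difference of the
lateral acceleration (each trial aligned to its own jump time) cancels
jump-independent curvature.  The *vigour* of the response is the signed
peak of that difference over the response window.  The lateral-position
half-difference, indexed by time before each trial's own tap, shows how
far the finger's position was displaced by a single jump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LEFT, RIGHT, JUMP_BACK
from .kinematics import AccelerationTrace
from .types import SampleSeries, TrialMeta, EventTimes


class PairingError(ValueError):
    """Block structure does not permit pairing (names the block)."""


#: only the response to the *first* jump is quantified.  In jump-back
#: trials a second, opposite correction begins roughly one visuomotor
#: latency (~100 ms) after the jump back (150 ms), i.e. ~250 ms after the
#: first jump; its deceleration lobe points in the first-jump direction
#: and would otherwise masquerade as first-response vigour, so the peak
#: search in jump-back pairs stops here (s from the jump).
FIRST_RESPONSE_WINDOW = 0.250


@dataclass
class TrialPair:
    participant: int
    session: int
    block_index: int
    condition: str
    target_diameter: float
    pair_index: int
    left_trial: str
    right_trial: str
    usable_for_acceleration: bool = True
    usable_for_position: bool = True

    @property
    def members(self) -> tuple[str, str]:
        return self.left_trial, self.right_trial


@dataclass
class ResponseDifference:
    """Difference traces of one pair (either part may be absent)."""

    t_from_jump: np.ndarray | None = None
    delta_accel: np.ndarray | None = None
    accel_valid: np.ndarray | None = None
    t_before_tap: np.ndarray | None = None
    half_delta_pos: np.ndarray | None = None
    pos_valid: np.ndarray | None = None


@dataclass
class VigourMeasure:
    vigour: float                 # m/s^2, signed peak of delta_accel
    peak_time: float              # s from jump
    remaining_time: float         # s, pair mean of (tap - jump)
    remaining_times: tuple[float, float]
    reaction_time: float          # s, pair mean of (appearance -> jump)
    peak_main_accel: float        # m/s^2, pair mean of per-trial peaks


def pair_trials(block_trials: list[TrialMeta],
                ledger: pd.DataFrame | None = None) -> list[TrialPair]:
    """Pair the i-th leftward with the i-th rightward jump of a block.

    Pairing depends only on the occurrence rank of each direction, not
    on absolute trial position.  Usability flags propagate from the
    exclusion ledger: a pair is unusable for a measure when either
    member is.
    """
    if not block_trials:
        raise PairingError("empty block")
    key = (block_trials[0].participant, block_trials[0].session,
           block_trials[0].block_index)
    ordered = sorted(block_trials, key=lambda m: m.trial_index)
    lefts = [m for m in ordered if m.jump_direction == LEFT]
    rights = [m for m in ordered if m.jump_direction == RIGHT]
    if len(lefts) != len(rights):
        raise PairingError(
            f"block P{key[0]}/S{key[1]}/B{key[2]} has {len(lefts)} left and "
            f"{len(rights)} right jumps; expected equal counts")
    pairs = []
    for rank, (lt, rt) in enumerate(zip(lefts, rights), start=1):
        usable_acc = usable_pos = True
        if ledger is not None:
            rows = ledger.loc[[lt.trial_id, rt.trial_id]]
            usable_acc = bool(rows.usable_for_acceleration.all())
            usable_pos = bool(rows.usable_for_position_trace.all())
        pairs.append(TrialPair(
            participant=lt.participant, session=lt.session,
            block_index=lt.block_index, condition=lt.condition,
            target_diameter=lt.target_diameter, pair_index=rank,
            left_trial=lt.trial_id, right_trial=rt.trial_id,
            usable_for_acceleration=usable_acc, usable_for_position=usable_pos))
    return pairs


def _jump_index(t: np.ndarray, jump: float, dt: float) -> int:
    return int(round(jump / dt))


def acceleration_difference(pair: TrialPair,
                            traces: dict[str, AccelerationTrace],
                            events: dict[str, EventTimes],
                            ) -> ResponseDifference | None:
    """Right-minus-left lateral acceleration on a common time-from-jump grid.

    Each member is aligned at its own jump time (which falls on the
    sample grid); samples invalid in either member are invalid in the
    difference.  Returns None when the post-jump overlap is empty.
    """
    evl, evr = events[pair.left_trial], events[pair.right_trial]
    if evl.jump is None or evr.jump is None:
        return None
    trl, trr = traces[pair.left_trial], traces[pair.right_trial]
    dt = float(trl.t[1] - trl.t[0])
    jl = _jump_index(trl.t, evl.jump, dt)
    jr = _jump_index(trr.t, evr.jump, dt)
    k = min(len(trl.t) - jl, len(trr.t) - jr)
    if k <= 0:
        return None
    delta = trr.a_x[jr:jr + k] - trl.a_x[jl:jl + k]
    valid = trr.valid[jr:jr + k] & trl.valid[jl:jl + k]
    return ResponseDifference(
        t_from_jump=np.arange(k) * dt,
        delta_accel=np.where(valid, delta, np.nan),
        accel_valid=valid)


def _interp_before_tap(series: SampleSeries, tap: float,
                       tb_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lateral position at given times-before-tap, linearly interpolated
    over valid samples; points bridging gaps wider than 2.5 samples or
    outside the recorded span are invalid."""
    ok = series.valid & np.isfinite(series.x)
    tq = tap - tb_grid
    tv, xv = series.t[ok], series.x[ok]
    vals = np.interp(tq, tv, xv)
    right = np.searchsorted(tv, tq)
    valid = (tq >= tv[0]) & (tq <= tv[-1])
    inner = valid & (right > 0) & (right < len(tv))
    gap = np.full(len(tq), 0.0)
    gap[inner] = tv[right[inner]] - tv[right[inner] - 1]
    valid &= gap <= 2.5 * series.dt
    return np.where(valid, vals, np.nan), valid


def position_half_difference(pair: TrialPair,
                             series: dict[str, SampleSeries],
                             events: dict[str, EventTimes],
                             ) -> ResponseDifference | None:
    """Half the right-minus-left lateral position against time before tap.

    Each member is re-indexed by time before its *own* tap and linearly
    interpolated onto a common grid at the native sample period; the
    half-difference scales the trace to a single target jump.  Requires
    both taps (pair usable for position); returns None otherwise.
    """
    if not pair.usable_for_position:
        return None
    evl, evr = events[pair.left_trial], events[pair.right_trial]
    if evl.tap is None or evr.tap is None or evl.jump is None or evr.jump is None:
        return None
    sl, sr = series[pair.left_trial], series[pair.right_trial]
    dt = sl.dt
    span = min(evl.tap - evl.jump, evr.tap - evr.jump)
    if span <= 0:
        return None
    tb = np.arange(0.0, span, dt)
    xl, vl = _interp_before_tap(sl, evl.tap, tb)
    xr, vr = _interp_before_tap(sr, evr.tap, tb)
    valid = vl & vr
    half = 0.5 * (xr - xl)
    return ResponseDifference(
        t_before_tap=tb,
        half_delta_pos=np.where(valid, half, np.nan),
        pos_valid=valid)


def vigour(diff: ResponseDifference, events: dict[str, EventTimes],
           pair: TrialPair, traces: dict[str, AccelerationTrace],
           window: tuple[float, float] | None = None) -> VigourMeasure | None:
    """Signed peak of the acceleration difference over the response window.

    The default window runs from the jump to the earlier of the two
    taps, so both members' traces are defined throughout.  Pairs whose
    taps were never recovered still get a measure — only the jump time
    is needed for the difference trace — using the full common overlap
    as the window and carrying +inf as the remaining time.  Ties break
    to the earliest peak.  Returns None when no valid samples fall in
    the window.
    """
    if diff is None or diff.delta_accel is None:
        return None
    evl, evr = events[pair.left_trial], events[pair.right_trial]
    rem = tuple(
        ev.tap - ev.jump if ev.tap is not None else np.inf for ev in (evl, evr))
    if window is None:
        end = min(rem)
        if not np.isfinite(end):
            end = float(diff.t_from_jump[-1])
        if pair.condition == JUMP_BACK:
            end = min(end, FIRST_RESPONSE_WINDOW)
        window = (0.0, end)
    mask = (diff.accel_valid
            & (diff.t_from_jump >= window[0])
            & (diff.t_from_jump <= window[1]))
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    peak = idx[int(np.argmax(diff.delta_accel[idx]))]  # argmax -> earliest tie
    peaks_main = []
    for tid, ev in ((pair.left_trial, evl), (pair.right_trial, evr)):
        tr = traces[tid]
        t_hi = ev.tap if ev.tap is not None else float(tr.t[-1])
        m = tr.valid & (tr.t >= ev.onset) & (tr.t <= t_hi)
        peaks_main.append(float(np.nanmax(tr.a_y[m])) if m.any() else np.nan)
    return VigourMeasure(
        vigour=float(diff.delta_accel[peak]),
        peak_time=float(diff.t_from_jump[peak]),
        remaining_time=float(np.mean(rem)),
        remaining_times=(float(rem[0]), float(rem[1])),
        reaction_time=float(np.mean([evl.jump, evr.jump])),
        peak_main_accel=float(np.mean(peaks_main)))


def mean_difference_traces(metas: list[TrialMeta],
                           series: dict[str, SampleSeries],
                           events: dict[str, EventTimes],
                           traces: dict[str, AccelerationTrace],
                           ledger: pd.DataFrame,
                           span: float = 0.300) -> pd.DataFrame:
    """Cell-mean response traces in long format (plot-ready).

    For every condition x target-size x pair-index cell, the mean
    across usable pairs of (a) the acceleration difference on the
    time-from-jump grid and (b) the position half-difference on the
    time-before-tap grid, each over ``span`` seconds.  One row per
    (cell, kind, time); ``n_pairs`` records how many pairs contributed.
    """
    by_block: dict[tuple, list[TrialMeta]] = {}
    for m in metas:
        if m.analysed:
            by_block.setdefault((m.participant, m.session, m.block_index),
                                []).append(m)
    dt = next(iter(series.values())).dt
    k = int(round(span / dt)) + 1
    sums: dict[tuple, np.ndarray] = {}
    counts: dict[tuple, np.ndarray] = {}

    def accumulate(key, values):
        if key not in sums:
            sums[key] = np.zeros(k)
            counts[key] = np.zeros(k, dtype=int)
        v = values[:k]
        ok = np.isfinite(v)
        sums[key][:len(v)][ok] += v[ok]
        counts[key][:len(v)][ok] += 1

    for block in by_block.values():
        for pair in pair_trials(block, ledger):
            cell = (pair.condition, pair.target_diameter, pair.pair_index)
            if pair.usable_for_acceleration:
                d = acceleration_difference(pair, traces, events)
                if d is not None:
                    accumulate(cell + ("delta_accel",), d.delta_accel)
            if pair.usable_for_position:
                d = position_half_difference(pair, series, events)
                if d is not None:
                    accumulate(cell + ("half_delta_pos",), d.half_delta_pos)

    rows = []
    for key in sorted(sums):
        cond, diam, pidx, kind = key
        n = counts[key]
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, sums[key] / np.maximum(n, 1), np.nan)
        for i in range(k):
            if n[i] == 0:
                continue
            rows.append({
                "condition": cond, "target_diameter": diam,
                "pair_index": pidx, "kind": kind, "t": i * dt,
                "value": mean[i], "n_pairs": int(n[i])})
    return pd.DataFrame(rows)


def _pair_time_measure(values: tuple[float, float]) -> float:
    """Pair-level combination of per-trial time measures: the mean, with
    +inf propagating (a pair containing an extreme trial is extreme)."""
    return float(np.mean(values))


def compute_pair_measures(metas: list[TrialMeta],
                          series: dict[str, SampleSeries],
                          events: dict[str, EventTimes],
                          traces: dict[str, AccelerationTrace],
                          ledger: pd.DataFrame,
                          replications_offset: int = 2) -> pd.DataFrame:
    """One row of response measures per analysed pair.

    ``replication`` numbers the analysed blocks of each condition within
    a session (1..5 for the default plan, warm-up blocks excluded).
    Time measures of trials without a usable tap enter as +inf
    sentinels, legal only inside downstream medians.
    """
    by_block: dict[tuple, list[TrialMeta]] = {}
    for m in metas:
        if m.analysed:
            by_block.setdefault((m.participant, m.session, m.block_index), []).append(m)
    rows = []
    for (p, s, b), block in sorted(by_block.items()):
        for pair in pair_trials(block, ledger):
            evl, evr = events[pair.left_trial], events[pair.right_trial]
            diff = (acceleration_difference(pair, traces, events)
                    if pair.usable_for_acceleration else None)
            meas = vigour(diff, events, pair, traces) if diff is not None else None
            tap_times = tuple(
                ev.tap - ev.appearance if ev.tap is not None else np.inf
                for ev in (evl, evr))
            rem_times = tuple(
                ev.tap - ev.jump if (ev.tap is not None and ev.jump is not None)
                else np.inf for ev in (evl, evr))
            hits = [bool(events[tid].hit) for tid in pair.members]
            rows.append({
                "participant": p, "session": s, "block_index": b,
                "replication": (b - replications_offset) // 2 + 1,
                "condition": pair.condition,
                "target_diameter": pair.target_diameter,
                "pair_index": pair.pair_index,
                "vigour": meas.vigour if meas else np.nan,
                "peak_time": meas.peak_time if meas else np.nan,
                "remaining_time": (meas.remaining_time if meas
                                   else _pair_time_measure(rem_times)),
                "reaction_time": meas.reaction_time if meas else np.nan,
                "peak_main_accel": meas.peak_main_accel if meas else np.nan,
                "time_per_tap": _pair_time_measure(tap_times),
                "fraction_hit": float(np.mean(hits)),
                "usable_for_acceleration": pair.usable_for_acceleration,
                "usable_for_position": pair.usable_for_position,
            })
    return pd.DataFrame(rows)
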