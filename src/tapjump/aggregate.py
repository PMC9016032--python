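"""Within-participant medians and across-participant means.

The study's aggregation scheme: every measure is computed per pair of
trials, the median is taken over the 5 analysed replications of each
block type for each participant (cells keyed by condition x target size
x pair index), and group values are unweighted means with standard
errors across the ten participants.  Trials without a usable tap time
enter the medians as +inf sentinels; the scheme is only sound while the
sentinel never becomes the median, so a sentinel median aborts the run.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import EventTimes

CELL_KEYS = ["participant", "condition", "target_diameter", "pair_index"]
GROUP_KEYS = ["condition", "target_diameter", "pair_index"]

MEDIAN_MEASURES = ["vigour", "remaining_time", "time_per_tap",
                   "reaction_time", "peak_main_accel"]


class SentinelMedianError(RuntimeError):
    """A median landed on the +inf sentinel: too many unusable trials."""


def checked_median(values) -> float:
    """Median that tolerates +inf members but never returns one."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan")
    med = float(np.median(values))
    if math.isinf(med):
        raise SentinelMedianError(
            "median of a cell is the +inf sentinel; the sentinel scheme "
            "requires a majority of usable trials per cell")
    return med


def time_per_tap(events: EventTimes, extreme: bool = False) -> float:
    """Appearance-to-tap time; +inf sentinel when no usable tap exists."""
    if extreme or events.tap is None:
        return float("inf")
    return float(events.tap - events.appearance)


def hit_fraction(meta_df: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Fraction of targets hit at the requested granularity.

    Every analysed trial counts (no-move trials are misses); empty
    cells are absent from the output rather than reported as zero.
    """
    df = meta_df[meta_df.analysed].copy()
    if "hit" not in df or df.hit.isna().any():
        raise ValueError("hit flags must be present for all analysed trials")
    by = by or GROUP_KEYS
    out = (df.groupby(by, sort=True)["hit"]
           .agg(fraction_hit="mean", n_trials="size").reset_index())
    return out


def cell_summaries(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-participant medians across replications for each cell.

    The vigour median uses only replications where the pair was usable
    for acceleration (``n_replications_used`` records how many); time
    medians run over all replications, sentinels included.
    """
    rows = []
    for key, cell in measures.groupby(CELL_KEYS, sort=True):
        usable = cell[cell.usable_for_acceleration & np.isfinite(cell.vigour)]
        rec = dict(zip(CELL_KEYS, key))
        rec["median_vigour"] = checked_median(usable.vigour) if len(usable) else float("nan")
        rec["median_remaining_time"] = checked_median(cell.remaining_time)
        rec["median_time_per_tap"] = checked_median(cell.time_per_tap)
        rec["median_reaction_time"] = (checked_median(usable.reaction_time)
                                       if len(usable) else float("nan"))
        rec["median_peak_main_accel"] = (checked_median(usable.peak_main_accel)
                                         if len(usable) else float("nan"))
        rec["fraction_hit"] = float(cell.fraction_hit.mean())
        rec["n_replications_used"] = int(len(usable))
        rows.append(rec)
    return pd.DataFrame(rows)


def group_summaries(cells: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean and standard error across participants per cell.

    SE is the sample standard deviation (ddof=1) over participants
    divided by sqrt(n); it is NaN when only one participant contributes.
    """
    value_cols = [c for c in cells.columns
                  if c.startswith("median_") or c == "fraction_hit"]
    rows = []
    for key, cell in cells.groupby(GROUP_KEYS, sort=True):
        rec = dict(zip(GROUP_KEYS, key))
        for col in value_cols:
            vals = cell[col].dropna().to_numpy(dtype=float)
            name = col.removeprefix("median_")
            rec[f"mean_{name}"] = float(vals.mean()) if vals.size else float("nan")
            rec[f"se_{name}"] = (float(vals.std(ddof=1) / math.sqrt(vals.size))
                                 if vals.size > 1 else float("nan"))
        rec["n_participants"] = int(cell.participant.nunique())
        rows.append(rec)
    out = pd.DataFrame(rows)
    bad = ~np.isfinite(out.select_dtypes("number").fillna(0.0))
    if bad.to_numpy().any():
        raise SentinelMedianError("sentinel leaked into a group summary")
    return out


def summarize(measures: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells (per-participant medians) and group means/SEs in one call."""
    cells = cell_summaries(measures)
    return cells, group_summaries(cells)


def participant_overall_means(cells: pd.DataFrame) -> pd.DataFrame:
    """Each participant's overall mean vigour and remaining time (the
    across-participant scatter of the study's Fig 5D analogue)."""
    return (cells.groupby("participant", sort=True)
            .agg(vigour=("median_vigour", "mean"),
                 remaining_time=("median_remaining_time", "mean"),
                 reaction_time=("median_reaction_time", "mean"),
                 peak_main_accel=("median_peak_main_accel", "mean"))
            .reset_index())
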