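"""CSV / JSON interchange for every pipeline stage.

All tables are plain CSV with a header row (pandas handles quoting);
positions are metres and times seconds unless a unit is declared on
read.  Writing, re-reading and writing again is byte-identical, which
makes runs diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import SampleSeries, TrialMeta, TrialTruth


class ParseError(ValueError):
    """An input table violates the documented layout (names the culprit)."""


SAMPLE_COLUMNS = ["trial_id", "t", "x", "y", "z", "valid"]
META_COLUMNS = ["trial_id", "participant", "session", "block_index",
                "trial_index", "condition", "target_diameter",
                "jump_direction", "pair_index", "analysed", "hit"]

_UNIT_SCALE = {"m": 1.0, "cm": 0.01, "mm": 0.001}


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{what} is missing columns: {', '.join(missing)}")


def write_samples(series: dict[str, SampleSeries], path: str | Path) -> Path:
    path = Path(path)
    frames = [pd.DataFrame({
        "trial_id": s.trial_id, "t": s.t, "x": s.x, "y": s.y, "z": s.z,
        "valid": s.valid.astype(int)}) for s in series.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_samples(path: str | Path, units: str = "m") -> dict[str, SampleSeries]:
    """Read a sample table; positions may be declared in m, cm or mm.

    Raises :class:`ParseError` for missing columns, duplicate sample
    times, or a non-uniform time grid (naming the offending trial).
    """
    if units not in _UNIT_SCALE:
        raise ParseError(f"unknown position unit {units!r}")
    scale = _UNIT_SCALE[units]
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SAMPLE_COLUMNS, f"sample table {path}")
    out: dict[str, SampleSeries] = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        t = g["t"].to_numpy(dtype=float)
        if len(t) >= 2:
            steps = np.diff(t)
            if steps.min() <= 0 or np.ptp(steps) > 1e-9:
                raise ParseError(
                    f"trial {trial_id}: sample times are not a uniform grid")
        out[str(trial_id)] = SampleSeries(
            trial_id=str(trial_id), t=t,
            x=g["x"].to_numpy(dtype=float) * scale,
            y=g["y"].to_numpy(dtype=float) * scale,
            z=g["z"].to_numpy(dtype=float) * scale,
            valid=g["valid"].to_numpy(dtype=float) > 0)
    return out


def write_meta(metas: list[TrialMeta], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([vars(m) for m in metas])[META_COLUMNS]
    df.to_csv(path, index=False)
    return path


def read_meta(path: str | Path) -> list[TrialMeta]:
    df = pd.read_csv(path)
    _require_columns(df, META_COLUMNS, f"metadata table {path}")
    if df.trial_id.duplicated().any():
        dup = df.trial_id[df.trial_id.duplicated()].iloc[0]
        raise ParseError(f"duplicate trial id {dup!r} in {path}")
    metas = []
    for rec in df.to_dict("records"):
        rec["trial_id"] = str(rec["trial_id"])
        for k in ("participant", "session", "block_index", "trial_index",
                  "pair_index"):
            rec[k] = int(rec[k])
        rec["target_diameter"] = float(rec["target_diameter"])
        rec["analysed"] = bool(rec["analysed"])
        rec["hit"] = None if pd.isna(rec["hit"]) else bool(rec["hit"])
        metas.append(TrialMeta(**rec))
    return metas


def write_truth(truths: dict[str, TrialTruth], path: str | Path) -> Path:
    path = Path(path)
    payload = {tid: t.to_dict() for tid, t in truths.items()}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_truth(path: str | Path) -> dict[str, TrialTruth]:
    payload = json.loads(Path(path).read_text())
    return {tid: TrialTruth.from_dict(d) for tid, d in payload.items()}


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any tidy stage output (events, ledger, measures, summaries).

    +inf sentinels must never reach serialized reports."""
    num = df.select_dtypes("number")
    if np.isinf(num.to_numpy(dtype=float, na_value=0.0)).any():
        raise ValueError(f"refusing to serialize +/-inf sentinel into {path}")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_measures(df: pd.DataFrame, path: str | Path) -> Path:
    """Pair-measures table: sentinels are blanked (NaN) on disk, with a
    companion boolean column recording where they were."""
    out = df.copy()
    num_cols = out.select_dtypes("number").columns
    inf_mask = np.isinf(out[num_cols].to_numpy(dtype=float, na_value=0.0)).any(axis=1)
    out["had_extreme_time"] = inf_mask
    out[num_cols] = out[num_cols].replace([np.inf, -np.inf], np.nan)
    out.to_csv(Path(path), index=False)
    return Path(path)


def write_fits(fits: dict[str, dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fits, indent=1, sort_keys=True))
    return path
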