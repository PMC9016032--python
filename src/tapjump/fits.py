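"""SD-standardized orthogonal (total least squares) regression.

Both vigour and remaining time are measured with error, so an ordinary
regression of one on the other is biased; the relation is summarised
instead by the line minimizing summed squared *perpendicular* distances.
Because the variables carry different units, each is standardized by
its mean and sample standard deviation first, which makes the distance
metric unit-free.  A well-known consequence: on standardized data the
orthogonal slope is exactly sign(r) with |slope| = 1 whenever the
correlation r is nonzero, so the raw-unit slope is sign(r) * sd_y/sd_x
and the line passes through the point of means.  The implementation
uses the principal axis of the standardized covariance (SVD) so the
closed form is a checkable consequence, not an assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Any

import numpy as np
import pandas as pd


class DegenerateDataError(ValueError):
    """Zero variance in a variable: no orthogonal line is identifiable."""


class InsufficientDataError(ValueError):
    """Fewer points than the fit requires."""


@dataclass
class FitResult:
    slope_std: float       # slope in standardized coordinates (+-1)
    intercept_std: float   # 0 by construction (line through the means)
    slope_raw: float       # (m/s^2) / s for the vigour fit
    intercept_raw: float
    sd_x: float
    sd_y: float
    mean_x: float
    mean_y: float
    n_points: int
    residual_rms_std: float  # rms perpendicular distance, standardized units
    correlation: float
    scope: str = "pooled"
    label: str = ""

    def predict(self, x) -> np.ndarray:
        return self.slope_raw * np.asarray(x, dtype=float) + self.intercept_raw

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def orthogonal_fit(x, y, scope: str = "pooled", label: str = "") -> FitResult:
    """Orthogonal regression of SD-standardized ``y`` against ``x``.

    Standardizes both variables (ddof=1), takes the principal axis of
    the standardized scatter as the line direction, and back-transforms
    to raw units.  Residual rms is reported in standardized units so
    fits over different subsets are comparable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"orthogonal fit needs >= 3 points, got {n}")
    mx, my = float(x.mean()), float(y.mean())
    sx, sy = float(x.std(ddof=1)), float(y.std(ddof=1))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDataError("zero variance in x or y")
    zx, zy = (x - mx) / sx, (y - my) / sy
    r = float(np.dot(zx, zy) / (n - 1))
    # principal axis of the centred standardized cloud
    _, _, vt = np.linalg.svd(np.column_stack([zx, zy]), full_matrices=False)
    vx, vy = vt[0]
    if abs(vx) < 1e-12:
        raise DegenerateDataError("orthogonal line is vertical in standardized "
                                  "coordinates (should not occur)")
    slope_std = float(vy / vx)
    perp = (zy - slope_std * zx) / math.hypot(1.0, slope_std)
    residual = float(np.sqrt(np.mean(perp ** 2)))
    slope_raw = slope_std * sy / sx
    return FitResult(
        slope_std=slope_std, intercept_std=0.0,
        slope_raw=slope_raw, intercept_raw=my - slope_raw * mx,
        sd_x=sx, sd_y=sy, mean_x=mx, mean_y=my, n_points=n,
        residual_rms_std=residual, correlation=r, scope=scope, label=label)


def fit_by_scope(points: pd.DataFrame, scope: str,
                 x: str = "remaining_time", y: str = "vigour",
                 ) -> dict[str, FitResult]:
    """Orthogonal fits at the requested granularity.

    ``points`` carries one row per symbol: group-level cells for the
    pooled and by-size fits (columns ``x``, ``y`` and
    ``target_diameter``), participant overall means for the
    by-participant fit.  Returns a mapping from scope label to fit.
    """
    if scope == "pooled":
        return {"pooled": orthogonal_fit(points[x], points[y], scope, "all cells")}
    if scope == "by_size":
        out = {}
        for diameter, sub in points.groupby("target_diameter", sort=True):
            label = f"diameter={diameter:g}"
            out[label] = orthogonal_fit(sub[x], sub[y], scope, label)
        return out
    if scope == "by_participant":
        return {"by_participant": orthogonal_fit(
            points[x], points[y], scope, "participant overall means")}
    raise ValueError(f"unknown scope {scope!r}")


def fit_points_from_groups(groups: pd.DataFrame) -> pd.DataFrame:
    """Fig 5C-style symbols: one point per condition x size x pair-index
    cell, taking the across-participant mean of each measure."""
    cols = {"mean_vigour": "vigour", "mean_remaining_time": "remaining_time",
            "mean_reaction_time": "reaction_time",
            "mean_peak_main_accel": "peak_main_accel"}
    keep = ["condition", "target_diameter", "pair_index"] + list(cols)
    return groups[keep].rename(columns=cols)


ALTERNATIVE_PREDICTORS = ("remaining_time", "reaction_time", "peak_main_accel")


def correlate_alternatives(points: pd.DataFrame,
                           y: str = "vigour") -> dict[str, FitResult]:
    """Fit vigour against remaining time and against the two alternative
    correlates (reaction time, peak main-direction acceleration) on the
    same points, for a residual-rms comparison in standardized units."""
    return {pred: orthogonal_fit(points[pred], points[y], "pooled", pred)
            for pred in ALTERNATIVE_PREDICTORS}
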