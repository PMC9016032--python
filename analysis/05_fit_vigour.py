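#!/usr/bin/env python
"""Fit vigour against remaining time with SD-standardized orthogonal
regression, pooled and per target size, plus the across-participant fit
and the alternative correlates (reaction time, main-direction peak
acceleration)."""

import pandas as pd

from common import parser

import tapjump as tj
from tapjump.fits import fit_points_from_groups
from tapjump.io import write_fits


def main() -> None:
    args = parser(__doc__).parse_args()
    cells = pd.read_csv(args.results_dir / "cell_summaries.csv")
    groups = pd.read_csv(args.results_dir / "group_summaries.csv")
    points = fit_points_from_groups(groups)

    fits = {}
    for scope in ("pooled", "by_size"):
        for label, f in tj.fit_by_scope(points, scope).items():
            fits[label] = f
    fits["by_participant"] = tj.fit_by_scope(
        tj.participant_overall_means(cells), "by_participant")["by_participant"]
    alternatives = tj.correlate_alternatives(points)

    write_fits({**{k: f.to_dict() for k, f in fits.items()},
                "alternatives": {k: f.to_dict()
                                 for k, f in alternatives.items()}},
               args.results_dir / "fits.json")

    print("orthogonal fits of vigour vs remaining time "
          "(slope in (m/s^2)/s; residual in SD units):")
    for label, f in fits.items():
        print(f"  {label:>16}: slope {f.slope_raw:8.2f}  "
              f"residual {f.residual_rms_std:.3f}  r={f.correlation:+.3f}")
    print("alternative correlates of vigour (residual in SD units):")
    for label, f in alternatives.items():
        print(f"  {label:>16}: residual {f.residual_rms_std:.3f}  "
              f"r={f.correlation:+.3f}")
    print(f"wrote fits.json -> {args.results_dir}")


if __name__ == "__main__":
    main()
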