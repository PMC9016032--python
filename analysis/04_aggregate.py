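#!/usr/bin/env python
"""Aggregate pair measures into cell and group summaries.

Medians across the five replications of each block type within each
participant, then unweighted means and standard errors across the ten
participants, for every condition x target-size x pair-index cell;
plus the general performance measures (fraction hit, time per tap).
"""

import numpy as np
import pandas as pd

from common import parser

import tapjump as tj
from tapjump.io import write_table
from tapjump.pipeline import load_inputs


def main() -> None:
    args = parser(__doc__).parse_args()
    args.results_dir.mkdir(parents=True, exist_ok=True)
    measures = pd.read_csv(args.data_dir / "pair_measures.csv")
    # re-inflate the serialized extreme-time sentinels for the medians
    if "had_extreme_time" in measures:
        ext = measures.had_extreme_time.fillna(False).astype(bool)
        for col in ("remaining_time", "time_per_tap"):
            measures.loc[ext & measures[col].isna(), col] = np.inf
    cells, groups = tj.summarize(measures)
    write_table(cells, args.results_dir / "cell_summaries.csv")
    write_table(groups, args.results_dir / "group_summaries.csv")

    _, metas = load_inputs(args.data_dir)
    meta_df = pd.DataFrame([vars(m) for m in metas])
    write_table(tj.hit_fraction(meta_df), args.results_dir / "hit_fractions.csv")

    perf = groups.groupby(["condition", "target_diameter"])[
        ["mean_fraction_hit", "mean_time_per_tap", "mean_vigour"]].mean()
    print("group performance (averaged over pair index):")
    print(perf.round(3).to_string())
    print(f"wrote cell/group summaries -> {args.results_dir}")


if __name__ == "__main__":
    main()
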