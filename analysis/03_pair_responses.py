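#!/usr/bin/env python
"""Pair left/right jump trials and compute the response measures.

Each block's i-th leftward jump is paired with its i-th rightward
jump; the right-minus-left lateral acceleration difference (aligned to
each trial's own jump) yields the vigour statistic, along with the
remaining time, reaction time and main-direction peak acceleration.
"""

from common import parser

import tapjump as tj
from tapjump.io import write_measures, write_table
from tapjump.pairs import mean_difference_traces
from tapjump.pipeline import load_inputs, stage_events, stage_pairs


def main() -> None:
    args = parser(__doc__).parse_args()
    args.results_dir.mkdir(parents=True, exist_ok=True)
    series, metas = load_inputs(args.data_dir)
    cfg = tj.PipelineConfig(seed=args.seed)
    events, traces, ledger = stage_events(series, metas, cfg)
    measures = stage_pairs(metas, series, events, traces, ledger, cfg)
    write_measures(measures, args.data_dir / "pair_measures.csv")
    trace_df = mean_difference_traces(metas, series, events, traces, ledger)
    write_table(trace_df, args.data_dir / "mean_difference_traces.csv")

    usable = measures.usable_for_acceleration
    print(f"{len(measures)} pairs; {int(usable.sum())} usable for vigour")
    by_cond = measures[usable].groupby("condition").vigour.mean()
    print("mean vigour by condition (m/s^2):")
    for cond, v in by_cond.items():
        print(f"  {cond}: {v:.2f}")
    print(f"wrote pair_measures.csv -> {args.data_dir}")


if __name__ == "__main__":
    main()
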