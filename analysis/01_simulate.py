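#!/usr/bin/env python
"""Simulate the full synthetic experiment.

Ten participants, two sessions (one target size each, counterbalanced),
12 blocks of 20 trials alternating stay / jump-back, first two blocks
warm-up.  Writes the raw sample table, trial metadata and the
generative truth record under scratch/ (they are large), and prints the
design accounting that any downstream analysis relies on.
"""

import json

from common import parser

import tapjump as tj
from tapjump.io import write_meta, write_samples, write_truth


def main() -> None:
    args = parser(__doc__).parse_args()
    args.data_dir.mkdir(parents=True, exist_ok=True)
    plan = tj.ExperimentPlan()
    config = tj.SimulationConfig(seed=args.seed)
    series, metas, truths = tj.simulate_experiment(plan, config)
    write_samples(series, args.data_dir / "samples.csv")
    write_meta(metas, args.data_dir / "meta.csv")
    write_truth(truths, args.data_dir / "truth.json")
    (args.data_dir / "config.json").write_text(json.dumps(
        {"seed": args.seed, "simulation": config.to_dict()}, indent=1))

    analysed = sum(m.analysed for m in metas)
    no_move = sum(t.no_move for t in truths.values())
    gentle = sum(t.gentle for t in truths.values())
    print(f"simulated {len(metas)} trials; {analysed} analysed "
          f"({analysed // plan.n_participants} per participant)")
    print(f"generative nuisances: {no_move} no-move trials, {gentle} gentle taps")
    print(f"wrote samples/meta/truth -> {args.data_dir}")


if __name__ == "__main__":
    main()
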