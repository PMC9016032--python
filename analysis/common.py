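"""Shared paths and defaults for the numbered analysis drivers."""

from __future__ import annotations

import argparse
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
DATA_DIR = REPO / "scratch" / "pipeline"       # heavy intermediates
RESULTS_DIR = REPO / "results" / "analysis"    # small result tables

DEFAULT_SEED = 7


def parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=DEFAULT_SEED)
    p.add_argument("--data-dir", type=Path, default=DATA_DIR)
    p.add_argument("--results-dir", type=Path, default=RESULTS_DIR)
    return p
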