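"""Closed-loop checks that tie the generator to the analysis chain.

These run tiny, noise-free simulated scenarios through the same package
operations as a full run and extract a single physically interpretable
number each, for end-to-end verification:

* the onset latency of the corrective response to the jump *back*,
  measured relative to the first jump (jump-back delay + one visuomotor
  latency; 250 ms at the defaults);
* the asymptote of the lateral-position half-difference for fully
  compensating stay pairs (the jump magnitude; 2.6 cm).
"""

from __future__ import annotations

import numpy as np

from .config import (JUMP_BACK, LEFT, RIGHT, STAY, SimulationConfig,
                     noise_free)
from .kinematics import compute_events
from .pairs import TrialPair, position_half_difference
from .simulate import simulate_trial
from .types import TrialMeta


def _clean_config(config: SimulationConfig | None, seed: int) -> SimulationConfig:
    """Noise-free, condition-symmetric configuration: equal first-response
    gains and no movement prolongation, so a jump-back trial differs from
    its matched stay trial only by the second (return) correction."""
    base = config if config is not None else SimulationConfig()
    return noise_free(
        base, seed=seed,
        first_response_gain={STAY: 1.0, JUMP_BACK: 1.0},
    )


def second_response_onset_ms(config: SimulationConfig | None = None,
                             seed: int = 0) -> tuple[float, int]:
    """Latency of the return response relative to the first jump (ms).

    Simulates one noise-free jump-back trial and its matched stay trial
    (identical draws), and locates the first sample at which the lateral
    trajectories — hence their accelerations — diverge in the return
    direction.  With the stated 150 ms jump-back delay and a 100 ms
    visuomotor latency this composes to 250 ms.  Returns (ms, n samples
    compared).
    """
    cfg = _clean_config(config, seed)
    make = lambda tid, cond, block: TrialMeta(  # noqa: E731
        tid, 1, 1, block, 0, cond, 0.03, RIGHT, 1, True)
    s_jb, truth = simulate_trial(make("JB", JUMP_BACK, 3), cfg)
    s_st, _ = simulate_trial(make("ST", STAY, 3), cfg)
    n = min(s_jb.n, s_st.n)
    dev = s_jb.x[:n] - s_st.x[:n]
    # the return correction pulls back toward the original path (negative
    # for a rightward first jump)
    idx = np.flatnonzero(dev < -1e-12)
    if idx.size == 0:
        raise RuntimeError("jump-back and stay trials never diverged")
    onset_ms = (float(s_jb.t[idx[0]]) - truth.jump) * 1000.0
    return onset_ms, n


def stay_pair_compensation_cm(config: SimulationConfig | None = None,
                              seed: int = 0) -> tuple[float, int]:
    """Asymptote of the position half-difference for stay pairs (cm).

    Simulates a noise-free left/right stay pair with full first-response
    gain, runs event detection and the pipeline's position
    half-difference, and reads the trace at time-before-tap zero; full
    compensation puts it at the configured jump magnitude.  Returns
    (cm, n samples in the common grid).
    """
    cfg = _clean_config(config, seed)
    ml = TrialMeta("L", 1, 1, 2, 0, STAY, 0.03, LEFT, 1, True)
    mr = TrialMeta("R", 1, 1, 2, 1, STAY, 0.03, RIGHT, 1, True)
    series = {}
    for meta in (ml, mr):
        s, _ = simulate_trial(meta, cfg)
        series[meta.trial_id] = s
    events = {tid: compute_events(s, STAY) for tid, s in series.items()}
    pair = TrialPair(1, 1, 2, STAY, 0.03, 1, "L", "R")
    diff = position_half_difference(pair, series, events)
    if diff is None or not diff.pos_valid[0]:
        raise RuntimeError("stay pair produced no valid half-difference trace")
    return float(diff.half_delta_pos[0]) * 100.0, int(len(diff.t_before_tap))
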