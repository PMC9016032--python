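"""Shared fixtures: small simulated cohorts and noise-free trial pairs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import tapjump as tj

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_config() -> tj.SimulationConfig:
    return tj.noise_free(seed=1)


def make_meta(trial_id="T0", participant=1, session=1, block=2, index=0,
              condition=tj.STAY, diameter=tj.LARGE_DIAMETER,
              direction=tj.RIGHT, pair_index=1) -> tj.TrialMeta:
    return tj.TrialMeta(trial_id, participant, session, block, index,
                        condition, diameter, direction, pair_index, True)


@pytest.fixture(scope="session")
def noise_free_pair(noise_free_config):
    """A left/right stay pair simulated without any noise sources."""
    ml = make_meta("L", index=0, direction=tj.LEFT)
    mr = make_meta("R", index=1, direction=tj.RIGHT)
    sl, tl = tj.simulate_trial(ml, noise_free_config)
    sr, tr = tj.simulate_trial(mr, noise_free_config)
    return {"metas": (ml, mr), "series": {"L": sl, "R": sr},
            "truths": {"L": tl, "R": tr}}


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants through the full pipeline (shared, read-only)."""
    cfg = tj.PipelineConfig(seed=11, plan=tj.ExperimentPlan(n_participants=3))
    return tj.run_pipeline(cfg, "scratch/test_small", write_raw=False)
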