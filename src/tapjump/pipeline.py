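"""End-to-end orchestration: simulate -> events -> pairs -> summaries -> fits."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .aggregate import hit_fraction, participant_overall_means, summarize
from .config import ExperimentPlan, KinematicsConfig, SimulationConfig
from .fits import correlate_alternatives, fit_by_scope, fit_points_from_groups
from .io import (read_meta, read_samples, write_fits, write_measures,
                 write_meta, write_samples, write_table, write_truth)
from .kinematics import (acceleration_trace, build_exclusion_ledger,
                         compute_events, events_table)
from .pairs import compute_pair_measures
from .simulate import simulate_experiment
from .types import EventTimes, SampleSeries, TrialMeta

log = logging.getLogger("tapjump")


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs, JSON-serializable."""

    seed: int = 0
    plan: ExperimentPlan = field(default_factory=ExperimentPlan)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    fit_scopes: tuple[str, ...] = ("pooled", "by_size", "by_participant")
    input_units: str = "m"

    def __post_init__(self) -> None:
        self.simulation.seed = int(self.seed)

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "plan": vars(self.plan) | {"target_diameters": list(self.plan.target_diameters)},
            "simulation": self.simulation.to_dict(),
            "kinematics": self.kinematics.to_dict(),
            "fit_scopes": list(self.fit_scopes),
            "input_units": self.input_units,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        plan = d.get("plan", {})
        if "target_diameters" in plan:
            plan = plan | {"target_diameters": tuple(plan["target_diameters"])}
        return cls(
            seed=int(d.get("seed", 0)),
            plan=ExperimentPlan(**plan),
            simulation=SimulationConfig(**d.get("simulation", {})),
            kinematics=KinematicsConfig(**d.get("kinematics", {})),
            fit_scopes=tuple(d.get("fit_scopes", ("pooled", "by_size", "by_participant"))),
            input_units=d.get("input_units", "m"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


@_stage("simulate")
def stage_simulate(config: PipelineConfig):
    return simulate_experiment(config.plan, config.simulation)


@_stage("kinematics")
def stage_events(series: dict[str, SampleSeries], metas: list[TrialMeta],
                 config: PipelineConfig):
    events: dict[str, EventTimes] = {}
    traces = {}
    for meta in metas:
        s = series[meta.trial_id]
        events[meta.trial_id] = compute_events(
            s, meta.condition, config.kinematics,
            jump_back_delay=config.simulation.jump_back_delay, hit=meta.hit)
        traces[meta.trial_id] = acceleration_trace(
            s, config.kinematics.sg_half_window)
    ledger = build_exclusion_ledger(events, metas)
    return events, traces, ledger


@_stage("pair")
def stage_pairs(metas, series, events, traces, ledger, config: PipelineConfig):
    return compute_pair_measures(
        metas, series, events, traces, ledger,
        replications_offset=config.plan.warmup_blocks_per_session)


@_stage("aggregate")
def stage_aggregate(measures: pd.DataFrame):
    return summarize(measures)


@_stage("fit")
def stage_fits(cells: pd.DataFrame, groups: pd.DataFrame,
               config: PipelineConfig) -> dict[str, dict]:
    from .fits import DegenerateDataError, InsufficientDataError
    points = fit_points_from_groups(groups)
    out: dict[str, dict] = {}
    for scope in config.fit_scopes:
        source = participant_overall_means(cells) if scope == "by_participant" else points
        try:
            for label, fit in fit_by_scope(source, scope).items():
                out[label] = fit.to_dict()
        except (InsufficientDataError, DegenerateDataError) as exc:
            # e.g. too few participants for the by-participant fit; record
            # the reason instead of aborting the whole run
            log.warning("fit scope %s skipped: %s", scope, exc)
            out[scope] = {"error": str(exc)}
    out["alternatives"] = {pred: fit.to_dict() for pred, fit
                           in correlate_alternatives(points).items()}
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 write_raw: bool = True) -> dict[str, Any]:
    """Execute the full pipeline and write every stage output.

    Returns the in-memory artifacts; on disk the run leaves the sample
    and metadata tables (optional), events and ledger CSVs, pair
    measures, cell and group summaries, fit JSON and a run-metadata
    record echoing the configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.plan.validate()
    config.simulation.validate()
    config.kinematics.validate()

    series, metas, truths = stage_simulate(config)
    log.info("simulated %d trials (%d analysed)", len(metas),
             sum(m.analysed for m in metas))
    if write_raw:
        write_samples(series, out_dir / "samples.csv")
        write_meta(metas, out_dir / "meta.csv")
        write_truth(truths, out_dir / "truth.json")

    events, traces, ledger = stage_events(series, metas, config)
    write_table(events_table(events, metas), out_dir / "events.csv")
    write_table(ledger.reset_index(), out_dir / "ledger.csv")

    measures = stage_pairs(metas, series, events, traces, ledger, config)
    write_measures(measures, out_dir / "pair_measures.csv")

    cells, groups = stage_aggregate(measures)
    write_table(cells, out_dir / "cell_summaries.csv")
    write_table(groups, out_dir / "group_summaries.csv")
    meta_df = pd.DataFrame([vars(m) for m in metas])
    hits = hit_fraction(meta_df)
    write_table(hits, out_dir / "hit_fractions.csv")

    fits = stage_fits(cells, groups, config)
    write_fits(fits, out_dir / "fits.json")

    analysed = int(meta_df.analysed.sum())
    exclusions = {c: int(ledger.loc[[m.trial_id for m in metas if m.analysed], c].sum())
                  for c in ledger.columns}
    run_meta = {
        "version": __version__,
        "config": config.to_dict(),
        "n_trials": len(metas),
        "n_analysed": analysed,
        "exclusions_analysed": exclusions,
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(run_meta, indent=1))
    log.info("exclusion counts (analysed trials): %s", exclusions)
    return {
        "series": series, "metas": metas, "truths": truths,
        "events": events, "traces": traces, "ledger": ledger,
        "measures": measures, "cells": cells, "groups": groups,
        "hit_fractions": hits, "fits": fits, "run_metadata": run_meta,
    }


def load_inputs(data_dir: str | Path, units: str = "m"):
    """Read previously written sample and metadata tables."""
    data_dir = Path(data_dir)
    series = read_samples(data_dir / "samples.csv", units=units)
    metas = read_meta(data_dir / "meta.csv")
    return series, metas
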