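"""Canned study designs: the standard sweep and the return-to-work sweep.

These functions run the simulation batches the model is analysed with --
minimum-standard dose-response, worker-isolation dose-response and the
headline-scenario stratified summaries -- reducing each trace to summary
statistics on the fly so full traces never accumulate in memory.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .scenarios import EngineParams, PopulationConfig, default_narrative, run_scenario

__all__ = [
    "sweep_minimum_standards",
    "sweep_worker_isolation",
    "headline_summary",
    "pooled_stratified_means",
]

DEFAULT_STANDARD_LEVELS = (0.0, 20.0, 40.0, 60.0, 80.0)
DEFAULT_ISOLATION_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def sweep_minimum_standards(
    levels: Sequence[float] = DEFAULT_STANDARD_LEVELS,
    iterations: int = 20,
    base_seed: int = 0,
    population: PopulationConfig = PopulationConfig(),
    engine: EngineParams = EngineParams(),
    horizon: int = 500,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Final median adult diet quality for each (standard, iteration) run.

    Runs the three-phase narrative with a universal minimum standard at each
    level (schools from step 0, workplaces from step 200), no isolation.
    Returns a tidy frame with columns ``standard``, ``iteration``, ``value``
    ready for :func:`dietnorms.metrics.slope_vs_standard`.
    """
    rows = []
    for level in levels:
        cfg = default_narrative(
            float(level), 0.0, horizon=horizon, iterations=iterations,
            base_seed=base_seed, population=population, engine=engine,
        )
        for it in range(iterations):
            value = metrics.final_adult_median(run_scenario(cfg, it))
            rows.append({"standard": float(level), "iteration": it, "value": value})
            if progress:
                progress(f"standard {level} iteration {it}: median {value:.2f}")
    return pd.DataFrame(rows)


def headline_summary(trace, interaction_window=(0, 300)) -> dict:
    """Reduce one headline-scenario trace to the reported statistics."""
    return {
        "final_mean": metrics.final_adult_mean(trace),
        "final_median": metrics.final_adult_median(trace),
        "stratified": metrics.stratified_summary(trace),
        "interaction": metrics.interaction_effect(trace, interaction_window).slope,
        "declined": metrics.proportion_declined(trace),
    }


def sweep_worker_isolation(
    fractions: Sequence[float] = DEFAULT_ISOLATION_FRACTIONS,
    min_standard: float = 60.0,
    iterations: int = 20,
    base_seed: int = 0,
    population: PopulationConfig = PopulationConfig(),
    engine: EngineParams = EngineParams(),
    horizon: int = 500,
    progress: Callable[[str], None] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Final mean adult diet quality per (isolation fraction, iteration) run.

    At every fraction the universal ``min_standard`` narrative is run; the
    zero-isolation runs are the headline scenario, and for those the full
    :func:`headline_summary` reductions are also collected.  Returns the
    tidy sweep frame (columns ``fraction``, ``iteration``, ``value``) and
    the list of headline summaries.
    """
    rows = []
    headline: list[dict] = []
    for f in fractions:
        cfg = default_narrative(
            min_standard, float(f), horizon=horizon, iterations=iterations,
            base_seed=base_seed, population=population, engine=engine,
        )
        for it in range(iterations):
            trace = run_scenario(cfg, it)
            value = metrics.final_adult_mean(trace)
            rows.append({"fraction": float(f), "iteration": it, "value": value})
            if f == 0.0:
                headline.append(headline_summary(trace))
            if progress:
                progress(f"isolation {f} iteration {it}: mean {value:.2f}")
    return pd.DataFrame(rows), headline


def pooled_stratified_means(summaries: Sequence[dict]) -> pd.Series:
    """Pool per-iteration stratified means, weighting by stratum size."""
    tables = [s["stratified"] for s in summaries]
    combined = pd.concat(tables)
    weighted = combined["mean"] * combined["n"]
    return weighted.groupby(level=0).sum() / combined["n"].groupby(level=0).sum()
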