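"""Scenario definitions and the seeded batch runner.

A scenario is a sequence of *phases* over a step horizon (pre-pandemic
status quo, enforced working-from-home, and a partial return to work with a
daily-resampled fraction of workers isolating at home), combined with a
*standards policy*: per-setting minimum dietary standards with activation
steps (schools from step 0, workplaces from step 200 by default).
``run_scenario`` executes one seeded iteration end-to-end; ``run_batch``
runs a grid of configurations with reproducible per-iteration seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from . import dynamics
from .diet import (
    DEFAULT_MENU_SIZE,
    DEFAULT_POOL_MEAN,
    DEFAULT_POOL_SD,
    DEFAULT_POOL_SIZE,
    InfeasibleStandardError,
    generate_meal_pool,
)
from .dynamics import AgentStates, Clock, StepContext, step_meal
from .population import (
    ConfigurationError,
    DEFAULT_MIX,
    DEFAULT_SIGMA_DIST,
    DEFAULT_SIZE_MODEL,
    DEFAULT_VENUE_SPECS,
    DEFAULT_W_DIST,
    HouseholdSizeModel,
    HouseholdTypeMix,
    VenueSpec,
    synthesise_population,
)
from .trace import Trace

__all__ = [
    "Phase",
    "StandardsPolicy",
    "PopulationConfig",
    "EngineParams",
    "ScenarioConfig",
    "default_narrative",
    "isolation_draw",
    "run_scenario",
    "run_batch",
    "iteration_seed",
]

_SETTING_OF_KIND = {
    "workplace-big": "workplaces_big",
    "workplace-medium": "workplaces_medium",
    "workplace-small": "workplaces_small",
    "school-secondary": "schools",
    "school-primary": "schools",
}


@dataclass(frozen=True)
class Phase:
    """A contiguous block of steps with one adult-lunch regime.

    ``adult_lunch_mode`` is ``"normal"`` (workers attend workplace lunches)
    or ``"all-home"`` (all adults eat every meal in the household).
    ``isolation_fraction`` is the proportion of workers, re-sampled daily,
    who stay home at lunch while the mode is ``"normal"``.
    """

    start_step: int
    end_step: int  # exclusive
    adult_lunch_mode: str = "normal"
    isolation_fraction: float = 0.0

    def __post_init__(self):
        if not 0 <= self.start_step < self.end_step:
            raise ConfigurationError("phase must satisfy 0 <= start < end")
        if not 0.0 <= self.isolation_fraction <= 1.0:
            raise ConfigurationError("isolation_fraction must lie in [0, 1]")
        if self.adult_lunch_mode not in ("normal", "all-home"):
            raise ConfigurationError(f"unknown adult_lunch_mode {self.adult_lunch_mode!r}")


@dataclass(frozen=True)
class StandardsPolicy:
    """Per-setting minimum DQI standards and their activation steps."""

    schools: float = 0.0
    workplaces_big: float = 0.0
    workplaces_medium: float = 0.0
    workplaces_small: float = 0.0
    schools_start: int = 0
    workplaces_start: int = 200

    def __post_init__(self):
        for name in ("schools", "workplaces_big", "workplaces_medium", "workplaces_small"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigurationError(f"standard {name}={v!r} outside [0, 100]")

    @classmethod
    def universal(
        cls, standard: float, schools_start: int = 0, workplaces_start: int = 200
    ) -> "StandardsPolicy":
        return cls(
            schools=standard,
            workplaces_big=standard,
            workplaces_medium=standard,
            workplaces_small=standard,
            schools_start=schools_start,
            workplaces_start=workplaces_start,
        )

    def active_standard(self, venue_kind: str, step: int) -> float:
        """The minimum standard in force for a venue kind at a given step."""
        setting = _SETTING_OF_KIND[venue_kind]
        start = self.schools_start if setting == "schools" else self.workplaces_start
        return getattr(self, setting) if step >= start else 0.0


@dataclass(frozen=True)
class PopulationConfig:
    n_households: int = 1000
    mix: HouseholdTypeMix = DEFAULT_MIX
    size_model: HouseholdSizeModel = DEFAULT_SIZE_MODEL
    venue_specs: tuple[VenueSpec, ...] = DEFAULT_VENUE_SPECS
    sigma_dist: tuple[float, float] = DEFAULT_SIGMA_DIST
    w_dist: tuple[float, float, float] = DEFAULT_W_DIST


@dataclass(frozen=True)
class EngineParams:
    history_length: int = dynamics.DEFAULT_HISTORY_LENGTH
    group_size: int = dynamics.DEFAULT_GROUP_SIZE
    menu_size: int = DEFAULT_MENU_SIZE
    pool_size: int = DEFAULT_POOL_SIZE
    pool_mean: float = DEFAULT_POOL_MEAN
    pool_sd: float = DEFAULT_POOL_SD
    init_mean: float = DEFAULT_POOL_MEAN
    init_sd: float = DEFAULT_POOL_SD
    include_self: bool = True
    #: Home meals draw on the full unconstrained pool; set to an int to
    #: sub-sample a daily home menu of that size instead.
    home_menu_size: int | None = None


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully-specified, reproducible simulation experiment."""

    population: PopulationConfig = PopulationConfig()
    standards: StandardsPolicy = StandardsPolicy()
    phases: tuple[Phase, ...] = (Phase(0, 500),)
    engine: EngineParams = EngineParams()
    horizon: int = 500
    iterations: int = 20
    base_seed: int = 0
    name: str = "scenario"

    def __post_init__(self):
        phases = tuple(sorted(self.phases, key=lambda p: p.start_step))
        object.__setattr__(self, "phases", phases)
        cursor = 0
        for p in phases:
            if p.start_step != cursor:
                raise ConfigurationError(
                    f"phases must tile [0, horizon) without gaps or overlap; "
                    f"expected a phase starting at {cursor}, got {p.start_step}"
                )
            cursor = p.end_step
        if cursor != self.horizon:
            raise ConfigurationError(
                f"phases end at {cursor} but horizon is {self.horizon}"
            )

    def phase_at(self, step: int) -> Phase:
        for p in self.phases:
            if p.start_step <= step < p.end_step:
                return p
        raise IndexError(f"step {step} outside the scenario horizon")


def default_narrative(
    min_standard: float = 60.0,
    isolation_fraction: float = 0.0,
    horizon: int = 500,
    iterations: int = 20,
    base_seed: int = 0,
    strict_methods: bool = False,
    name: str | None = None,
    population: PopulationConfig = PopulationConfig(),
    engine: EngineParams = EngineParams(),
) -> ScenarioConfig:
    """The pandemic return-to-work narrative.

    Three phases: steps 0-100 status quo, 101-200 all adults eating at home
    (children still attend school lunches), 201 onward a return to work
    with the given daily isolation fraction.  School standards are active
    from step 0 and workplace standards from step 200; ``strict_methods``
    delays school standards to step 201 as well, making the first phase a
    genuinely standard-free baseline.
    """
    if not 0.0 <= min_standard <= 100.0:
        raise ConfigurationError("min_standard must lie in [0, 100]")
    if horizon < 201:
        raise ConfigurationError("the three-phase narrative needs horizon >= 201")
    schools_start = 201 if strict_methods else 0
    phases = (
        Phase(0, 101, "normal", 0.0),
        Phase(101, 201, "all-home", 0.0),
        Phase(201, horizon, "normal", isolation_fraction),
    )
    return ScenarioConfig(
        population=population,
        standards=StandardsPolicy.universal(
            min_standard, schools_start=schools_start, workplaces_start=200
        ),
        phases=phases,
        engine=engine,
        horizon=horizon,
        iterations=iterations,
        base_seed=base_seed,
        name=name or f"narrative-std{min_standard:g}-iso{isolation_fraction:g}",
    )


def isolation_draw(
    workers: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample today's isolating workers: round(fraction * n) without replacement."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must lie in [0, 1]")
    workers = np.asarray(workers)
    k = int(round(fraction * workers.size))
    if k == 0:
        return workers[:0]
    return rng.choice(workers, size=k, replace=False)


def iteration_seed(cfg: ScenarioConfig, iteration_index: int) -> np.random.SeedSequence:
    """Reproducible per-(config, iteration) seed from the base seed."""
    salt = zlib.crc32(cfg.name.encode())
    return np.random.SeedSequence([int(cfg.base_seed), int(salt), int(iteration_index)])


def run_scenario(cfg: ScenarioConfig, iteration_index: int = 0) -> Trace:
    """Execute one seeded iteration of a scenario, returning its Trace.

    Each iteration re-synthesises the population, meal pool and initial
    states from its own seed, then advances ``cfg.horizon`` meal steps with
    daily venue menus and isolation draws.
    """
    rng = np.random.default_rng(iteration_seed(cfg, iteration_index))
    eng = cfg.engine
    p = cfg.population

    pop = synthesise_population(
        p.n_households, p.mix, p.size_model, p.venue_specs, p.sigma_dist, p.w_dist, rng
    )
    arrays = pop.to_arrays()
    pool = generate_meal_pool(eng.pool_size, eng.pool_mean, eng.pool_sd, rng)
    pool_sorted = pool.sorted_scores

    # Eligible-slice start index per venue for each standard regime.
    n_venues = arrays.venue_kind.size
    def _slice_start(standard: float) -> int:
        start = int(np.searchsorted(pool_sorted, standard))
        if start >= pool_sorted.size:
            raise InfeasibleStandardError(
                f"no meals in the pool meet the minimum standard {standard!r}"
            )
        return start

    states, initial = dynamics.init_states(
        arrays, (eng.init_mean, eng.init_sd), eng.history_length, rng
    )

    horizon = cfg.horizon
    n = arrays.n_agents
    choices = np.empty((horizon, n), dtype=float)
    running = np.empty((horizon + 1, n), dtype=float)
    at_venue = np.zeros((horizon, n), dtype=bool)
    running[0] = states.running_mean

    workers_idx = np.flatnonzero(arrays.is_worker)
    menus: dict[int, np.ndarray] = {}
    isolated_mask: np.ndarray | None = None
    home_scores = pool_sorted

    for t in range(horizon):
        clock = Clock(t)
        phase = cfg.phase_at(t)
        if clock.meal == 0 or t == 0:
            lunch_step = clock.day * 3 + 1
            if clock.is_weekday:
                menus = {}
                for vid in range(n_venues):
                    std = cfg.standards.active_standard(str(arrays.venue_kind[vid]), lunch_step)
                    lo = _slice_start(std)
                    menu = pool_sorted[rng.integers(lo, pool_sorted.size, size=eng.menu_size)]
                    menu.sort()
                    menus[vid] = menu
                lunch_phase = cfg.phase_at(min(lunch_step, horizon - 1))
                if lunch_phase.adult_lunch_mode == "normal" and lunch_phase.isolation_fraction > 0:
                    isolated_mask = np.zeros(n, dtype=bool)
                    isolated_mask[isolation_draw(workers_idx, lunch_phase.isolation_fraction, rng)] = True
                else:
                    isolated_mask = None
            if eng.home_menu_size is not None:
                home_scores = np.sort(
                    pool_sorted[rng.integers(0, pool_sorted.size, size=eng.home_menu_size)]
                )
        ctx = StepContext(
            home_scores=home_scores,
            venue_menus=menus,
            adult_lunch_mode=phase.adult_lunch_mode,
            isolated=isolated_mask,
            group_size=eng.group_size,
            include_self=eng.include_self,
        )
        chosen, attend = step_meal(states, arrays, clock, ctx, rng)
        choices[t] = chosen
        at_venue[t] = attend
        running[t + 1] = states.running_mean

    roster = pop.roster()
    roster["init_dqi"] = initial
    meta = {
        "name": cfg.name,
        "iteration": iteration_index,
        "seed_entropy": list(iteration_seed(cfg, iteration_index).entropy),
        "horizon": horizon,
        "standards": {
            "schools": cfg.standards.schools,
            "workplaces_big": cfg.standards.workplaces_big,
            "workplaces_medium": cfg.standards.workplaces_medium,
            "workplaces_small": cfg.standards.workplaces_small,
            "schools_start": cfg.standards.schools_start,
            "workplaces_start": cfg.standards.workplaces_start,
        },
        "isolation_fraction": max(
            (p_.isolation_fraction for p_ in cfg.phases), default=0.0
        ),
    }
    return Trace(roster=roster, choices=choices, running_mean=running, at_venue=at_venue, meta=meta)


def run_batch(
    configs: Sequence[ScenarioConfig],
    reduce: Callable[[Trace], object] | None = None,
    out_dir=None,
    progress: Callable[[str], None] | None = None,
) -> dict[tuple[str, int], object]:
    """Run every iteration of every configuration.

    Returns a dict keyed by ``(config name, iteration)``.  With ``reduce``
    given, each Trace is immediately reduced (e.g. to summary statistics)
    so full traces never accumulate in memory; with ``out_dir`` given, each
    trace is also streamed to a gzipped CSV there.
    """
    configs = list(configs)
    if not configs:
        raise ConfigurationError("batch requires at least one configuration")
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate configuration names in batch: {names}")
    results: dict[tuple[str, int], object] = {}
    for cfg in configs:
        for it in range(cfg.iterations):
            trace = run_scenario(cfg, it)
            if out_dir is not None:
                from pathlib import Path

                d = Path(out_dir)
                d.mkdir(parents=True, exist_ok=True)
                trace.write_csv(d / f"{cfg.name}-it{it}.csv.gz")
            results[(cfg.name, it)] = reduce(trace) if reduce is not None else trace
            if progress is not None:
                progress(f"{cfg.name} iteration {it} done")
    return results
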