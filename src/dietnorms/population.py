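"""Synthetic society: households, workplaces and schools.

The simulated population mirrors the socio-demographic structure of a
medium-sized UK city at roughly 1% scale.  Households are typed by a
categorical mix over (working adult?, children?) combinations; workplaces
come in three size strata and schools in two levels, with agents allocated
to venues with probability proportional to venue capacity.  Each agent also
carries two fixed behavioural parameters:

``sigma_pref``
    standard deviation (in diet-quality-index units) of the agent's
    meal-to-meal internal preference around its personal norm, drawn once
    from a normal distribution;
``w_group``
    weight given to the descriptive group norm when eating in a venue
    group, drawn once from a triangular distribution on [0, 1].

Collections are held as :class:`pandas.DataFrame` tables inside a
:class:`Population`, which round-trips to JSON and exports a flat roster
CSV for inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "HouseholdTypeMix",
    "HouseholdSizeModel",
    "VenueSpec",
    "Population",
    "PopulationArrays",
    "DEFAULT_MIX",
    "DEFAULT_SIZE_MODEL",
    "DEFAULT_VENUE_SPECS",
    "DEFAULT_SIGMA_DIST",
    "DEFAULT_W_DIST",
    "SIGMA_FLOOR",
    "build_households",
    "build_venues",
    "assign_behaviour_params",
    "synthesise_population",
]


class ConfigurationError(ValueError):
    """Raised when configuration values are inconsistent or out of range."""


# Agent roles.
WORKER = "worker"
NONWORKING_ADULT = "nonworking-adult"
CHILD = "child"

# Integer role codes used by the vectorised engine.
ROLE_CODES = {WORKER: 0, NONWORKING_ADULT: 1, CHILD: 2}

WORKPLACE_KINDS = ("workplace-big", "workplace-medium", "workplace-small")
SCHOOL_KINDS = ("school-secondary", "school-primary")

#: Truncation floor for sigma_pref, in DQI units; keeps the preference
#: distribution proper even in the extreme lower tail of the normal draw.
SIGMA_FLOOR = 0.1


@dataclass(frozen=True)
class HouseholdTypeMix:
    """Categorical mix of household types (fractions of households)."""

    p_work_child: float = 0.305
    p_work_nochild: float = 0.544
    p_nowork_child: float = 0.026
    p_nowork_nochild: float = 0.124

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p_work_child, self.p_work_nochild, self.p_nowork_child, self.p_nowork_nochild]
        )

    def validate(self) -> None:
        p = self.as_array()
        if np.any(p < 0):
            raise ConfigurationError(f"household mix has negative probabilities: {tuple(p)}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"household mix must sum to 1, got {p.sum()!r}")

    @classmethod
    def from_percentages(cls, work_child: float, work_nochild: float,
                         nowork_child: float, nowork_nochild: float) -> "HouseholdTypeMix":
        """Build a mix from printed percentages, normalising rounding slack.

        Published census-style tables round each share to one decimal, so
        the four shares need not sum to exactly 100.
        """
        p = np.array([work_child, work_nochild, nowork_child, nowork_nochild], dtype=float)
        if np.any(p < 0) or p.sum() <= 0:
            raise ConfigurationError("percentages must be non-negative and not all zero")
        p = p / p.sum()
        return cls(*p)


@dataclass(frozen=True)
class HouseholdSizeModel:
    """How many adults and children a household of a given type contains.

    Adults per household are 1 or 2, with ``p_two_adults`` calibrated so the
    expected number of adults per household is 1.6 (about 1,600 adults per
    1,000 households).  Households of a with-children type draw 1-3 children
    with ``child_count_probs`` weights (default expectation 1.8, about 600
    children per 1,000 households).  In working-adult households the first
    adult always works; a second adult works with probability
    ``p_second_adult_works``.
    """

    p_two_adults: float = 0.6
    child_count_probs: tuple[float, float, float] = (0.45, 0.30, 0.25)
    p_second_adult_works: float = 0.7

    def validate(self) -> None:
        if not 0.0 <= self.p_two_adults <= 1.0:
            raise ConfigurationError("p_two_adults must lie in [0, 1]")
        probs = np.asarray(self.child_count_probs, dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("child_count_probs must be a probability vector")
        if not 0.0 <= self.p_second_adult_works <= 1.0:
            raise ConfigurationError("p_second_adult_works must lie in [0, 1]")

    @property
    def expected_adults(self) -> float:
        return 1.0 + self.p_two_adults

    @property
    def expected_children_per_child_household(self) -> float:
        return float(np.dot(self.child_count_probs, [1, 2, 3]))


@dataclass(frozen=True)
class VenueSpec:
    """One stratum of venues: its kind, nominal capacity and count."""

    kind: str
    target_size: int
    count: int

    def validate(self) -> None:
        if self.kind not in WORKPLACE_KINDS + SCHOOL_KINDS:
            raise ConfigurationError(f"unknown venue kind {self.kind!r}")
        if self.target_size <= 0:
            raise ConfigurationError("venue target_size must be positive")
        if self.count < 0:
            raise ConfigurationError("venue count must be non-negative")


DEFAULT_MIX = HouseholdTypeMix.from_percentages(30.5, 54.4, 2.6, 12.4)
DEFAULT_SIZE_MODEL = HouseholdSizeModel()
DEFAULT_VENUE_SPECS: tuple[VenueSpec, ...] = (
    VenueSpec("workplace-big", 232, 2),
    VenueSpec("workplace-medium", 132, 5),
    VenueSpec("workplace-small", 24, 7),
    VenueSpec("school-secondary", 230, 1),
    VenueSpec("school-primary", 89, 3),
)
#: Normal (mean, sd) for per-agent preference variability, DQI units.
DEFAULT_SIGMA_DIST = (13.0, 2.5)
#: Triangular (min, peak, max) for the group-matching weight.
DEFAULT_W_DIST = (0.0, 0.39, 1.0)

_HTYPE_LABELS = ("work-child", "work-nochild", "nowork-child", "nowork-nochild")


@dataclass
class PopulationArrays:
    """Flat numpy view of a population, consumed by the simulation engine."""

    role: np.ndarray  # int8 codes, see ROLE_CODES
    household_id: np.ndarray  # int64
    venue_id: np.ndarray  # int64, -1 for agents with no venue
    sigma_pref: np.ndarray  # float64
    w_group: np.ndarray  # float64
    n_households: int
    venue_kind: np.ndarray  # object array of kind per venue id

    @property
    def n_agents(self) -> int:
        return self.role.size

    @property
    def is_worker(self) -> np.ndarray:
        return self.role == ROLE_CODES[WORKER]

    @property
    def is_child(self) -> np.ndarray:
        return self.role == ROLE_CODES[CHILD]

    @property
    def is_adult(self) -> np.ndarray:
        return self.role != ROLE_CODES[CHILD]


@dataclass
class Population:
    """Agents, households and venues as aligned tables.

    ``agents`` columns: agent_id, role, household_id, venue_id (nullable
    Int64), sigma_pref, w_group.  ``households`` columns: household_id,
    htype, n_adults, n_children.  ``venues`` columns: venue_id, kind,
    target_size.
    """

    agents: pd.DataFrame
    households: pd.DataFrame
    venues: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["venue_id", "kind", "target_size"])
    )

    # -- derived views ---------------------------------------------------
    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def n_households(self) -> int:
        return len(self.households)

    def household_has_children(self) -> pd.Series:
        """Boolean per household: does it contain at least one child?"""
        return (self.households.set_index("household_id")["n_children"] > 0)

    def to_arrays(self) -> PopulationArrays:
        a = self.agents
        venue_arr = a["venue_id"].astype("Int64").fillna(-1).to_numpy(dtype=np.int64)
        if len(self.venues):
            kinds = (
                self.venues.sort_values("venue_id")["kind"].to_numpy(dtype=object)
            )
        else:
            kinds = np.array([], dtype=object)
        return PopulationArrays(
            role=a["role"].map(ROLE_CODES).to_numpy(dtype=np.int8),
            household_id=a["household_id"].to_numpy(dtype=np.int64),
            venue_id=venue_arr.astype(np.int64),
            sigma_pref=a["sigma_pref"].to_numpy(dtype=float),
            w_group=a["w_group"].to_numpy(dtype=float),
            n_households=self.n_households,
            venue_kind=kinds,
        )

    def roster(self) -> pd.DataFrame:
        """Flat one-row-per-agent table with household/venue context."""
        hh = self.households.set_index("household_id")
        out = self.agents.copy()
        out["htype"] = out["household_id"].map(hh["htype"])
        out["has_children"] = out["household_id"].map(hh["n_children"] > 0)
        out["n_household"] = out["household_id"].map(hh["n_adults"] + hh["n_children"])
        if len(self.venues):
            out["venue_kind"] = out["venue_id"].map(
                self.venues.set_index("venue_id")["kind"]
            )
        else:
            out["venue_kind"] = pd.NA
        return out

    # -- serialisation ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "agents": self.agents.where(self.agents.notna(), None).to_dict(orient="records"),
            "households": self.households.to_dict(orient="records"),
            "venues": self.venues.to_dict(orient="records"),
        }
        text = json.dumps(doc, indent=1, default=_json_scalar)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Population":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        agents = pd.DataFrame(doc["agents"])
        agents["venue_id"] = agents["venue_id"].astype("Int64")
        return cls(
            agents=agents,
            households=pd.DataFrame(doc["households"]),
            venues=pd.DataFrame(doc["venues"], columns=["venue_id", "kind", "target_size"]),
        )

    def write_roster_csv(self, path: str | Path) -> None:
        self.roster().to_csv(path, index=False)

    # -- consistency -----------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise AssertionError on violation."""
        a, hh = self.agents, self.households
        counts = a.groupby("household_id").size()
        sizes = hh.set_index("household_id").eval("n_adults + n_children")
        assert counts.sort_index().equals(sizes.sort_index().astype(counts.dtype)), (
            "household member counts inconsistent with size table"
        )
        children = a[a["role"] == CHILD]
        workers = a[a["role"] == WORKER]
        if len(self.venues):
            assert children["venue_id"].notna().all(), "children must attend a school"
            assert workers["venue_id"].notna().all(), "workers must attend a workplace"
            kind = self.venues.set_index("venue_id")["kind"]
            assert children["venue_id"].map(kind).isin(SCHOOL_KINDS).all()
            assert workers["venue_id"].map(kind).isin(WORKPLACE_KINDS).all()
        for _, row in hh.iterrows():
            label = row["htype"]
            has_worker = (
                (a["household_id"] == row["household_id"]) & (a["role"] == WORKER)
            ).any()
            assert label.startswith("work") == has_worker, (
                f"household {row['household_id']} type {label} but has_worker={has_worker}"
            )


def _json_scalar(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def build_households(
    n_households: int,
    mix: HouseholdTypeMix = DEFAULT_MIX,
    size_model: HouseholdSizeModel = DEFAULT_SIZE_MODEL,
    rng: np.random.Generator | None = None,
) -> Population:
    """Generate households and their members (no venues yet).

    Each household draws a type from ``mix``, then adult and child counts
    from ``size_model``.  Working-adult household types always contain at
    least one worker; with-children types at least one child.
    """
    if n_households < 1:
        raise ConfigurationError("n_households must be >= 1")
    mix.validate()
    size_model.validate()
    rng = np.random.default_rng(rng)

    htype = rng.choice(4, size=n_households, p=mix.as_array())
    n_adults = 1 + (rng.random(n_households) < size_model.p_two_adults).astype(int)
    has_children_type = (htype == 0) | (htype == 2)
    n_children = np.where(
        has_children_type,
        rng.choice([1, 2, 3], size=n_households, p=size_model.child_count_probs),
        0,
    )

    # Adults, household-major order; first adult of a working household works.
    hh_of_adult = np.repeat(np.arange(n_households), n_adults)
    first = np.r_[True, hh_of_adult[1:] != hh_of_adult[:-1]]
    working_type = htype < 2
    adult_works = working_type[hh_of_adult] & (
        first | (rng.random(hh_of_adult.size) < size_model.p_second_adult_works)
    )

    hh_of_child = np.repeat(np.arange(n_households), n_children)
    roles = np.concatenate(
        [
            np.where(adult_works, WORKER, NONWORKING_ADULT),
            np.full(hh_of_child.size, CHILD, dtype=object),
        ]
    )
    household_id = np.concatenate([hh_of_adult, hh_of_child])
    order = np.argsort(household_id, kind="stable")

    agents = pd.DataFrame(
        {
            "agent_id": np.arange(household_id.size),
            "role": roles[order],
            "household_id": household_id[order],
            "venue_id": pd.array([pd.NA] * household_id.size, dtype="Int64"),
            "sigma_pref": np.nan,
            "w_group": np.nan,
        }
    )
    households = pd.DataFrame(
        {
            "household_id": np.arange(n_households),
            "htype": np.array(_HTYPE_LABELS, dtype=object)[htype],
            "n_adults": n_adults,
            "n_children": n_children,
        }
    )
    return Population(agents=agents, households=households)


def build_venues(
    pop: Population,
    specs: Sequence[VenueSpec] = DEFAULT_VENUE_SPECS,
    rng: np.random.Generator | None = None,
) -> Population:
    """Assign every worker to a workplace and every child to a school.

    Each agent draws its venue independently with probability proportional
    to venue capacity (``target_size``) within the relevant venue class, so
    realised sizes fluctuate around the capacity shares -- exact-capacity
    packing is deliberately not enforced.
    """
    rng = np.random.default_rng(rng)
    for s in specs:
        s.validate()
    rows = []
    vid = 0
    for s in specs:
        for _ in range(s.count):
            rows.append({"venue_id": vid, "kind": s.kind, "target_size": s.target_size})
            vid += 1
    venues = pd.DataFrame(rows, columns=["venue_id", "kind", "target_size"])

    agents = pop.agents.copy()
    for cls_kinds, role in ((WORKPLACE_KINDS, WORKER), (SCHOOL_KINDS, CHILD)):
        eligible = agents.index[agents["role"] == role]
        if eligible.empty:
            continue
        cls = venues[venues["kind"].isin(cls_kinds)]
        if cls.empty:
            raise ConfigurationError(f"no venues available for role {role!r}")
        weights = cls["target_size"].to_numpy(dtype=float)
        weights = weights / weights.sum()
        draws = rng.choice(cls["venue_id"].to_numpy(), size=eligible.size, p=weights)
        agents.loc[eligible, "venue_id"] = draws
    return Population(agents=agents, households=pop.households, venues=venues)


def assign_behaviour_params(
    pop: Population,
    sigma_dist: tuple[float, float] = DEFAULT_SIGMA_DIST,
    w_dist: tuple[float, float, float] = DEFAULT_W_DIST,
    rng: np.random.Generator | None = None,
) -> Population:
    """Draw each agent's fixed ``sigma_pref`` and ``w_group``.

    ``sigma_pref`` ~ Normal(*sigma_dist*) truncated below at
    :data:`SIGMA_FLOOR`; ``w_group`` ~ Triangular(*w_dist*).  Values are
    constant for the lifetime of the agent.
    """
    mean, sd = sigma_dist
    if mean <= 0:
        raise ConfigurationError("sigma_dist mean must be positive")
    if sd < 0:
        raise ConfigurationError("sigma_dist sd must be non-negative")
    lo, peak, hi = w_dist
    if not 0 <= lo <= peak <= hi:
        raise ConfigurationError("w_dist must satisfy 0 <= min <= peak <= max")
    rng = np.random.default_rng(rng)
    n = pop.n_agents
    sigma = np.maximum(rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean), SIGMA_FLOOR)
    if hi > lo:
        w = rng.triangular(lo, peak, hi, size=n)
    else:
        w = np.full(n, lo)
    agents = pop.agents.copy()
    agents["sigma_pref"] = sigma
    agents["w_group"] = w
    return Population(agents=agents, households=pop.households, venues=pop.venues)


def synthesise_population(
    n_households: int = 1000,
    mix: HouseholdTypeMix = DEFAULT_MIX,
    size_model: HouseholdSizeModel = DEFAULT_SIZE_MODEL,
    venue_specs: Sequence[VenueSpec] = DEFAULT_VENUE_SPECS,
    sigma_dist: tuple[float, float] = DEFAULT_SIGMA_DIST,
    w_dist: tuple[float, float, float] = DEFAULT_W_DIST,
    rng: np.random.Generator | None = None,
) -> Population:
    """Full pipeline: households, venues, behavioural parameters."""
    rng = np.random.default_rng(rng)
    pop = build_households(n_households, mix, size_model, rng)
    pop = build_venues(pop, venue_specs, rng)
    return assign_behaviour_params(pop, sigma_dist, w_dist, rng)
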