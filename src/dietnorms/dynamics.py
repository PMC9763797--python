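"""The per-meal engine: preference draws, norm mixing and meal choice.

Each agent carries a *personal norm*: a normal distribution centred on the
running mean of its last H chosen meals (H = 45, roughly two weeks at three
meals a day) with a fixed per-agent SD.  A simulated meal proceeds as:

1. every agent draws an *internal preference* from its personal norm;
2. agents eating at home average internal preferences within the household
   and all members eat the single meal nearest that average on the
   unconstrained home list;
3. agents eating at a workplace or school are partitioned into random
   eating groups; each forms a descriptive *group norm* (normal with the
   group's preference mean and SD), samples a final preference from the
   mixture of group and personal norms (weight ``w_group`` on the group
   component), and takes the nearest item on the venue's daily menu;
4. every agent's history is updated with its chosen meal.

Scalar reference implementations of each sub-step are exposed alongside the
vectorised whole-population ``step_meal`` so the two can be checked against
each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diet import nearest_sorted
from .population import PopulationArrays, Population, ROLE_CODES

__all__ = [
    "DEFAULT_HISTORY_LENGTH",
    "DEFAULT_GROUP_SIZE",
    "Clock",
    "AgentStates",
    "StepContext",
    "internal_preference",
    "household_choice",
    "group_norm",
    "mixed_preference",
    "init_states",
    "step_meal",
]

#: Running-mean window, in meals (~ two weeks at three meals/day).
DEFAULT_HISTORY_LENGTH = 45
#: Default venue eating-group size at weekday lunches.
DEFAULT_GROUP_SIZE = 6

BREAKFAST, LUNCH, DINNER = 0, 1, 2
_CHILD = ROLE_CODES["child"]
_WORKER = ROLE_CODES["worker"]


@dataclass(frozen=True)
class Clock:
    """Position in simulated time: three meals a day, weeks of 5+2 days.

    Step 0 is Monday breakfast; steps advance breakfast, lunch, dinner.
    """

    step: int

    @property
    def day(self) -> int:
        return self.step // 3

    @property
    def meal(self) -> int:
        return self.step % 3

    @property
    def is_weekday(self) -> bool:
        return self.day % 7 < 5

    @property
    def is_venue_lunch_slot(self) -> bool:
        return self.is_weekday and self.meal == LUNCH


@dataclass
class AgentStates:
    """Ring-buffer meal histories and running means for all agents.

    The buffer is always full: at initialisation it is pre-filled with the
    agent's initial whole-diet DQI, so the running mean starts exactly at
    that value.
    """

    history: np.ndarray  # (n_agents, H)
    total: np.ndarray  # (n_agents,) running sum of the buffer
    ptr: int = 0

    @property
    def n_agents(self) -> int:
        return self.history.shape[0]

    @property
    def history_length(self) -> int:
        return self.history.shape[1]

    @property
    def running_mean(self) -> np.ndarray:
        return self.total / self.history_length

    @classmethod
    def from_initial(cls, initial: np.ndarray, history_length: int = DEFAULT_HISTORY_LENGTH):
        initial = np.asarray(initial, dtype=float)
        hist = np.repeat(initial[:, None], history_length, axis=1)
        return cls(history=hist, total=hist.sum(axis=1))

    def update(self, chosen: np.ndarray) -> None:
        """Push one chosen meal per agent, evicting the oldest."""
        old = self.history[:, self.ptr].copy()
        self.history[:, self.ptr] = chosen
        self.total += chosen - old
        self.ptr = (self.ptr + 1) % self.history_length

    def recompute_means(self) -> np.ndarray:
        """Direct (non-incremental) running mean, for consistency checks."""
        return self.history.mean(axis=1)


@dataclass
class StepContext:
    """Everything outside agent state that one meal step depends on."""

    home_scores: np.ndarray  # ascending-sorted unconstrained meal list
    venue_menus: dict[int, np.ndarray] | None = None  # venue id -> sorted menu
    adult_lunch_mode: str = "normal"  # "normal" | "all-home"
    isolated: np.ndarray | None = None  # bool per agent; workers eating at home today
    group_size: int = DEFAULT_GROUP_SIZE
    include_self: bool = True


# ---------------------------------------------------------------------------
# Scalar reference operations
# ---------------------------------------------------------------------------

def internal_preference(
    running_mean: float, sigma_pref: float, rng: np.random.Generator
) -> float:
    """One draw from the personal norm, clipped to the DQI scale."""
    return float(np.clip(rng.normal(running_mean, sigma_pref), 0.0, 100.0))


def household_choice(prefs) -> float:
    """Household-shared final preference: the plain mean of members' draws."""
    prefs = np.asarray(prefs, dtype=float)
    if prefs.size == 0:
        raise ValueError("household must have at least one member present")
    return float(prefs.mean())


def group_norm(prefs) -> tuple[float, float]:
    """Descriptive norm of an eating group: (mean, sample SD) of preferences.

    Sample SD uses the n-1 denominator; a single co-eater yields SD 0.
    """
    prefs = np.asarray(prefs, dtype=float)
    if prefs.size == 0:
        raise ValueError("group must be non-empty")
    sd = float(prefs.std(ddof=1)) if prefs.size > 1 else 0.0
    return float(prefs.mean()), sd


def mixed_preference(
    personal: tuple[float, float],
    group: tuple[float, float],
    w_group: float,
    rng: np.random.Generator,
) -> float:
    """Sample the mixture of personal and group norms.

    Component selection: with probability ``w_group`` draw from the group
    norm, otherwise from the personal norm; the draw is clipped to [0, 100].
    """
    if not 0.0 <= w_group <= 1.0:
        raise ValueError("w_group must lie in [0, 1]")
    mean, sd = group if rng.random() < w_group else personal
    return float(np.clip(rng.normal(mean, sd), 0.0, 100.0))


def init_states(
    pop: Population | PopulationArrays,
    init_dist: tuple[float, float] = (37.4, 18.7),
    history_length: int = DEFAULT_HISTORY_LENGTH,
    rng: np.random.Generator | None = None,
) -> tuple[AgentStates, np.ndarray]:
    """Draw initial whole-diet DQI per agent and pre-fill histories.

    ``init_dist`` is (mean, sd) of a normal truncated to [0, 100] emulating
    the survey DQI distribution (median ~38, IQR ~26-51).  Returns the
    states and the vector of initial values.
    """
    mean, sd = init_dist
    n = pop.n_agents
    rng = np.random.default_rng(rng)
    if sd == 0:
        initial = np.full(n, float(np.clip(mean, 0.0, 100.0)))
    elif sd < 0:
        raise ValueError("init sd must be non-negative")
    else:
        a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
        initial = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return AgentStates.from_initial(initial, history_length), initial


# ---------------------------------------------------------------------------
# Vectorised whole-population step
# ---------------------------------------------------------------------------

def step_meal(
    states: AgentStates,
    pop: PopulationArrays,
    clock: Clock,
    ctx: StepContext,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance every agent by one meal.

    Returns ``(chosen, at_venue)``: the DQI of each agent's recorded meal
    and a boolean mask of agents who ate in a venue group this step.
    Household members eating at home share one identical meal.
    """
    n = pop.n_agents
    mu = states.running_mean
    prefs = np.clip(rng.normal(mu, pop.sigma_pref), 0.0, 100.0)

    attend = np.zeros(n, dtype=bool)
    if clock.is_venue_lunch_slot:
        if ctx.adult_lunch_mode == "normal":
            attend |= pop.role == _WORKER
            if ctx.isolated is not None:
                attend &= ~ctx.isolated
        elif ctx.adult_lunch_mode != "all-home":
            raise ValueError(f"unknown adult_lunch_mode {ctx.adult_lunch_mode!r}")
        attend |= pop.role == _CHILD

    chosen = np.empty(n, dtype=float)

    home_idx = np.flatnonzero(~attend)
    if home_idx.size:
        hh = pop.household_id[home_idx]
        hsum = np.bincount(hh, weights=prefs[home_idx], minlength=pop.n_households)
        hcnt = np.bincount(hh, minlength=pop.n_households)
        with np.errstate(invalid="ignore"):
            hmean = hsum / hcnt
        hh_meal = nearest_sorted(ctx.home_scores, np.nan_to_num(hmean))
        chosen[home_idx] = hh_meal[hh]

    if attend.any():
        _venue_lunch(states, pop, ctx, rng, prefs, attend, chosen)

    states.update(chosen)
    return chosen, attend


def _venue_lunch(states, pop, ctx, rng, prefs, attend, chosen):
    if ctx.venue_menus is None:
        raise RuntimeError("venue lunch step requires venue menus for the day")
    gs = max(int(ctx.group_size), 1)

    idx = np.flatnonzero(attend)
    perm = rng.permutation(idx)  # random order -> random groups within venue
    order = np.argsort(pop.venue_id[perm], kind="stable")
    members = perm[order]
    v_sorted = pop.venue_id[members]

    starts = np.flatnonzero(np.r_[True, v_sorted[1:] != v_sorted[:-1]])
    sizes = np.diff(np.r_[starts, members.size])
    pos = np.arange(members.size) - np.repeat(starts, sizes)
    groups_per_venue = (sizes + gs - 1) // gs
    offsets = np.repeat(np.r_[0, np.cumsum(groups_per_venue)[:-1]], sizes)
    gid = offsets + pos // gs

    p = prefs[members]
    cnt = np.bincount(gid)
    s1 = np.bincount(gid, weights=p)
    s2 = np.bincount(gid, weights=p * p)

    if ctx.include_self:
        gmean = s1 / cnt
        var = np.where(cnt > 1, (s2 - cnt * gmean**2) / np.maximum(cnt - 1, 1), 0.0)
        m_g, s_g = gmean[gid], np.sqrt(np.clip(var, 0.0, None))[gid]
    else:
        # leave-one-out co-eater statistics
        c = cnt[gid].astype(float)
        loo_mean = np.where(c > 1, (s1[gid] - p) / np.maximum(c - 1, 1), states.running_mean[members])
        loo_s2 = s2[gid] - p * p
        loo_var = np.where(
            c > 2,
            (loo_s2 - (c - 1) * loo_mean**2) / np.maximum(c - 2, 1),
            0.0,
        )
        m_g, s_g = loo_mean, np.sqrt(np.clip(loo_var, 0.0, None))

    use_group = rng.random(members.size) < pop.w_group[members]
    mix_mean = np.where(use_group, m_g, states.running_mean[members])
    mix_sd = np.where(use_group, s_g, pop.sigma_pref[members])
    final = np.clip(rng.normal(mix_mean, mix_sd), 0.0, 100.0)

    for b, start in enumerate(starts):
        stop = start + sizes[b]
        menu = ctx.venue_menus[int(v_sorted[start])]
        chosen[members[start:stop]] = nearest_sorted(menu, final[start:stop])
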