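"""Meals as diet-quality scores; menus under minimum dietary standards.

Every meal is represented solely by a diet quality index (DQI) score on
[0, 100], higher meaning healthier.  The synthetic meal universe emulates
the DQI distribution observed in UK adult diet surveys (normal with mean
37.4 and SD 18.7, truncated to the scale).  A venue's *daily menu* is a
uniform sub-sample of the meals meeting the venue's active minimum
standard; home meals draw on the unconstrained pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InfeasibleStandardError",
    "MealPool",
    "Menu",
    "generate_meal_pool",
    "build_daily_menu",
    "nearest_meal",
    "nearest_sorted",
    "DEFAULT_POOL_MEAN",
    "DEFAULT_POOL_SD",
    "DEFAULT_POOL_SIZE",
    "DEFAULT_MENU_SIZE",
]

DEFAULT_POOL_MEAN = 37.4
DEFAULT_POOL_SD = 18.7
#: Pool of 3000 meals keeps nearest-meal discretisation error well below
#: 1 DQI unit over the bulk of the distribution.
DEFAULT_POOL_SIZE = 3000
DEFAULT_MENU_SIZE = 10


class InfeasibleStandardError(ValueError):
    """No meal in the pool satisfies the requested minimum standard."""


def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("score list must be non-empty")
    if np.any((scores < 0) | (scores > 100)):
        raise ValueError("DQI scores must lie in [0, 100]")
    return scores


@dataclass(frozen=True)
class MealPool:
    """The fixed universe of meals, as DQI scores on [0, 100]."""

    scores: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "scores", _check_scores(self.scores))

    @property
    def sorted_scores(self) -> np.ndarray:
        return np.sort(self.scores)

    def eligible(self, min_standard: float) -> np.ndarray:
        return self.scores[self.scores >= min_standard]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"dqi": self.scores}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MealPool":
        return cls(pd.read_csv(path)["dqi"].to_numpy())


@dataclass(frozen=True)
class Menu:
    """A daily list of meal options, all meeting ``min_standard``."""

    scores: np.ndarray
    min_standard: float = 0.0

    def __post_init__(self):
        scores = _check_scores(self.scores)
        if np.any(scores < self.min_standard):
            raise ValueError("menu contains scores below its minimum standard")
        object.__setattr__(self, "scores", scores)


def generate_meal_pool(
    n_meals: int = DEFAULT_POOL_SIZE,
    mean: float = DEFAULT_POOL_MEAN,
    sd: float = DEFAULT_POOL_SD,
    rng: np.random.Generator | None = None,
) -> MealPool:
    """Draw the meal universe from a normal truncated to [0, 100]."""
    if n_meals < 1:
        raise ValueError("n_meals must be >= 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(rng)
    if sd == 0:
        return MealPool(np.full(n_meals, np.clip(mean, 0.0, 100.0)))
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    scores = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_meals, random_state=rng)
    return MealPool(scores)


def build_daily_menu(
    pool: MealPool,
    min_standard: float,
    menu_size: int = DEFAULT_MENU_SIZE,
    rng: np.random.Generator | None = None,
) -> Menu:
    """Sample a daily menu uniformly (with replacement) from eligible meals."""
    rng = np.random.default_rng(rng)
    eligible = pool.eligible(min_standard)
    if eligible.size == 0:
        raise InfeasibleStandardError(
            f"no meals in the pool meet the minimum standard {min_standard!r}"
        )
    return Menu(rng.choice(eligible, size=menu_size, replace=True), min_standard)


def nearest_sorted(sorted_scores: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Vectorised nearest value in an ascending-sorted array; ties go high."""
    i = np.searchsorted(sorted_scores, targets)
    hi = sorted_scores[np.minimum(i, sorted_scores.size - 1)]
    lo = sorted_scores[np.maximum(i - 1, 0)]
    return np.where(hi - targets <= targets - lo, hi, lo)


def nearest_meal(
    preference: float,
    menu: Menu | np.ndarray,
    tie_break: str = "higher",
    rng: np.random.Generator | None = None,
) -> float:
    """The menu item closest in DQI to ``preference``.

    Ties (preference equidistant from two items) resolve to the higher-DQI
    item by default, or uniformly at random with ``tie_break="random"``.
    """
    scores = menu.scores if isinstance(menu, Menu) else np.asarray(menu, dtype=float)
    if scores.size == 0:
        raise ValueError("menu must be non-empty")
    d = np.abs(scores - preference)
    best = d.min()
    candidates = np.unique(scores[np.isclose(d, best, rtol=0.0, atol=1e-12)])
    if tie_break == "higher" or candidates.size == 1:
        return float(candidates.max())
    if tie_break == "random":
        rng = np.random.default_rng(rng)
        return float(rng.choice(candidates))
    raise ValueError(f"unknown tie_break {tie_break!r}")
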