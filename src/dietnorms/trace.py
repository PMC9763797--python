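"""Simulation output container.

A :class:`Trace` records, for one scenario run, every agent's chosen-meal
DQI at every step, the per-step running mean (the habitual-diet series the
analysis layer works on), a venue-attendance mask, and the agent roster
with strata labels.  It is the sole input to the metrics layer and can be
round-tripped through a long-format CSV.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace"]


@dataclass
class Trace:
    """Output of one scenario iteration.

    ``running_mean`` has ``horizon + 1`` rows: row 0 is the initial state,
    row ``t`` the state after step ``t-1``.  ``choices`` and ``at_venue``
    have one row per step.
    """

    roster: pd.DataFrame
    choices: np.ndarray  # (horizon, n_agents) chosen-meal DQI
    running_mean: np.ndarray  # (horizon + 1, n_agents)
    at_venue: np.ndarray  # (horizon, n_agents) bool
    meta: dict = field(default_factory=dict)

    @property
    def horizon(self) -> int:
        return self.choices.shape[0]

    @property
    def n_agents(self) -> int:
        return self.choices.shape[1]

    @property
    def adult_mask(self) -> np.ndarray:
        return (self.roster["role"] != "child").to_numpy()

    def adult_running_mean(self) -> np.ndarray:
        """Running-mean series restricted to adults, shape (horizon+1, n_adults)."""
        return self.running_mean[:, self.adult_mask]

    def final_running_mean(self) -> np.ndarray:
        return self.running_mean[-1]

    def initial_running_mean(self) -> np.ndarray:
        return self.running_mean[0]

    # -- long-format CSV -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long per-step, per-agent table of chosen meals with strata labels."""
        horizon, n = self.choices.shape
        steps = np.repeat(np.arange(horizon), n)
        r = self.roster
        out = pd.DataFrame(
            {
                "step": steps,
                "day": steps // 3,
                "meal": steps % 3,
                "agent_id": np.tile(r["agent_id"].to_numpy(), horizon),
                "household_id": np.tile(r["household_id"].to_numpy(), horizon),
                "venue_id": np.tile(r["venue_id"].to_numpy(), horizon),
                "role": np.tile(r["role"].to_numpy(), horizon),
                "has_children": np.tile(r["has_children"].to_numpy(), horizon),
                "chosen_dqi": self.choices.ravel(),
                "at_venue": self.at_venue.ravel(),
                "running_mean": self.running_mean[1:].ravel(),
            }
        )
        return out

    def write_csv(self, path: str | Path, compress: bool | None = None) -> Path:
        path = Path(path)
        if compress is None:
            compress = path.suffix == ".gz"
        frame = self.to_frame()
        if compress:
            with gzip.open(path, "wt") as fh:
                frame.to_csv(fh, index=False)
        else:
            frame.to_csv(path, index=False)
        return path
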