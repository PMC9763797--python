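"""Configuration files, run manifests and report writing.

Scenario configuration is a flat YAML/JSON key set; every key has a shipped
default so an empty file yields the headline experiment (universal minimum
standard 60, schools from step 0, workplaces from step 200, no isolation,
1,000 households, 500 steps, 20 iterations).  A :class:`RunManifest`
records everything needed to reproduce a run: the canonical config hash,
base seed, per-iteration seeds and output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .population import ConfigurationError, HouseholdSizeModel, HouseholdTypeMix
from .scenarios import (
    EngineParams,
    PopulationConfig,
    ScenarioConfig,
    default_narrative,
    iteration_seed,
)

__all__ = ["load_config", "config_hash", "RunManifest", "write_report", "config_to_dict"]

_VERSION = "0.1.0"

# Flat config keys and where they land; value = (section, attribute, validator).
def _fraction(v):
    if not 0.0 <= v <= 1.0:
        raise ConfigurationError(f"expected a fraction in [0, 1], got {v!r}")
    return float(v)


def _standard(v):
    if not 0.0 <= v <= 100.0:
        raise ConfigurationError(f"expected a DQI value in [0, 100], got {v!r}")
    return float(v)


def _count(v):
    if int(v) < 1:
        raise ConfigurationError(f"expected a positive count, got {v!r}")
    return int(v)


_KEYS = {
    "name": str,
    "seed": int,
    "iterations": _count,
    "horizon": _count,
    "n_households": _count,
    "min_standard": _standard,
    "isolation_fraction": _fraction,
    "strict_methods": bool,
    "history_length": _count,
    "group_size": _count,
    "menu_size": _count,
    "pool_size": _count,
    "pool_mean": _standard,
    "pool_sd": float,
    "init_mean": _standard,
    "init_sd": float,
    "sigma_mean": float,
    "sigma_sd": float,
    "w_min": _fraction,
    "w_peak": _fraction,
    "w_max": _fraction,
    "p_two_adults": _fraction,
    "p_second_adult_works": _fraction,
}


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a flat YAML/JSON scenario configuration.

    Unknown keys and out-of-range values raise
    :class:`~dietnorms.population.ConfigurationError`; missing keys take
    the headline-scenario defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping of keys")
    unknown = set(raw) - set(_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    vals = {}
    for key, value in raw.items():
        try:
            vals[key] = _KEYS[key](value)
        except ConfigurationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad value for {key!r}: {value!r}") from exc

    size_model = HouseholdSizeModel(
        p_two_adults=vals.get("p_two_adults", 0.6),
        p_second_adult_works=vals.get("p_second_adult_works", 0.7),
    )
    population = PopulationConfig(
        n_households=vals.get("n_households", 1000),
        size_model=size_model,
        sigma_dist=(vals.get("sigma_mean", 13.0), vals.get("sigma_sd", 2.5)),
        w_dist=(vals.get("w_min", 0.0), vals.get("w_peak", 0.39), vals.get("w_max", 1.0)),
    )
    engine = EngineParams(
        history_length=vals.get("history_length", 45),
        group_size=vals.get("group_size", 6),
        menu_size=vals.get("menu_size", 10),
        pool_size=vals.get("pool_size", 3000),
        pool_mean=vals.get("pool_mean", 37.4),
        pool_sd=vals.get("pool_sd", 18.7),
        init_mean=vals.get("init_mean", 37.4),
        init_sd=vals.get("init_sd", 18.7),
    )
    cfg = default_narrative(
        min_standard=vals.get("min_standard", 60.0),
        isolation_fraction=vals.get("isolation_fraction", 0.0),
        horizon=vals.get("horizon", 500),
        iterations=vals.get("iterations", 20),
        base_seed=vals.get("seed", 0),
        strict_methods=vals.get("strict_methods", False),
        population=population,
        engine=engine,
    )
    if "name" in vals:
        cfg = dataclasses.replace(cfg, name=vals["name"])
    return cfg


def config_to_dict(cfg: ScenarioConfig) -> dict:
    """Canonical plain-dict form of a scenario configuration."""
    return json.loads(json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str))


def config_hash(cfg: ScenarioConfig) -> str:
    """Deterministic hash over the semantic content of a configuration."""
    canonical = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    base_seed: int
    per_run_seeds: dict[str, list[int]]
    version: str = _VERSION
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path


def write_report(
    traces: dict,
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    cfg: ScenarioConfig | None = None,
    write_traces: bool = True,
) -> Path:
    """Write trace CSVs, metric tables and a manifest to ``out_dir``.

    ``traces`` maps (name, iteration) keys to Trace objects; ``tables``
    maps file stems to DataFrames.  Existing files are overwritten.
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    if write_traces:
        for (name, it), trace in traces.items():
            p = out / f"trace-{name}-it{it}.csv.gz"
            trace.write_csv(p)
            outputs.append(p.name)
    for stem, table in tables.items():
        p = out / f"{stem}.csv"
        table.to_csv(p)
        outputs.append(p.name)
    seeds = {}
    if cfg is not None:
        seeds[cfg.name] = [
            list(map(int, iteration_seed(cfg, i).entropy)) for i in range(cfg.iterations)
        ]
    manifest = RunManifest(
        config_hash=config_hash(cfg) if cfg is not None else "",
        base_seed=cfg.base_seed if cfg is not None else 0,
        per_run_seeds=seeds,
        outputs=outputs,
    )
    return manifest.write(out / "manifest.json")
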