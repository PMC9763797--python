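"""Summary statistics over simulation traces.

Per-agent "diet quality" at a step is the running mean of the last H
chosen meals -- the habitual diet -- not the single meal eaten at that
step.  The functions here compute the descriptive outputs the simulator is
analysed with: percentile bands of the adult distribution over time,
end-of-run means stratified by household composition and work status,
ordinary-least-squares dose-response slopes over swept scenario parameters,
and the proportion of adults whose habitual diet declined.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trace import Trace

__all__ = [
    "RegressionResult",
    "percentile_series",
    "final_adult_median",
    "final_adult_mean",
    "slope_vs_standard",
    "slope_vs_isolation",
    "stratified_summary",
    "interaction_effect",
    "proportion_declined",
]


class RegressionResult(NamedTuple):
    slope: float
    conf_int: tuple[float, float]

    @property
    def ci_low(self) -> float:
        return self.conf_int[0]

    @property
    def ci_high(self) -> float:
        return self.conf_int[1]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    model = sm.OLS(np.asarray(y, float), sm.add_constant(np.asarray(x, float))).fit()
    lo, hi = model.conf_int()[1]
    return RegressionResult(float(model.params[1]), (float(lo), float(hi)))


def percentile_series(
    traces: Sequence[Trace], percentiles: Sequence[float] = (2.5, 25.0, 50.0, 75.0, 97.5)
) -> pd.DataFrame:
    """Per-step percentiles of adult diet quality, pooled across iterations.

    Returns a DataFrame indexed by step (0 = initial state) with one column
    per requested percentile.
    """
    if not len(traces):
        raise ValueError("at least one trace is required")
    percentiles = list(percentiles)
    if not percentiles:
        raise ValueError("percentile list must be non-empty")
    pooled = np.hstack([t.adult_running_mean() for t in traces])
    table = np.percentile(pooled, percentiles, axis=1).T
    return pd.DataFrame(table, columns=[f"p{p:g}" for p in percentiles]).rename_axis("step")


def final_adult_median(trace: Trace) -> float:
    """Median adult diet quality at the end of the run."""
    return float(np.median(trace.final_running_mean()[trace.adult_mask]))


def final_adult_mean(trace: Trace) -> float:
    """Mean adult diet quality at the end of the run."""
    return float(np.mean(trace.final_running_mean()[trace.adult_mask]))


def slope_vs_standard(results: pd.DataFrame) -> RegressionResult:
    """OLS slope of end-of-run median adult DQI on the minimum standard.

    ``results`` needs columns ``standard`` and ``value`` (one row per
    (standard, iteration) run).  Returns the slope per 1-point increase in
    the standard, with its 95% CI.
    """
    if results["standard"].nunique() < 2:
        raise ValueError("at least two distinct standard levels are required")
    return _ols_slope(results["standard"].to_numpy(), results["value"].to_numpy())


def slope_vs_isolation(results: pd.DataFrame, increment: float = 0.2) -> RegressionResult:
    """OLS slope of end-of-run mean adult DQI per ``increment`` of isolation.

    ``results`` needs columns ``fraction`` (of workers isolating, in
    [0, 1]) and ``value``.  The slope is rescaled to the given increment
    (default: per additional 20% of workers isolating).
    """
    if results["fraction"].nunique() < 2:
        raise ValueError("at least two distinct isolation fractions are required")
    r = _ols_slope(results["fraction"].to_numpy(), results["value"].to_numpy())
    return RegressionResult(
        r.slope * increment, (r.conf_int[0] * increment, r.conf_int[1] * increment)
    )


_STRATA = {
    "children": lambda w, c: c,
    "no_children": lambda w, c: ~c,
    "worker": lambda w, c: w,
    "non_worker": lambda w, c: ~w,
    "worker_children": lambda w, c: w & c,
    "worker_no_children": lambda w, c: w & ~c,
    "non_worker_children": lambda w, c: ~w & c,
    "non_worker_no_children": lambda w, c: ~w & ~c,
}


def stratified_summary(trace: Trace, at_step: int | None = None) -> pd.DataFrame:
    """Mean +/- SD adult diet quality by household/work strata.

    Strata: presence of children in the household, worker status, and
    their cross.  SD is the sample SD (n-1 denominator; 0 for a single
    agent).  Empty strata are omitted from the table.
    """
    if at_step is None:
        at_step = trace.horizon
    if not 0 <= at_step <= trace.horizon:
        raise ValueError("at_step outside the trace horizon")
    adults = trace.adult_mask
    values = trace.running_mean[at_step][adults]
    worker = (trace.roster["role"] == "worker").to_numpy()[adults]
    children = trace.roster["has_children"].to_numpy(dtype=bool)[adults]
    rows = []
    for name, pick in _STRATA.items():
        mask = pick(worker, children)
        if not mask.any():
            continue
        v = values[mask]
        rows.append(
            {
                "stratum": name,
                "n": int(mask.sum()),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def interaction_effect(trace: Trace, window: tuple[int, int] = (0, 300)) -> RegressionResult:
    """Child-presence x time interaction in adult diet quality.

    Fits ``dqi ~ time + children + time:children`` by OLS over adult
    running means for steps in the inclusive ``window`` and returns the
    interaction coefficient (DQI points per model step) with its 95% CI.
    """
    lo, hi = window
    if not 0 <= lo < hi <= trace.horizon:
        raise ValueError("window must lie within the trace horizon")
    adults = trace.adult_mask
    children = trace.roster["has_children"].to_numpy(dtype=bool)[adults]
    if children.all() or not children.any():
        raise ValueError("both child-present and child-absent adults are required")
    y = trace.running_mean[lo : hi + 1, adults]
    steps = np.arange(lo, hi + 1, dtype=float)
    t = np.repeat(steps, children.size)
    c = np.tile(children.astype(float), steps.size)
    X = sm.add_constant(np.column_stack([t, c, t * c]))
    model = sm.OLS(y.ravel(), X).fit()
    ci = model.conf_int()[3]
    return RegressionResult(float(model.params[3]), (float(ci[0]), float(ci[1])))


def proportion_declined(trace: Trace) -> float:
    """Fraction of adults whose final habitual diet is below their initial one."""
    adults = trace.adult_mask
    return float(
        np.mean(trace.final_running_mean()[adults] < trace.initial_running_mean()[adults])
    )
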