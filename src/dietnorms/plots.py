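"""Optional plotting helpers (require matplotlib, installed as the
``dietnorms[plot]`` extra): percentile ribbons of adult diet quality over
time and per-agent spaghetti trajectories stratified by household type.
"""

from __future__ import annotations

import numpy as np

from . import metrics
from .trace import Trace


def percentile_ribbon(traces, ax=None):
    """Shaded 2.5-97.5 and 25-75 percentile bands with the median line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = metrics.percentile_series(traces, (2.5, 25, 50, 75, 97.5))
    steps = table.index.to_numpy()
    ax.fill_between(steps, table["p2.5"], table["p97.5"], color="0.85", label="2.5-97.5%")
    ax.fill_between(steps, table["p25"], table["p75"], color="0.6", label="25-75%")
    ax.plot(steps, table["p50"], color="black", lw=1.2, label="median")
    ax.set_xlabel("time step")
    ax.set_ylabel("adult diet quality index")
    ax.legend(frameon=False)
    return ax


def stratified_spaghetti(trace: Trace, max_lines_per_panel: int = 200, axes=None):
    """Per-adult trajectories, split by worker status x children in household."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 2, sharex=True, sharey=True, figsize=(8, 6))
    adults = trace.adult_mask
    worker = (trace.roster["role"] == "worker").to_numpy()[adults]
    children = trace.roster["has_children"].to_numpy(dtype=bool)[adults]
    series = trace.adult_running_mean()
    panels = [
        ("worker, children", worker & children),
        ("worker, no children", worker & ~children),
        ("non-worker, children", ~worker & children),
        ("non-worker, no children", ~worker & ~children),
    ]
    for ax, (title, mask) in zip(np.ravel(axes), panels):
        cols = np.flatnonzero(mask)[:max_lines_per_panel]
        ax.plot(series[:, cols], color="tab:blue", alpha=0.08, lw=0.5)
        if mask.any():
            ax.plot(series[:, mask].mean(axis=1), color="tab:red", lw=1.5)
        ax.set_title(f"{title} (n={int(mask.sum())})", fontsize=9)
    return axes
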