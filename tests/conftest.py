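import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dietnorms.trace import Trace

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_trace(running_mean, roles, has_children, choices=None):
    """Build a minimal Trace from explicit running-mean series.

    ``running_mean``: array (horizon+1, n_agents); ``roles``: list of role
    strings; ``has_children``: bool per agent.
    """
    running_mean = np.asarray(running_mean, dtype=float)
    n = running_mean.shape[1]
    horizon = running_mean.shape[0] - 1
    roster = pd.DataFrame(
        {
            "agent_id": np.arange(n),
            "role": roles,
            "household_id": np.arange(n),
            "venue_id": pd.array([pd.NA] * n, dtype="Int64"),
            "has_children": np.asarray(has_children, dtype=bool),
        }
    )
    if choices is None:
        choices = running_mean[1:]
    return Trace(
        roster=roster,
        choices=np.asarray(choices, dtype=float),
        running_mean=running_mean,
        at_venue=np.zeros((horizon, n), dtype=bool),
        meta={"name": "toy"},
    )


@pytest.fixture
def toy_trace():
    rm = np.array(
        [
            [30.0, 40.0, 50.0, 60.0],
            [35.0, 38.0, 55.0, 58.0],
            [40.0, 36.0, 60.0, 56.0],
        ]
    )
    return make_toy_trace(
        rm,
        roles=["worker", "worker", "nonworking-adult", "nonworking-adult"],
        has_children=[True, False, True, False],
    )
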