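import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture()
def small_clone_table():
    from clonfate import CloneTable

    return CloneTable(
        clone_id=np.array([1, 2, 3, 4]),
        n_H=np.array([10, 0, 5, 100]),
        n_L=np.array([0, 20, 5, 100]),
    )


def tables_by_day(traj):
    """Regroup a Trajectory's sorted counts as {day: {gate: counts}}."""
    by_day: dict[float, dict[str, pd.Series]] = {}
    for (day, gate), counts in traj.sorted_counts.items():
        by_day.setdefault(day, {})[gate] = counts
    return by_day
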