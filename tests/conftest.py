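import numpy as np
import pytest

import bptraj as bt


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 120-patient cohort with BP series (shared across tests)."""
    return bt.simulate_cohort(bt.CohortConfig(n_patients=120), seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """A seeded full-size (n=353) cohort with BP series."""
    return bt.simulate_cohort(seed=1)


@pytest.fixture
def flat_two_group_series():
    """200 patients from two well-separated flat trajectories (120 vs 160 mmHg)."""
    rng = np.random.default_rng(42)
    grid = np.linspace(0.0, 24.0, 13)
    series, truth = [], []
    for i in range(200):
        g = int(rng.uniform() < 0.4)  # 60% low, 40% high
        mu = 120.0 if g == 0 else 160.0
        series.append(bt.BPSeries(f"P{i:03d}", "SBP", grid,
                                  mu + rng.normal(0, 5.0, size=len(grid))))
        truth.append(g + 1)
    return series, np.array(truth)
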