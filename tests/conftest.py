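"""Shared fixtures: seeded generators and small planted datasets."""

import numpy as np
import pytest

import tenec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_block_data():
    """Clean 3-group planted tensor with alternating disjoint schedules."""
    groups = {f"G{g}": tuple(f"g{g}n{i}" for i in range(5)) for g in range(3)}
    n_intervals = 12
    schedule = {}
    for g in range(3):
        probs = np.zeros(n_intervals)
        probs[g::3] = 1.0
        schedule[f"G{g}"] = probs
    spec = tenec.PlantedSpec(groups=groups, schedule=schedule,
                             n_intervals=n_intervals, p_in=1.0, p_noise=0.0, seed=1)
    return tenec.generate(spec)


@pytest.fixture(scope="session")
def school_data():
    """School-like fixture: 10 groups of 6, 40 intervals, 4-group lunch event."""
    return tenec.generate(tenec.school_spec(seed=11))


@pytest.fixture(scope="session")
def school_best(school_data):
    """Selected best run of R=11, 10-restart factorization of the school fixture."""
    values = school_data.tensor.values
    config = tenec.SolverConfig(rank=11, n_runs=10, seed=0)
    runs = tenec.factorize(values, config)
    ranked = tenec.select_best(values, runs)
    return ranked[0]
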