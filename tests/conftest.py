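import numpy as np
import pandas as pd
import pytest

from mirtraj import SimulationConfig, default_contrasts, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config with strong planted effects, reused across tests."""
    return SimulationConfig(n_genes=800, n_mirnas=60, n_reps_per_condition=3,
                            lib_size_mean=300_000.0, mirna_lib_size_mean=150_000.0,
                            n_regulator_mirnas=6, targets_per_mirna=10, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_contrasts(small_dataset):
    return default_contrasts(small_dataset.design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_counts():
    """Deterministic 6-feature x 4-sample count matrix."""
    return pd.DataFrame(
        [[10, 12, 100, 95], [0, 3, 5, 0], [50, 48, 52, 55],
         [200, 180, 20, 25], [7, 7, 7, 7], [1000, 1100, 900, 950]],
        index=[f"g{i}" for i in range(6)],
        columns=["s1", "s2", "s3", "s4"],
    )
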