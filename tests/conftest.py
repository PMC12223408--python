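import numpy as np
import pandas as pd
import pytest

from bogforam import OtuTable, SimConfig, simulate_dataset


def random_table(rng: np.random.Generator, n_otus: int, n_samples: int, scale: float = 200.0) -> OtuTable:
    """A random integer table with heavy-tailed cells and plenty of zeros."""
    lam = rng.exponential(scale, size=(n_otus, 1))
    counts = rng.poisson(lam * rng.random((n_otus, n_samples)))
    counts[rng.random(counts.shape) < 0.3] = 0
    return OtuTable(
        pd.DataFrame(
            counts.astype(np.int64),
            index=[f"OTU{i + 1}" for i in range(n_otus)],
            columns=[f"S{j + 1}" for j in range(n_samples)],
        )
    )


@pytest.fixture
def small_table() -> OtuTable:
    return OtuTable(
        pd.DataFrame(
            [[100, 200, 50], [10, 0, 30], [0, 5, 0]],
            index=["OTU1", "OTU2", "OTU3"],
            columns=["S1", "S2", "S3"],
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic dataset, shared across tests."""
    return simulate_dataset(SimConfig(seed=11))
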