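import numpy as np
import pytest

from rfqt import Dataset, SimConfig, simulate_dataset


@pytest.fixture
def toy_dataset() -> Dataset:
    """Small deterministic dataset with exact structure: X = Z, Y = 2Z."""
    n = 12
    z = np.arange(n, dtype=float)
    return Dataset(
        ids=np.arange(n),
        Z=z,
        X=z.copy(),
        Y=2 * z,
        M=np.column_stack([z, np.ones(n)]),
        covariate_names=("M1", "M2"),
    )


@pytest.fixture(scope="session")
def modified_sim():
    """Scenario A with strong effect modification (gamma = 0.5)."""
    return simulate_dataset(SimConfig(n=4000, scenario="A", gamma=0.5, seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """Scenario A with the modifier effects forced to exactly zero."""
    return simulate_dataset(SimConfig(n=4000, scenario="A", pure_null=True, seed=12))
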