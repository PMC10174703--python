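import numpy as np
import pytest

from protdpc import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def paper_design():
    """One full-size dataset under the reference simulation design."""
    return simulate_dataset(SimConfig(seed=123))


@pytest.fixture(scope="session")
def small_sim():
    """A small two-group dataset with DPC missingness for fast unit tests."""
    return simulate_dataset(
        SimConfig(n_features=400, n_samples_per_group=4, n_de=40, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
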