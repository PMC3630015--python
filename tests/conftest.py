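import numpy as np
import pytest

from paircorr import PairedDataset, SimulationDesign, simulate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n=12, p=6, q=4):
    return PairedDataset(
        rng.standard_normal((n, p)), rng.standard_normal((n, q))
    ).standardize()


@pytest.fixture
def small_data(rng):
    return random_dataset(rng)


@pytest.fixture(scope="session")
def design():
    return SimulationDesign()


@pytest.fixture(scope="session")
def sim30(design):
    """One n=30 draw of the default block-correlated design."""
    return simulate_pair(design, seed=123)


@pytest.fixture(scope="session")
def sim500(design):
    """A large draw for population-level checks."""
    import dataclasses

    big = dataclasses.replace(design, n_samples=500)
    return simulate_pair(big, seed=77)
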