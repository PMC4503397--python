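import numpy as np
import pytest

from nabind.fixtures import FixtureConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by read-only tests."""
    return generate_dataset(FixtureConfig(seed=42, n_chains=10,
                                          length_range=(50, 70)))


@pytest.fixture(scope="session")
def complementary_dataset():
    """Feature signal and template annotations on disjoint binding halves."""
    return generate_dataset(FixtureConfig(seed=42, n_chains=10,
                                          length_range=(50, 70),
                                          complementary=True))


@pytest.fixture(scope="session")
def medium_dataset():
    """A 30-chain dataset large enough for classifier-regime comparisons."""
    return generate_dataset(FixtureConfig(seed=7, n_chains=30))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
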