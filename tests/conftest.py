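import numpy as np
import pytest

from smlmkit import LocalizationTable, S2Config, make_s2_testset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_table(rng):
    """100 random localizations with frame and photon columns."""
    n = 100
    return LocalizationTable.from_arrays(
        rng.uniform(0, 1000, n),
        rng.uniform(0, 1000, n),
        rng.uniform(5, 30, n),
        channel=rng.integers(1, 3, n),
        frame=rng.integers(0, 500, n),
        photons=rng.uniform(100, 5000, n),
    )


@pytest.fixture(scope="session")
def s2_default():
    """One default benchmark realization shared across tests."""
    return make_s2_testset(S2Config(seed=7))
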