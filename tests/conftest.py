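import numpy as np
import pytest

from torfes import synthetic as syn
from torfes.geometry import ConfigurationSet


@pytest.fixture(scope="session")
def ala2_mixture():
    return syn.ala2_like()


@pytest.fixture(scope="session")
def small_ala2_sample(ala2_mixture):
    """2D three-mode sample, small enough for unit tests."""
    return syn.sample_unbiased(ala2_mixture, 3000, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def uniform_2d():
    rng = np.random.default_rng(7)
    return ConfigurationSet(rng.uniform(-np.pi, np.pi, size=(500, 2)))
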