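import numpy as np
import pytest

from hsi_oncopipe.bands import make_band_table
from hsi_oncopipe.synthetic import make_default_library


@pytest.fixture(scope="session")
def bands():
    return make_band_table()


@pytest.fixture(scope="session")
def library(bands):
    return make_default_library(bands)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
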