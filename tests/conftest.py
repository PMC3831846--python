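import numpy as np
import pytest

from alutrack.core_io import default_registry, toy_registry


@pytest.fixture(scope="session")
def toy_reg():
    return toy_registry()


@pytest.fixture(scope="session")
def yb_reg():
    return default_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
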