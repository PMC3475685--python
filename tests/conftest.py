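import numpy as np
import pytest

from laminarcortex import ModelParams


@pytest.fixture(scope="session")
def tiny_params():
    """Small grid for fast dynamical tests."""
    return ModelParams(grid_n=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
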