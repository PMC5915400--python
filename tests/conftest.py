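import numpy as np
import pytest
from hypothesis import settings

import matesim

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A quick desk-scale parameterization: 20x20 grid at moderate density."""
    return matesim.SimParams(
        lattice=matesim.LatticeConfig(side_length=20, density=0.2),
        max_transfers=50,
        seed=7,
    )
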