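import numpy as np
import pytest

from clockmesh import synth


@pytest.fixture
def small_slice_config():
    """A small, quick slice simulation used across imaging/network tests."""
    return synth.SliceSimConfig(
        grid_shape=(96, 96), n_shell=8, n_core=8, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
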