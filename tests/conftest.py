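import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rand_image(rng, h=16, w=16):
    """Random unit-range RGB image."""
    return rng.random((h, w, 3))


@pytest.fixture
def phantom():
    from desmoke.smoke_sim import make_tissue_phantom
    return make_tissue_phantom(64, seed=7)
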