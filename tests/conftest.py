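import numpy as np
import pytest

from lumenflow import generate_scene, preset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wildtype_scene():
    return generate_scene(preset("wildtype_ring"))


@pytest.fixture(scope="session")
def conversion_scene():
    params = preset("conversion_test")
    stack, truth = generate_scene(params)
    return params, stack, truth


def random_mask(rng, shape=(40, 40), p=0.3):
    from lumenflow import BinaryMask

    return BinaryMask(rng.random(shape) < p)
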