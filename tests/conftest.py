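import numpy as np
import pytest

from waveden import GrayImage, NoiseSpec, add_gaussian_noise, make_phantom


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(64, 64, 2, seed=7)


@pytest.fixture(scope="session")
def phantom128():
    return make_phantom(128, 128, 3, seed=11)


@pytest.fixture(scope="session")
def noisy64(phantom64):
    """phantom64 with the standard Gaussian corruption (std 25, 8-bit scale)."""
    return add_gaussian_noise(phantom64, NoiseSpec("gaussian", gaussian_std=25.0, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_image(rng, shape=(16, 16), value_range="unit"):
    peak = 1.0 if value_range == "unit" else 255.0
    return GrayImage(rng.uniform(0, peak, size=shape), value_range)
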