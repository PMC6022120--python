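import numpy as np
import pytest

from mff.synthetic import half_plane_mask, make_multifocus_pair, make_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_rgb(rng):
    """A 32x32 random RGB image in [0, 1]."""
    return rng.uniform(0.0, 1.0, (32, 32, 3))


@pytest.fixture(scope="session")
def small_pair():
    """A 128x128 plant-like complementary-blur pair for fast pipeline tests."""
    truth = make_truth("plant-like", (128, 128), seed=7)
    return make_multifocus_pair(truth, half_plane_mask((128, 128)), blur_sigma=3.0, seed=7)
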