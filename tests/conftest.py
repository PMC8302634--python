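import numpy as np
import pytest

from fatquant import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mid_phantom():
    """One noiseless moderate-fat phantom shared by read-only tests."""
    spec = PhantomSpec(image_size=128, occupation_ratio_true=0.6, fat_fraction_true=0.3,
                       intensity_sd=0.0, seed=7)
    return generate_phantom(spec)


def random_mask_pair(rng, shape=(40, 40), p=0.3):
    gt = rng.random(shape) < p
    pred = gt ^ (rng.random(shape) < 0.1)
    return gt, pred
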