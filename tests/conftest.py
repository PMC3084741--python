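import numpy as np
import pytest

from truecoloc import ImagePair, SimConfigA, simulate_pixel_objects
from truecoloc.kinetics import subtract_background


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_pair(rng):
    """A generic strictly-positive random pair (all coefficients defined)."""
    s1 = rng.uniform(1, 255, size=(24, 24))
    s2 = rng.uniform(1, 255, size=(24, 24))
    return ImagePair(s1, s2)


def make_sim_pair(density=0.10, coloc_fraction=0.5, seed=0, side=160):
    """Pixel-object pair, background-subtracted to exact-zero background."""
    cfg = SimConfigA(
        image_side=side,
        density_green=density,
        density_red=density,
        coloc_fraction=coloc_fraction,
        rng_seed=seed,
    )
    noisy, truth = simulate_pixel_objects(cfg)
    bg = cfg.noise_range[1]
    pair = ImagePair(
        subtract_background(noisy.s1, bg), subtract_background(noisy.s2, bg)
    )
    return pair, truth


@pytest.fixture
def sim_pair():
    return make_sim_pair(seed=42)
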