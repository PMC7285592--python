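import numpy as np
import pytest

from suprafat import IntensitySlice, PhantomSpec, RoiMask, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_roi_slice():
    """10x10 slice with 25 bright (200) and 75 dark (50) pixels, full mask."""
    pixels = np.full((10, 10), 50.0)
    pixels.flat[:25] = 200.0
    image = IntensitySlice(pixels=pixels)
    mask = RoiMask(np.ones((10, 10), dtype=bool), "muscle")
    return image, mask


@pytest.fixture
def phantom_04():
    """Seeded streak phantom with true muscle fat fraction 0.40."""
    spec = PhantomSpec(true_fat_fraction=0.40, mu_muscle=100, mu_fat=180,
                       sigma_noise=8.0, seed=7)
    return generate_phantom(spec)
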