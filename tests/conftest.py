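import numpy as np
import pytest

from uweval import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gray_image():
    """Constant mid-gray 16x16 image."""
    return np.full((16, 16, 3), 128, dtype=np.uint8)


@pytest.fixture
def two_tone_image():
    """Fixed 16x16 two-tone pattern (checkerboard of dark teal / light sand)."""
    img = np.zeros((16, 16, 3), dtype=np.uint8)
    ii, jj = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
    mask = (ii + jj) % 2 == 0
    img[mask] = (40, 90, 110)
    img[~mask] = (200, 180, 120)
    return img


@pytest.fixture
def red_blue_checkerboard():
    img = np.zeros((16, 16, 3), dtype=np.uint8)
    ii, jj = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
    mask = (ii + jj) % 2 == 0
    img[mask] = (220, 30, 30)
    img[~mask] = (30, 30, 220)
    return img


@pytest.fixture
def metric_corpus():
    """20 deterministic synthetic images spanning degradation levels."""
    images = []
    for k in range(20):
        images.append(
            synthetic.generate_degraded_image(
                seed=1000 + k,
                width=32,
                height=24,
                cast_strength=(k % 5) / 5.0,
                haze_strength=(k % 4) / 4.0,
                noise_sigma=2.0 * (k % 3),
            )
        )
    return images


@pytest.fixture(scope="session")
def small_scenario():
    """A small but nontrivial scenario shared by detection-level tests."""
    config = synthetic.ScenarioConfig(n_images=30, n_variants=3, seed=7)
    return synthetic.generate_scenario(config)
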