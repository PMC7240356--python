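import numpy as np
import pytest

from virtualstain import gan, phantom
from virtualstain.imaging import RGBImage


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_image(rng):
    return RGBImage(rng.integers(0, 256, (64, 64, 3), dtype=np.uint8))


@pytest.fixture(scope="session")
def noise_free_palette():
    return phantom.StainPalette(noise_sd=0.0)


@pytest.fixture(scope="session")
def small_phantom():
    return phantom.generate_phantom(7, shape=(128, 128), grade="G3",
                                    n_glands_range=(3, 5))


@pytest.fixture(scope="session")
def tiny_model():
    """A briefly trained desk-scale staining model shared across tests."""
    palette = phantom.StainPalette(noise_sd=0.0)
    pairs = phantom.make_training_set(24, seed=5, shape=(64, 64), palette=palette)
    cfg = gan.TrainingConfig(direction="stain", epochs=2, batch_size=8,
                             seed=5, patch_size=64)
    return gan.train(pairs, cfg)
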