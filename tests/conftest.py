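import numpy as np
import pytest

from radnorm.image_io import GrayImage
from radnorm.phantom import default_config, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_100():
    """The canonical 100x100 uniform image used in the crop examples."""
    return GrayImage(np.full((100, 100), 50, dtype=np.uint8), "uint8")


@pytest.fixture(scope="session")
def small_phantom_manifest():
    """Noise-free three-domain phantom dataset, embedded pixels (no disk I/O)."""
    return generate_dataset(default_config(noise_sd=0.0, seed=11), 12, seed=11)


@pytest.fixture(scope="session")
def noisy_phantom_manifest():
    return generate_dataset(default_config(noise_sd=4.0, seed=23), 24, seed=23)
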