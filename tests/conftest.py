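import numpy as np
import pytest

from sczscreen.preprocess import skull_strip
from sczscreen.synthetic_data import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless control phantom: piecewise-constant head with ground truth."""
    cfg = PhantomConfig(noise_sigma=0.0, seed=7)
    img, labels = generate_phantom(cfg, "CON", 0)
    return cfg, img, labels


@pytest.fixture(scope="session")
def stripped_noiseless(noiseless_phantom):
    cfg, img, labels = noiseless_phantom
    return cfg, skull_strip(img), labels


@pytest.fixture(scope="session")
def noisy_phantom():
    cfg = PhantomConfig(noise_sigma=5.0, seed=11)
    img, labels = generate_phantom(cfg, "CON", 3)
    return cfg, img, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
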