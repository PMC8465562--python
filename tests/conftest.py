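import numpy as np
import pytest

from wlsm.io_formats import Image2D, RunConfig
from wlsm.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_image_8x8():
    rng = np.random.default_rng(7)
    return Image2D(rng.uniform(0.0, 255.0, size=(8, 8)))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, bias-free three-tissue phantom with its truth labels."""
    return make_phantom(PhantomSpec(noise_level=0.0, bias_amplitude=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_biased_phantom():
    """5% noise + order-2 bias phantom, the standard corrupted test case."""
    return make_phantom(PhantomSpec(noise_level=0.05, bias_amplitude=0.4, bias_order=2, seed=0))


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(seed=0)
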