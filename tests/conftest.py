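import numpy as np
import pytest

from nodulewalk.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def smooth_phantom():
    """Noiseless circular (benign-style) nodule."""
    return generate_phantom(PhantomSpec(noise_sigma=0.0, base_radius=18,
                                        spiculation_amplitude=0.0, rng_seed=11))


@pytest.fixture(scope="session")
def spiculated_phantom():
    """Noiseless spiculated (malignant-style) nodule, same seed as smooth."""
    return generate_phantom(PhantomSpec(noise_sigma=0.0, base_radius=18,
                                        spiculation_amplitude=0.4, rng_seed=11))


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(PhantomSpec(noise_sigma=0.1, base_radius=18,
                                        spiculation_amplitude=0.3, rng_seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
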