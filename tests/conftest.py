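import numpy as np
import pytest

from nlmstain.phantom import PhantomParams, generate_phantom_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_pair_256():
    """A clean, aligned 256×256 phantom pair with its label map."""
    params = PhantomParams(image_size=(256, 256), crypt_count=5, seed=11)
    nlm, he, labels, _ = generate_phantom_pair(params)
    return nlm, he, labels


@pytest.fixture(scope="session")
def noiseless_phantom_128():
    """Noise- and texture-free phantom: pixels are exact palette entries."""
    params = PhantomParams(
        image_size=(128, 128), crypt_count=2, crypt_radius_range=(14.0, 22.0),
        noise_sigma=0.0, texture_amplitude=0.0, seed=3,
    )
    return generate_phantom_pair(params), params
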