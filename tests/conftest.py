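import numpy as np
import pytest

from esnchaos.images import generate_naturalistic_images
from esnchaos.reservoir import ReservoirConfig, build_reservoir


@pytest.fixture(scope="session")
def natural_images():
    """Small naturalistic ensemble shared as a drive across dynamics tests."""
    return generate_naturalistic_images(20, 30, 30, seed=7)


@pytest.fixture(scope="session")
def driven_reservoir():
    """A moderately contracting reservoir matched to the 30-row images."""
    config = ReservoirConfig(
        n_units=100, spectral_radius=0.9, input_scaling=0.6, seed=3
    )
    return config, build_reservoir(config, n_inputs=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
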