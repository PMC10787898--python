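import numpy as np
import pytest

from memfluct.synthetic import MembraneSimParams, OpticsConfig


@pytest.fixture(scope="session")
def small_membrane_params():
    """Small, fast membrane simulation used by several unit tests."""
    return MembraneSimParams(domain_side=3.4656, n_modes_per_axis=48,
                             n_frames=512, seed=7)


@pytest.fixture(scope="session")
def default_optics():
    return OpticsConfig(camera_noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
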