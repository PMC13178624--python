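import numpy as np
import pytest

from sawoce import preprocess, simulate


@pytest.fixture(scope="session")
def homog_config():
    """Small noiseless homogeneous phantom at 3.2 m/s."""
    return simulate.small_config(layers=((64, 3.2),), noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def homog_volume(homog_config):
    return simulate.simulate_volume(homog_config)


@pytest.fixture(scope="session")
def homog_stack(homog_volume):
    surf = preprocess.detect_surface(homog_volume)
    flat = preprocess.flatten_volume(homog_volume, surf)
    return preprocess.extract_phase_stack(flat, 40)


@pytest.fixture(scope="session")
def layered_config():
    """Two-layer phantom: stiff 5.5 m/s on top of soft 3.1 m/s, step at index 20."""
    return simulate.small_config(layers=((20, 5.5), (44, 3.1)), noise_sigma=0.0, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
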