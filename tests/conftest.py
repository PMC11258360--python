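import numpy as np
import pytest

from smtkit import SimulationConfig, simulate_fov


@pytest.fixture(scope="session")
def small_fov():
    """One small rendered field of view with ground truth, shared
    read-only across tests."""
    config = SimulationConfig(
        n_frames=30,
        image_shape=(192, 192),
        n_nuclei=3,
        seed=5,
        bleach_survival=1.0,
    )
    return simulate_fov(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
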