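import dataclasses

import numpy as np
import pytest

from voltpipe.simulate import SimConfig, simulate_fov


def small_config(**overrides) -> SimConfig:
    """A fast-to-render configuration for unit tests (not a study preset)."""
    base = dict(
        n_neurons=3,
        fov_shape=(48, 64),
        frame_rate=500.0,
        duration=20.0,
        firing_rate=1.5,
        ap_fwhm=14.8,
        soma_radius_px=(3.0, 4.5),
        plateau_rate=0.0,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One small rendered movie + ground truth, shared across tests."""
    cfg = small_config(seed=42)
    movie, gt = simulate_fov(cfg)
    return cfg, movie, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
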