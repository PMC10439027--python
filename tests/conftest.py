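import dataclasses

import numpy as np
import pytest

from pinkstim import generate_pink_noise
from pinkstim.protocol import SessionConfig


@pytest.fixture(scope="session")
def pink_256():
    """A medium pink-noise field shared across read-only spectral tests."""
    return generate_pink_noise(256, 256, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_exp1a_config(**overrides) -> SessionConfig:
    """Full eccentricity-design geometry at a coarse pixel scale for speed."""
    base = dict(
        ppd=4.0,
        field_shape="circular",
        field_radius_deg=14.32,
        field_ramp_deg=2.39,
        window_r_deg=1.75,
        window_w_deg=0.875,
        sigmas=(30.0, 40.0, 50.0, 60.0, 70.0),
        trials_per_cell=1,
        master_seed=101,
        eccentricities=(0.0, 3.5, 7.0, 10.5),
    )
    base.update(overrides)
    return SessionConfig(**base)


@pytest.fixture()
def exp1a_small():
    return small_exp1a_config()
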