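"""Shared fixtures: small simulated datasets reused across test modules.

Unit tests run on reduced apertures (16–32 elements) to stay fast; the
acceptance tests use the full 128-element, 1 mm-pitch configuration.
"""

import numpy as np
import pytest

from flexbeam import Pulse, make_geometry, point_targets, simulate_rf

SOUND_SPEED = 1540.0


@pytest.fixture(scope="session")
def pulse():
    return Pulse()  # 5 MHz, 60% bandwidth, fs = 40 MHz


@pytest.fixture(scope="session")
def flat32():
    return make_geometry("flat", 32, 1.0)


@pytest.fixture(scope="session")
def marker17():
    """Single hyperechoic marker at the assistant-structure depth."""
    return point_targets([(0.0, 17.0)])


@pytest.fixture(scope="session")
def rf_marker32(flat32, marker17, pulse):
    """Noise-free RF data: 32-element flat array, marker at (0, 17) mm."""
    return simulate_rf(marker17, flat32, pulse)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
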