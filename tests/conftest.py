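from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ramanev.spectral import make_axis
from ramanev.synth import make_uptake_phantom_spec, simulate_cell_cube

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def full_axis():
    """Full instrument grid: 0-3700 cm-1 at 11 cm-1."""
    return make_axis(0.0, 3700.0, 11.0)


@pytest.fixture(scope="session")
def cropped_axis():
    return make_axis(400.0, 3600.0, 11.0)


@pytest.fixture(scope="session")
def clean_phantom(full_axis):
    """Noise-free internalised-cohort phantom with ground truth."""
    spec = replace(make_uptake_phantom_spec("internalised", seed=3), noise_sd=0.0)
    return simulate_cell_cube(spec, full_axis, seed=3)


@pytest.fixture(scope="session")
def noisy_phantom(full_axis):
    spec = make_uptake_phantom_spec("internalised", seed=3, noise_sd=0.1)
    return simulate_cell_cube(spec, full_axis, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
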