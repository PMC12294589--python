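import math

import numpy as np
import pytest
from hypothesis import settings

from fklpi import (
    FKProfile,
    MCMCOptions,
    ThermalSystem,
    make_model_potential,
    sample_centroid_ensemble,
    sample_fluctuation_cloud,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def harmonic_model():
    return make_model_potential("harmonic", {"mass": 1.0, "omega": 1.0})


@pytest.fixture(scope="session")
def harmonic_system():
    return ThermalSystem(beta=2.0, masses=[1.0])


@pytest.fixture(scope="session")
def harmonic_profile(harmonic_model, harmonic_system):
    return FKProfile(harmonic_model, harmonic_system, -7.0, 7.0, n_points=101)


@pytest.fixture(scope="session")
def harmonic_ensemble(harmonic_model, harmonic_system, harmonic_profile):
    """10^4 centroids x 10 planets of the unit harmonic oscillator at beta=2."""
    ens = sample_centroid_ensemble(
        harmonic_model, harmonic_system, 10_000, MCMCOptions(), 101,
        profile=harmonic_profile)
    planets = sample_fluctuation_cloud(ens, 10, 202)
    return ens, planets


@pytest.fixture(scope="session")
def double_well_model():
    # the standard low-temperature double-well benchmark V = -x^2/2 + x^4/4
    return make_model_potential("double_well", {"a": 1.0, "b": 1.0})


@pytest.fixture(scope="session")
def double_well_system():
    return ThermalSystem(beta=8.0, masses=[1.0])


@pytest.fixture(scope="session")
def morse_model():
    return make_model_potential("morse", {"D": 1.0, "a": 1.0})


def three_sigma(value, target, stderr, floor=1e-12):
    return abs(value - target) <= 3.0 * max(stderr, floor)


def exact_x2(beta, omega=1.0, mass=1.0, hbar=1.0):
    return hbar / (2 * mass * omega) / math.tanh(0.5 * beta * hbar * omega)
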