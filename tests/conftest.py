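import numpy as np
import pytest

from adaptivepull import (
    IdentityCoordinate,
    LangevinParams,
    PotentialSpec,
    SteeringProtocol,
    SystemState,
    System,
    generate_helix_fixture,
    make_potential,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def harmonic():
    return make_potential(PotentialSpec("harmonic", {"a": 1.0}))


@pytest.fixture
def double_well():
    return make_potential(PotentialSpec("double_well", {"h": 1.5, "w": 1.0}))


@pytest.fixture
def tilted_double_well():
    return make_potential(PotentialSpec("tilted_double_well", {"h": 1.5, "w": 1.0, "c": 0.3}))


@pytest.fixture
def helix10():
    return generate_helix_fixture(10)


@pytest.fixture
def extended10():
    return generate_helix_fixture(10, 180.0, 180.0)


def make_1d_system(potential, x0=0.0):
    return System(potential, SystemState(np.array([x0]), np.array([0.0])))


def make_steering(k=1.0, lam_start=0.0, lam_end=2.0, velocity=100.0, mode="pull"):
    return SteeringProtocol(IdentityCoordinate(), k, lam_start, lam_end, velocity, mode)


def make_params(T=300.0, gamma=2.0, dt=0.01, m=1.0):
    return LangevinParams(T, gamma, dt, m)
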