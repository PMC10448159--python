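import dataclasses

import numpy as np
import pytest

import triphase as tp


@pytest.fixture(scope="session")
def boreal():
    return tp.boreal_reference_spec()


@pytest.fixture(scope="session")
def boreal_params(boreal):
    return tp.derive_chain_params(boreal)


@pytest.fixture(scope="session")
def small_spec(boreal):
    """A desk-scale world: same superpopulation, small datasets."""
    return dataclasses.replace(boreal, n_I=30, n_II=50, n_III=80, n_IV=100, N=500)


@pytest.fixture(scope="session")
def small_world(small_spec):
    params = tp.derive_chain_params(small_spec)
    designs = tp.generate_designs(small_spec, 7)
    return small_spec, params, designs


def make_random_spec(rng: np.random.Generator) -> tp.SuperpopulationSpec:
    """A random valid superpopulation for property tests."""
    mu = rng.uniform(-20.0, 80.0, size=4)
    sd = rng.uniform(0.5, 30.0, size=4)
    r = rng.uniform(-0.95, 0.95, size=3)
    n1, n2, n3 = rng.integers(10, 60, size=3)
    N = int(rng.integers(50, 200))
    n4 = int(rng.integers(5, N + 1))
    return tp.SuperpopulationSpec(
        mu_Y=mu[0], mu_X=mu[1], mu_Z=mu[2], mu_P=mu[3],
        sd_Y=sd[0], sd_X=sd[1], sd_Z=sd[2], sd_P=sd[3],
        r_YX=r[0], r_XZ=r[1], r_ZP=r[2],
        n_I=int(n1), n_II=int(n2), n_III=int(n3), n_IV=n4, N=N,
    )


def zero_noise(params: tp.DerivedModelParams) -> tp.DerivedModelParams:
    """The same chain coefficients with all error variances set to zero."""
    z = np.zeros((2, 2))
    return dataclasses.replace(
        params, omega2=0.0, Delta_star=z, delta2=0.0, Theta_star=z, theta2=0.0
    )
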