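"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nashseg import PhantomSpec, add_noise, make_phantom
from nashseg.model_core import SolverParams


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_phase_phantom():
    """(clean, noisy, gt) 64x64 two-phase piecewise-smooth fixture, sigma=25."""
    spec = PhantomSpec(
        shape=(64, 64),
        n_phases=2,
        intensity_levels=(90.0, 150.0),
        gradient_amplitude=10.0,
        contrast_gap=30.0,
        seed=3,
    )
    clean, gt = make_phantom(spec)
    noisy = add_noise(clean, 25.0, seed=4)
    return clean, noisy, gt


@pytest.fixture(scope="session")
def tuned_params() -> SolverParams:
    """Parameters tuned for sigma=25 noise on the 8-bit scale."""
    return SolverParams(
        lambda1=0.05,
        mu1=0.01,
        xi1=0.1,
        rho1=0.1,
        lambda2=0.1,
        mu2=0.1,
        xi2=0.5,
        rho2=1.0,
        max_outer=500,
        tol=1e-5,
    )
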