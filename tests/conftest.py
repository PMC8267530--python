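import numpy as np
import pytest

from fracno import (
    AnomalousDiffusionParams,
    Geometry,
    InactivationParams,
    ModelSpec,
    SynthesisParams,
    WallParams,
)


@pytest.fixture
def geometry():
    """Arteriole geometry from the canonical parameter table (meters)."""
    return Geometry(a=25e-6, h=0.5e-6, d=4e-6, g=5e-6)


@pytest.fixture
def wall():
    """Normal-condition Maxwell wall parameters."""
    return WallParams(rho=1.0, E=6e3, gamma=0.75, omega=1.0, xi0=1e-3)


@pytest.fixture
def synthesis():
    return SynthesisParams(v1=1.6e-3, k1=2.0, k2=1.5)


@pytest.fixture
def inactivation():
    return InactivationParams(
        vmax=2e-3, Kmax=1e-5, lam=2.3e2, k_superoxide=6.7e9, c_superoxide=1.95e-6
    )


@pytest.fixture
def default_model(geometry, wall, synthesis, inactivation):
    """Baseline anomalous-diffusion model: epsilon = 0.85, forward-dominant."""
    return ModelSpec(
        geometry=geometry,
        n_intervals=300,
        diffusion=AnomalousDiffusionParams(D=3.3e-9, epsilon=0.85, p=0.75, q=0.25),
        synthesis=synthesis,
        inactivation=inactivation,
        wall=wall,
    )


@pytest.fixture
def small_model(geometry, wall, synthesis, inactivation):
    """Coarse-grid variant for fast structural tests."""
    return ModelSpec(
        geometry=geometry,
        n_intervals=20,
        diffusion=AnomalousDiffusionParams(D=3.3e-9, epsilon=0.85, p=0.75, q=0.25),
        synthesis=synthesis,
        inactivation=inactivation,
        wall=wall,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
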