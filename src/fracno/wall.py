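"""Maxwell viscoelastic endothelium: shear-driven NO production factor.

The endothelium is a thin homogeneous Maxwell (spring-dashpot-in-series)
layer driven at its inner face ``r = a`` by the oscillatory axial
displacement of the blood, ``xi0 * exp(i omega t)``, and tethered at the
outer face ``r = a + h``.  The axial displacement solves a damped wave
equation whose complex wavenumber ``alpha + i beta`` follows from the
loss factor ``gamma = omega mu / E``.  The normalized viscous dissipation
at the blood-endothelium interface — the real part of a closed-form
complex expression — multiplies the local NO concentration as a
mechanotransduction production rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry

__all__ = ["WallParams", "DispersionPair", "dispersion", "dissipation_factor", "axial_displacement"]


@dataclass(frozen=True)
class WallParams:
    """Constants of the oscillating Maxwell wall.

    Attributes
    ----------
    rho : float
        Wall mass density (kg/m^3, as tabulated).
    E : float
        Elastic modulus (N/m, as tabulated).
    gamma : float
        Loss factor omega*mu/E (dimensionless).
    omega : float
        Angular frequency of the imposed oscillation (1/s).
    xi0 : float
        Displacement amplitude at the blood-endothelium interface (m).
    """

    rho: float
    E: float
    gamma: float
    omega: float
    xi0: float

    def __post_init__(self) -> None:
        for name in ("rho", "E", "gamma", "omega", "xi0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"wall parameter {name!r} must be strictly positive, got {v}")

    @property
    def mu(self) -> float:
        """Wall viscosity mu = gamma * E / omega."""
        return self.gamma * self.E / self.omega


@dataclass(frozen=True)
class DispersionPair:
    """Attenuation (alpha) and wavenumber (beta) of the wall displacement.

    beta >= alpha always, since the radical sqrt(1 + 1/gamma^2) exceeds 1.
    """

    alpha: float
    beta: float


def dispersion(wall: WallParams) -> DispersionPair:
    """Spatial attenuation and wavenumber of the Maxwell-wall solution.

    alpha^2 = rho omega^2 / (2E) (sqrt(1 + 1/gamma^2) - 1),
    beta^2  = rho omega^2 / (2E) (sqrt(1 + 1/gamma^2) + 1).
    """
    radical = np.sqrt(1.0 + 1.0 / wall.gamma**2)
    scale = wall.rho * wall.omega**2 / (2.0 * wall.E)
    return DispersionPair(
        alpha=float(np.sqrt(scale * (radical - 1.0))),
        beta=float(np.sqrt(scale * (radical + 1.0))),
    )


def _dissipation_amplitude(
    r: np.ndarray, wall: WallParams, geometry: Geometry, formula: str = "printed"
) -> np.ndarray:
    """Complex amplitude of the dissipation factor (everything but exp(i omega t)).

    ``formula="printed"`` evaluates the closed-form expression as published;
    ``formula="derived"`` evaluates (sigma/tau_W) d(eps_rx)/dt directly from
    the analytic displacement solution xi = xi0 sinh(k(a+h-r))/sinh(kh),
    k = alpha + i beta.  The two differ because the published denominator
    keeps only the alpha^2 part of k^2, which inflates the amplitude by
    the factor (alpha^2 + beta^2)/alpha^2 and introduces a spurious
    loss-factor dependence; see the package methods note.
    """
    disp = dispersion(wall)
    a, b = disp.alpha, disp.beta
    aa, h = geometry.a, geometry.h
    if formula == "printed":
        depth = h - (r - aa)  # distance from the tethered outer face
        bracket = np.exp(2.0 * a * depth) + np.exp(-2.0 * a * depth) + 2.0
        # (a-ib)e^{2ah} - (a+ib)e^{-2ah} + 2ib, rewritten cancellation-free:
        denom = 2.0 * a * np.sinh(2.0 * a * h) - 4j * b * np.sinh(a * h) ** 2
        phase = np.exp(-2j * b * (r - aa))
        return -1j * wall.xi0 * wall.omega * (a**2 + b**2) * bracket / denom * phase
    if formula == "derived":
        # (sigma(r)/sigma(a)) * d(eps)/dt = i omega eps(r)^2 / eps(a) with
        # eps(r) = d xi/d r = -xi0 k cosh(k(a+h-r))/sinh(kh)
        k = a + 1j * b
        num = np.cosh(k * (aa + h - r)) ** 2
        return -1j * wall.xi0 * wall.omega * k * num / (np.sinh(k * h) * np.cosh(k * h))
    raise ValueError(f"unknown wall formula {formula!r}; use 'printed' or 'derived'")


def dissipation_factor(r, t, wall: WallParams, geometry: Geometry, formula: str = "printed"):
    """Real part of the normalized viscous-dissipation expression.

    Parameters
    ----------
    r : float or array
        Radial position(s), must lie inside the endothelium [a, a+h].
    t : float or array
        Time (s).  r and t broadcast against each other.

    Returns
    -------
    float or ndarray
        Production-rate factor (1/s scale); oscillates in sign with the
        phase omega*t - 2*beta*(r - a).
    """
    r = np.asarray(r, dtype=float)
    tol = 1e-12 * geometry.total_radius
    if np.any(r < geometry.a - tol) or np.any(r > geometry.a + geometry.h + tol):
        raise ValueError("r outside the endothelium [a, a+h]")
    amp = _dissipation_amplitude(r, wall, geometry, formula=formula)
    value = np.real(amp * np.exp(1j * wall.omega * np.asarray(t, dtype=float)))
    return value if value.ndim else float(value)


def axial_displacement(r, t, wall: WallParams, geometry: Geometry):
    """Complex axial displacement xi(r, t) of the endothelium.

    xi = xi0 sinh(k (a + h - r)) / sinh(k h) * exp(i omega t) with the
    complex wavenumber k = alpha + i beta.  Satisfies the driven inner
    boundary |xi(a, t)| = xi0 and the tethered outer boundary
    xi(a+h, t) = 0; exposed for verification of the derivation.
    """
    disp = dispersion(wall)
    k = disp.alpha + 1j * disp.beta
    r = np.asarray(r, dtype=float)
    return (
        wall.xi0
        * np.sinh(k * (geometry.a + geometry.h - r))
        / np.sinh(k * geometry.h)
        * np.exp(1j * wall.omega * np.asarray(t, dtype=float))
    )
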