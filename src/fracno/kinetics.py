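"""Non-diffusive production and decay terms of the NO balance law.

Four processes besides diffusion move NO mass in the model:

* neuronal synthesis — a transient pulse ``v1 (1 - exp(-k1 t)) exp(-k2 t)``
  matching Ca2+-calmodulin binding kinetics, active in the neuronal layer;
* saturable (Michaelis-Menten) inactivation outside the endothelium;
* hemoglobin scavenging — first-order loss at rate ``lam`` in the lumen;
* reaction with superoxide — first-order loss at rate ``lam_tilde`` in the
  extracellular region, with ``lam_tilde = k_superoxide * c_superoxide *
  sod_fraction`` (only the superoxide fraction escaping superoxide
  dismutase reacts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynthesisParams",
    "InactivationParams",
    "neuronal_production",
    "mm_inactivation",
    "superoxide_decay_rate",
    "linear_decay",
]


@dataclass(frozen=True)
class SynthesisParams:
    """Neuronal NO synthesis pulse parameters.

    v1 : peak-scale production rate, mol/(m^3 s)
    k1 : rise rate constant, 1/s
    k2 : decay rate constant, 1/s
    k2_sign_positive : audit switch restoring a growing exp(+k2 t) factor
        in place of the default decaying exp(-k2 t) envelope
    """

    v1: float
    k1: float
    k2: float
    k2_sign_positive: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.v1) or self.v1 < 0:
            # v1 = 0 is allowed: it switches the synthesis pulse off entirely
            raise ValueError(f"synthesis parameter 'v1' must be non-negative, got {self.v1}")
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"synthesis parameter {name!r} must be strictly positive, got {v}")

    @property
    def peak_time(self) -> float:
        """Time of the production maximum, (1/k1) ln(1 + k1/k2)."""
        return np.log1p(self.k1 / self.k2) / self.k1


def neuronal_production(t, params: SynthesisParams):
    """Neuronal synthesis rate v1 (1 - exp(-k1 t)) exp(-k2 t), mol/(m^3 s).

    Rises on the 1/k1 scale, decays on the 1/k2 scale; bounded by v1.
    With ``k2_sign_positive`` the decaying envelope is replaced by a
    growing one (diagnostic use only).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    sign = 1.0 if params.k2_sign_positive else -1.0
    out = params.v1 * -np.expm1(-params.k1 * t) * np.exp(sign * params.k2 * t)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class InactivationParams:
    """Rates of the three NO removal pathways.

    vmax, Kmax : Michaelis-Menten inactivation (mol/(m^3 s), mol/m^3)
    lam : hemoglobin scavenging rate in the lumen (1/s)
    k_superoxide : NO + superoxide bimolecular rate constant (1/(M s))
    c_superoxide : extracellular superoxide concentration (M)
    sod_fraction : fraction of superoxide left after SOD scavenging
    lambda_tilde_override : optional direct value for lam_tilde (1/s);
        checked for consistency with the derived product at construction
    """

    vmax: float
    Kmax: float
    lam: float
    k_superoxide: float
    c_superoxide: float
    sod_fraction: float = 0.5
    lambda_tilde_override: float | None = None

    def __post_init__(self) -> None:
        for name in ("vmax", "Kmax", "lam", "k_superoxide", "c_superoxide"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"inactivation parameter {name!r} must be strictly positive, got {v}"
                )
        if not 0 < self.sod_fraction <= 1:
            raise ValueError(f"sod_fraction must lie in (0, 1], got {self.sod_fraction}")
        if self.lambda_tilde_override is not None:
            derived = superoxide_decay_rate(
                self.k_superoxide, self.c_superoxide, self.sod_fraction
            )
            if abs(self.lambda_tilde_override - derived) > 1e-6 * derived:
                warnings.warn(
                    f"lambda_tilde override {self.lambda_tilde_override} differs from the "
                    f"value {derived} derived from (k_superoxide, c_superoxide, "
                    f"sod_fraction); the override takes precedence",
                    stacklevel=2,
                )

    @property
    def lam_tilde(self) -> float:
        """Superoxide-mediated NO removal rate (1/s)."""
        if self.lambda_tilde_override is not None:
            return self.lambda_tilde_override
        return superoxide_decay_rate(self.k_superoxide, self.c_superoxide, self.sod_fraction)


def superoxide_decay_rate(k_superoxide: float, c_superoxide: float, sod_fraction: float) -> float:
    """First-order NO loss rate to superoxide, k * C * f (1/s).

    ``sod_fraction`` is the fraction of the superoxide pool that escapes
    dismutation and remains available to react with NO.
    """
    if k_superoxide <= 0 or c_superoxide <= 0:
        raise ValueError("rate constant and concentration must be positive")
    if not 0 < sod_fraction <= 1:
        raise ValueError(f"sod_fraction must lie in (0, 1], got {sod_fraction}")
    return k_superoxide * c_superoxide * sod_fraction


def mm_inactivation(c, vmax: float, Kmax: float):
    """Saturable inactivation rate vmax c / (Kmax + c), mol/(m^3 s).

    Monotone and concave in c; half-maximal at c = Kmax.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = vmax * c / (Kmax + c)
    return out if out.ndim else float(out)


def linear_decay(c, rate: float):
    """First-order loss rate * c; used for both hemoglobin and superoxide."""
    c = np.asarray(c, dtype=float)
    out = rate * c
    return out if out.ndim else float(out)
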