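"""Independent classical (non-fractional) reference implementation.

Used as the cross-check for the classical-limit equivalence test: the
same vessel-tissue reaction-diffusion model discretized with ordinary
three-point stencils assembled from scratch (no imports from the package
under test), the wall factor evaluated with stdlib complex arithmetic,
and the stiff integration driven independently.
"""

from __future__ import annotations

import cmath

import numpy as np
from scipy.integrate import solve_ivp

# canonical parameter table
A, H, D_LAYER, G = 25e-6, 0.5e-6, 4e-6, 5e-6
D_NO = 3.3e-9
V1, K1, K2 = 1.6e-3, 2.0, 1.5
VMAX, KMAX, LAM = 2e-3, 1e-5, 2.3e2
LAM_TILDE = 6.7e9 * 1.95e-6 * 0.5
RHO, E_MOD, GAMMA, OMEGA, XI0 = 1.0, 6e3, 0.75, 1.0, 1e-3


def classical_reference(n_intervals=300, t_final=10.04, n_outputs=401, rtol=1e-6, atol=1e-12):
    """Integrate the classical (Fickian) model; returns (times, nodes, field)."""
    R = A + H + D_LAYER + G
    r = np.linspace(0.0, R, n_intervals + 1)
    dr = R / n_intervals
    ri = r[1:-1]
    m = n_intervals - 1

    lumen = ri < A
    endo = (ri >= A) & (ri < A + H)
    extra = (ri >= A + H) & (ri < A + H + D_LAYER)
    neuro = ri >= A + H + D_LAYER
    inact = ri >= A + H

    radical = (1.0 + 1.0 / GAMMA**2) ** 0.5
    alpha = (RHO * OMEGA**2 / (2 * E_MOD) * (radical - 1.0)) ** 0.5
    beta = (RHO * OMEGA**2 / (2 * E_MOD) * (radical + 1.0)) ** 0.5
    k = complex(alpha, beta)
    wall_amp = np.array(
        [
            -1j * XI0 * OMEGA * k * cmath.cosh(k * (A + H - x)) ** 2
            / (cmath.sinh(k * H) * cmath.cosh(k * H))
            if e
            else 0j
            for x, e in zip(ri, endo)
        ]
    )

    L = np.zeros((m, m))
    for i in range(m):
        L[i, i] = -2.0 * D_NO / dr**2
        if i > 0:
            L[i, i - 1] = D_NO / dr**2 - D_NO / (2.0 * dr * ri[i])
        if i < m - 1:
            L[i, i + 1] = D_NO / dr**2 + D_NO / (2.0 * dr * ri[i])

    def rhs(t, c):
        cc = np.maximum(c, 0.0)
        w = (wall_amp * cmath.exp(1j * OMEGA * t)).real
        out = L @ c
        out += V1 * (1.0 - np.exp(-K1 * t)) * np.exp(-K2 * t) * neuro
        out -= VMAX * cc / (KMAX + cc) * inact
        out += w * cc
        out -= LAM * cc * lumen
        out -= LAM_TILDE * cc * extra
        return out

    def jac(t, c):
        cc = np.maximum(c, 0.0)
        w = (wall_amp * cmath.exp(1j * OMEGA * t)).real
        return L + np.diag(
            -VMAX * KMAX / (KMAX + cc) ** 2 * inact + w - LAM * lumen - LAM_TILDE * extra
        )

    t_eval = np.linspace(0.0, t_final, n_outputs)
    sol = solve_ivp(
        rhs,
        (0.0, t_final),
        np.zeros(m),
        method="BDF",
        t_eval=t_eval,
        jac=jac,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(sol.message)
    field = np.zeros((n_intervals + 1, n_outputs))
    field[1:-1, :] = np.maximum(sol.y, 0.0)
    return t_eval, r, field
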