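"""Grünwald-Letnikov discretization of the two-sided fractional flux divergence.

Anomalous (Lévy-flight) diffusion of NO is modeled with left- and
right-sided Riemann-Liouville derivatives of order ``epsilon`` in (0, 1],
weighted by forward/backward jump probabilities ``p + q = 1``.  On an
equispaced grid the derivatives are realized by Grünwald-Letnikov (GL)
sums: the unshifted formulas for the order-``epsilon`` part and the
shifted formulas for the order-``epsilon + 1`` part (the shift is what
makes the scheme stable for orders in (1, 2]).

Both sums are linear in the nodal concentrations, so the whole cylindrical
flux divergence collapses to a single dense (N-1) x (N-1) matrix acting on
the interior nodes, precomputed once per (grid, parameters) and reused at
every time step.  Homogeneous Dirichlet values at both ends make the
boundary columns vanish exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, rgamma

from .geometry import RadialGrid

__all__ = [
    "GLWeights",
    "AnomalousDiffusionParams",
    "FluxDivergenceOperator",
    "gl_weights",
    "assemble_first_order_matrix",
    "assemble_second_order_matrix",
    "flux_divergence_operator",
    "rl_left_power",
    "gl_left_apply",
]


@dataclass(frozen=True)
class GLWeights:
    """Generalized binomial weights g_j = (-1)^j C(order, j).

    ``values[j]`` multiplies the sample j nodes away in the GL sum.
    g_0 = 1, g_1 = -order, and for integer order the weights terminate.
    """

    order: float
    values: np.ndarray


def gl_weights(order: float, count: int) -> GLWeights:
    """Compute GL weights g_0 .. g_count for a fractional order in (0, 2].

    Uses the multiplicative recurrence g_j = g_{j-1} * (1 - (order+1)/j),
    which is exact in the reals and avoids the overflow of raw gamma
    ratios at large j.
    """
    if not 0 < order <= 2:
        raise ValueError(f"fractional order must lie in (0, 2], got {order}")
    if count < 1:
        raise ValueError(f"need at least one weight beyond g_0, got count={count}")
    g = np.empty(count + 1)
    g[0] = 1.0
    for j in range(1, count + 1):
        g[j] = g[j - 1] * (1.0 - (order + 1.0) / j)
    return GLWeights(order=order, values=g)


def gl_weight_gammaln(order: float, j: int) -> float:
    """Single GL weight via log-gamma, (-1)^j Γ(order+1)/(Γ(j+1)Γ(order-j+1)).

    Cross-check route for :func:`gl_weights`; uses the reflection-free
    identity through ``rgamma`` so integer orders (where Γ(order-j+1)
    has poles) come out as exact zeros.
    """
    if j == 0:
        return 1.0
    # Γ(order+1)/Γ(order-j+1) = order*(order-1)*...*(order-j+1)
    falling = np.prod(order - np.arange(j))
    return (-1.0) ** j * falling * float(np.exp(-gammaln(j + 1.0)))


@dataclass(frozen=True)
class AnomalousDiffusionParams:
    """Generalized diffusion coefficient and Lévy-flight skewness.

    Attributes
    ----------
    D : float
        Generalized diffusion coefficient, m^(epsilon+1)/s.
    epsilon : float
        Fractional order in (0, 1]; classical diffusion at epsilon = 1.
    p, q : float
        Forward/backward jump probabilities, p + q = 1.
    """

    D: float
    epsilon: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diffusion coefficient must be positive, got {self.D}")
        if not 0 < self.epsilon <= 1:
            raise ValueError(f"epsilon must lie in (0, 1], got {self.epsilon}")
        if self.p < 0 or self.q < 0 or abs(self.p + self.q - 1.0) > 1e-12:
            raise ValueError(
                f"p, q must be non-negative with p + q = 1, got p={self.p}, q={self.q}"
            )


def assemble_first_order_matrix(epsilon: float, n_nodes: int) -> np.ndarray:
    """Matrix A with A[j, k] = g_{k-j}^epsilon for j <= k, else 0.

    Indices run over the interior nodes 1..N-1, so A is (N-1) x (N-1).
    Summing over the first index, sum_j A[j, k] C_j, reproduces the
    unshifted left GL sum at node k with the boundary value at r_0
    dropped (it is zero by the Dirichlet condition); the transposed sum
    gives the right-sided derivative.
    """
    if not 0 < epsilon <= 1:
        raise ValueError(f"epsilon must lie in (0, 1], got {epsilon}")
    if n_nodes < 4:
        raise ValueError(f"need at least 4 intervals, got N={n_nodes}")
    m = n_nodes - 1
    g = gl_weights(epsilon, m).values
    A = np.zeros((m, m))
    for j in range(m):
        for k in range(j, m):
            A[j, k] = g[k - j]
    return A


def assemble_second_order_matrix(epsilon: float, n_nodes: int) -> np.ndarray:
    """Matrix B with B[j, k] = g_{k-j+1}^(epsilon+1) for j <= k+1, else 0.

    Realizes the shifted GL formulas of order epsilon + 1 on the interior
    nodes; the single super-diagonal (j = k+1) carries g_0 = 1.  Boundary
    node contributions vanish under the zero Dirichlet condition.
    """
    if not 0 < epsilon <= 1:
        raise ValueError(f"epsilon must lie in (0, 1], got {epsilon}")
    if n_nodes < 4:
        raise ValueError(f"need at least 4 intervals, got N={n_nodes}")
    m = n_nodes - 1
    g = gl_weights(epsilon + 1.0, m + 1).values
    B = np.zeros((m, m))
    for j in range(m):
        for k in range(max(j - 1, 0), m):
            B[j, k] = g[k - j + 1]
    return B


@dataclass(frozen=True)
class FluxDivergenceOperator:
    """Dense linear operator returning -(1/r) d/dr (r F) on interior nodes.

    Applying :attr:`matrix` to the interior concentration vector yields
    the diffusive term that *adds* mass in the balance law, i.e. the
    negative cylindrical divergence of the fractional Fick flux.
    """

    matrix: np.ndarray
    grid: RadialGrid
    params: AnomalousDiffusionParams

    def __call__(self, c_interior: np.ndarray) -> np.ndarray:
        return self.matrix @ c_interior


def flux_divergence_operator(
    grid: RadialGrid, params: AnomalousDiffusionParams
) -> FluxDivergenceOperator:
    """Assemble the skewed two-sided fractional flux-divergence operator.

    Per interior node k the operator applies, to the interior vector C,

        M = D [ (q B^T + p B) / dr^(eps+1)
                + diag(1/r) (q A^T - p A) / dr^eps ]

    Direction convention: ``p`` weights the component whose heavy-tailed
    jumps point toward the vessel axis (decreasing r, the forward
    direction of NO signalling from the neuronal source to the blood),
    realized by the right-sided GL sums; ``q`` weights the outward
    component (left-sided sums).  At epsilon = 1 this reduces exactly to
    the classical stencils: a forward first difference for p = 1, a
    backward one for q = 1, and for p = q = 1/2 the central-difference
    discretization of D (C'' + C'/r), entry by entry.
    """
    eps = params.epsilon
    n = grid.N
    r_int = grid.interior
    if np.any(r_int <= 0):
        raise ValueError("interior nodes must have r > 0 (r = 0 belongs to the boundary)")
    A = assemble_first_order_matrix(eps, n)
    B = assemble_second_order_matrix(eps, n)
    dr = grid.dr
    inv_r = 1.0 / r_int
    M = params.D * (
        (params.q * B.T + params.p * B) / dr ** (eps + 1.0)
        + inv_r[:, None] * (params.q * A.T - params.p * A) / dr**eps
    )
    return FluxDivergenceOperator(matrix=M, grid=grid, params=params)


def gl_left_apply(epsilon: float, values: np.ndarray, dr: float) -> np.ndarray:
    """Unshifted left GL derivative of order epsilon at every node.

    ``values[k]`` are samples at nodes L + k*dr; the returned array holds
    dr^-eps * sum_{j=0}^{k} g_j values[k-j].  Used as the discrete side of
    the closed-form convergence checks.
    """
    n = len(values) - 1
    g = gl_weights(epsilon, n).values
    out = np.array([g[: k + 1] @ values[k::-1] for k in range(n + 1)])
    return out / dr**epsilon


def rl_left_power(mu: float, epsilon: float, x: float, L: float = 0.0) -> float:
    """Exact left Riemann-Liouville derivative of (r - L)^mu at r = x.

    Closed form Γ(mu+1)/Γ(mu+1-eps) (x-L)^(mu-eps), valid for mu >= 0.
    Serves as the independent oracle for the GL discretization.
    """
    if mu < 0:
        raise ValueError(f"power mu must be non-negative, got {mu}")
    if not x > L:
        raise ValueError(f"need x > L, got x={x}, L={L}")
    s = mu + 1.0 - epsilon
    if s <= 0 and s == round(s):
        raise ValueError(f"mu + 1 - epsilon = {s} is a non-positive integer (gamma pole)")
    return float(np.exp(gammaln(mu + 1.0)) * rgamma(s) * (x - L) ** (mu - epsilon))
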