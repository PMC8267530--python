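import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracno import (
    AnomalousDiffusionParams,
    Geometry,
    assemble_first_order_matrix,
    assemble_second_order_matrix,
    build_grid,
    flux_divergence_operator,
    gl_left_apply,
    gl_weights,
    rl_left_power,
)
from fracno.fractional import gl_weight_gammaln

mpmath.mp.dps = 40


def mp_gl_weight(order, j):
    """(-1)^j Gamma(order+1)/(Gamma(j+1) Gamma(order-j+1)) at 40 digits."""
    return float((-1) ** j * mpmath.binomial(order, j))


class TestGLWeights:
    @pytest.mark.parametrize(
        "order,expected",
        [
            (1.0, [1.0, -1.0, 0.0, 0.0, 0.0]),
            (2.0, [1.0, -2.0, 1.0, 0.0, 0.0]),
        ],
    )
    def test_integer_orders_terminate(self, order, expected):
        np.testing.assert_allclose(gl_weights(order, 4).values, expected, atol=1e-15)

    def test_half_order_values(self):
        g = gl_weights(0.5, 2).values
        assert g[1] == pytest.approx(-0.5, abs=1e-15)
        assert g[2] == pytest.approx(-0.125, abs=1e-15)

    @pytest.mark.parametrize("order", [0.3, 0.85, 1.5])
    def test_recurrence_matches_gamma_ratio(self, order):
        """Multiplicative recurrence agrees with the log-gamma route and mpmath."""
        g = gl_weights(order, 60).values
        for j in (0, 1, 5, 20, 60):
            assert g[j] == pytest.approx(gl_weight_gammaln(order, j), rel=1e-12, abs=1e-300)
            assert g[j] == pytest.approx(mp_gl_weight(order, j), rel=1e-12, abs=1e-300)

    @settings(deadline=None, derandomize=True)
    @given(order=st.floats(min_value=0.05, max_value=1.95))
    def test_telescoping_partial_sums(self, order):
        """Partial sums of GL weights shrink in magnitude toward zero."""
        g = gl_weights(order, 400).values
        partial = np.cumsum(g)
        tail = np.abs(partial[50:])
        assert np.all(np.diff(tail) <= 1e-15)
        assert tail[-1] < tail[0] or tail[0] < 1e-12

    @pytest.mark.parametrize("order", [0.0, -0.5, 2.5])
    def test_order_validation(self, order):
        with pytest.raises(ValueError):
            gl_weights(order, 5)


class TestMatrices:
    def test_A_diagonal_is_one(self):
        A = assemble_first_order_matrix(0.5, 8)
        np.testing.assert_allclose(np.diag(A), 1.0)

    def test_A_specific_entry(self):
        # interior indices j=1, k=3 hold g_2^{0.5} = -0.125 (0-based [0, 2])
        A = assemble_first_order_matrix(0.5, 5)
        assert A[0, 2] == pytest.approx(-0.125, abs=1e-15)

    def test_A_classical_backward_difference(self):
        """At epsilon = 1 the first-order sums reduce to C_k - C_{k-1}."""
        A = assemble_first_order_matrix(1.0, 5)
        rng = np.random.default_rng(7)
        c = rng.random(4)
        left_sum = A.T @ c  # left-sided orientation
        expected = c - np.concatenate([[0.0], c[:-1]])  # C_0 = 0 boundary
        np.testing.assert_allclose(left_sum, expected, atol=1e-15)

    def test_B_superdiagonal_is_one(self):
        B = assemble_second_order_matrix(0.5, 8)
        np.testing.assert_allclose(np.diag(B, k=-1), 1.0)  # rows j = k+1

    def test_B_diagonal_entry(self):
        B = assemble_second_order_matrix(0.5, 6)
        np.testing.assert_allclose(np.diag(B), -1.5)  # g_1^{1.5} = -(1+eps)

    def test_B_classical_second_difference(self):
        """At epsilon = 1, B realizes C_{k-1} - 2 C_k + C_{k+1} regardless of side."""
        B = assemble_second_order_matrix(1.0, 6)
        rng = np.random.default_rng(11)
        c = rng.random(5)
        padded = np.concatenate([[0.0], c, [0.0]])
        expected = padded[:-2] - 2 * padded[1:-1] + padded[2:]
        np.testing.assert_allclose(B.T @ c, expected, atol=1e-14)
        np.testing.assert_allclose(B @ c, expected, atol=1e-14)


def classical_cylindrical_matrix(grid, D):
    """Independent three-point discretization of D (C'' + C'/r)."""
    m = grid.N - 1
    dr = grid.dr
    ri = grid.interior
    M = np.zeros((m, m))
    for i in range(m):
        M[i, i] = -2 * D / dr**2
        if i > 0:
            M[i, i - 1] = D / dr**2 - D / (2 * dr * ri[i])
        if i < m - 1:
            M[i, i + 1] = D / dr**2 + D / (2 * dr * ri[i])
    return M


class TestFluxDivergenceOperator:
    def test_classical_limit_entrywise(self, geometry):
        grid = build_grid(geometry, 40)
        params = AnomalousDiffusionParams(D=3.3e-9, epsilon=1.0, p=0.5, q=0.5)
        op = flux_divergence_operator(grid, params)
        expected = classical_cylindrical_matrix(grid, params.D)
        np.testing.assert_allclose(op.matrix, expected, rtol=1e-12, atol=1e-3)

    def test_zero_input_zero_output(self, geometry):
        grid = build_grid(geometry, 12)
        params = AnomalousDiffusionParams(D=3.3e-9, epsilon=0.7, p=0.6, q=0.4)
        op = flux_divergence_operator(grid, params)
        np.testing.assert_array_equal(op(np.zeros(11)), 0.0)

    def test_hand_expanded_sums_small_grid(self):
        """Operator rows equal directly expanded GL sums at N = 6.

        Forward (p) weight applies the right-sided sums, backward (q) the
        left-sided ones; expansion written independently of the matrix
        assembly code.
        """
        geom = Geometry(a=0.25, h=0.25, d=0.25, g=0.25)
        grid = build_grid(geom, 6)
        eps, p, q, D = 0.6, 0.3, 0.7, 2.0
        params = AnomalousDiffusionParams(D=D, epsilon=eps, p=p, q=q)
        op = flux_divergence_operator(grid, params)
        rng = np.random.default_rng(3)
        c = rng.random(5)
        cfull = np.concatenate([[0.0], c, [0.0]])  # Dirichlet ends
        g1 = gl_weights(eps, 7).values
        g2 = gl_weights(eps + 1.0, 8).values
        dr = grid.dr
        N = 6
        out = np.empty(5)
        for k in range(1, N):
            left1 = sum(g1[j] * cfull[k - j] for j in range(0, k + 1)) / dr**eps
            right1 = sum(g1[j] * cfull[k + j] for j in range(0, N - k + 1)) / dr**eps
            left2 = sum(g2[j] * cfull[k - j + 1] for j in range(0, k + 2)) / dr ** (eps + 1)
            right2 = sum(g2[j] * cfull[k + j - 1] for j in range(0, N - k + 2)) / dr ** (
                eps + 1
            )
            rk = grid.nodes[k]
            out[k - 1] = D * ((q * left2 + p * right2) + (q * left1 - p * right1) / rk)
        np.testing.assert_allclose(op(c), out, rtol=1e-12)

    def test_linearity_and_scaling(self, geometry):
        grid = build_grid(geometry, 16)
        params = AnomalousDiffusionParams(D=3.3e-9, epsilon=0.85, p=0.75, q=0.25)
        op = flux_divergence_operator(grid, params)
        rng = np.random.default_rng(5)
        c = rng.random(15)
        np.testing.assert_allclose(op(3.5 * c), 3.5 * op(c), rtol=1e-12)

    def test_pq_validation(self):
        with pytest.raises(ValueError, match="p \\+ q"):
            AnomalousDiffusionParams(D=1.0, epsilon=0.5, p=0.7, q=0.2)


class TestRLPowerOracle:
    @pytest.mark.parametrize(
        "mu,eps,x,expected",
        [
            (1.0, 1.0, 2.0, 1.0),
            (1.0, 0.5, 1.0, 1.1283791670955126),  # 1/Gamma(1.5)
            (0.5, 0.5, 1.0, 0.8862269254527580),  # Gamma(1.5)/Gamma(1)
        ],
    )
    def test_closed_form_values(self, mu, eps, x, expected):
        assert rl_left_power(mu, eps, x) == pytest.approx(expected, rel=1e-12)

    def test_matches_mpmath(self):
        for mu, eps in [(2.0, 0.25), (2.0, 0.85), (1.3, 0.6)]:
            expected = float(
                mpmath.gamma(mu + 1) / mpmath.gamma(mu + 1 - eps) * mpmath.mpf(0.7) ** (mu - eps)
            )
            assert rl_left_power(mu, eps, 0.7) == pytest.approx(expected, rel=1e-13)

    def test_pole_rejected(self):
        with pytest.raises(ValueError, match="pole"):
            rl_left_power(0.0, 1.0, 1.0)

    def test_requires_x_beyond_L(self):
        with pytest.raises(ValueError):
            rl_left_power(1.0, 0.5, 0.0, 0.0)


class TestGLConvergence:
    @pytest.mark.parametrize("eps", [0.25, 0.5, 0.85])
    def test_first_order_convergence_to_closed_form(self, eps):
        """Unshifted GL of (r-L)^2 converges to the RL closed form.

        The empirical order approaches 1 from below (measured ~0.99 at the
        coarsest refinement pair and ~0.999 at the finest); asserted > 0.95
        to distinguish first-order convergence from stagnation, with the
        measured orders surfaced in the failure message.
        """
        errs = []
        for i in range(5):
            n = 16 * 2**i
            dr = 1.0 / n
            vals = (np.arange(n + 1) * dr) ** 2
            approx = gl_left_apply(eps, vals, dr)[n // 2]
            errs.append(abs(approx - rl_left_power(2.0, eps, 0.5)))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(4)]
        assert min(orders) > 0.95, f"measured orders {orders}"
        assert errs[-1] < errs[0] / 10
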