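import numpy as np
import pytest
from scipy.linalg import circulant

from rnflseg.errors import SnakeDivergenceError
from rnflseg.oct_io import BoundaryCurve
from rnflseg.snake_freq import (SnakeParams, bspline_spectrum,
                                build_internal_filter, evolve, external_force,
                                stiffness_spectrum)


def internal_matrix(params, S):
    """Circulant alpha*D2 + beta*D4 built from the [-1, 2, -1] stencil."""
    col = np.zeros(S)
    col[0], col[1], col[-1] = 2.0, -1.0, -1.0
    D2 = circulant(col)
    return params.alpha * D2 + params.beta * (D2 @ D2)


def spline_smooth(q):
    """Circular convolution with the sampled cubic B-spline (1/6, 2/3, 1/6)."""
    return (np.roll(q, 1) + np.roll(q, -1)) / 6.0 + 2.0 * q / 3.0


class TestInternalFilter:
    def test_closed_form_values(self):
        # alpha=0.5, beta=1, S=8: at k=4 (omega=pi), K = 0.5*4 + 1*16 = 18
        p = SnakeParams(alpha=0.5, beta=1.0, gamma_d=1.0, eta=1.0)
        H, a1, a2 = build_internal_filter(p, 8)
        K = stiffness_spectrum(p, 8)
        assert K[4] == pytest.approx(18.0)
        assert H[4] == pytest.approx(1.0 / 20.0)
        # DC bin: K=0, H = 1/(gamma_d + eta)
        assert K[0] == 0.0
        assert H[0] == pytest.approx(0.5)
        assert (a1, a2) == (3.0, -1.0)

    def test_dc_neutrality(self):
        for p in (SnakeParams(), SnakeParams(alpha=2.0, beta=0.1, gamma_d=3.0, eta=0.5)):
            H, a1, a2 = build_internal_filter(p, 32)
            assert H[0] * (a1 + a2) == pytest.approx(1.0)

    def test_spectrum_matches_circulant_matrix(self):
        p = SnakeParams(alpha=0.7, beta=1.3)
        S = 16
        K = stiffness_spectrum(p, S)
        eig = np.linalg.eigvals(internal_matrix(p, S))
        np.testing.assert_allclose(np.sort(K), np.sort(eig.real), atol=1e-9)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            build_internal_filter(SnakeParams(), 3)

    def test_invalid_params_rejected(self):
        for kw in (dict(alpha=0, beta=0), dict(gamma_d=0), dict(eta=-1),
                   dict(tol=0)):
            with pytest.raises(ValueError):
                SnakeParams(**kw)


class TestExternalForce:
    def test_flat_edge_map_zero_force(self):
        q = external_force(np.zeros((30, 8)), np.full(8, 15.0))
        np.testing.assert_array_equal(q, 0.0)

    def test_ridge_attraction_symmetry(self):
        e = np.zeros((60, 4))
        e[30] = 100.0
        above = external_force(e, np.full(4, 28.0))
        below = external_force(e, np.full(4, 33.0))
        assert np.all(above > 0)   # pulled downward toward the ridge
        assert np.all(below < 0)   # pulled upward

    def test_masked_column_cancelled(self):
        e = np.zeros((60, 4))
        e[30] = 100.0
        mask = np.zeros((60, 4), dtype=bool)
        mask[:, 2] = True
        q = external_force(e, np.full(4, 28.0), mask=mask)
        assert q[2] == 0.0 and np.all(q[[0, 1, 3]] > 0)


class TestEvolve:
    def test_constant_init_zero_force_is_fixed_point(self):
        init = BoundaryCurve(np.full(32, 80.0))
        out = evolve(init, None, SnakeParams(max_iter=50))
        np.testing.assert_allclose(out.y, 80.0, atol=1e-12)

    def test_spike_decays_monotonically_to_mean(self):
        y = np.full(32, 50.0)
        y[10] += 8.0
        init = BoundaryCurve(y)
        devs = []
        for iters in (1, 3, 6, 12, 50, 400):
            out = evolve(init, None, SnakeParams(max_iter=iters, tol=1e-300))
            devs.append(np.max(np.abs(out.y - y.mean())))
            assert out.y.mean() == pytest.approx(y.mean(), abs=1e-9)
        assert all(a > b for a, b in zip(devs, devs[1:]))
        assert devs[-1] < 0.05

    def test_internal_energy_decreases_force_free(self):
        rng = np.random.default_rng(7)
        y = 60.0 + rng.normal(0, 3, 64)
        p = SnakeParams()
        A = internal_matrix(p, 64)
        energies = []
        for iters in (1, 2, 4, 8, 16, 32):
            u = evolve(BoundaryCurve(y), None, SnakeParams(max_iter=iters, tol=1e-300)).y
            energies.append(0.5 * u @ A @ u)
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_output_real_valued(self):
        rng = np.random.default_rng(3)
        e = np.zeros((80, 48))
        e[40] = 100.0
        init = BoundaryCurve(38.0 + rng.normal(0, 1, 48))
        out = evolve(init, e, SnakeParams(max_iter=100))
        assert out.y.dtype == np.float64 and np.all(np.isfinite(out.y))

    def test_undetected_init_rejected(self):
        det = np.ones(16, dtype=bool)
        det[0] = False
        with pytest.raises(ValueError):
            evolve(BoundaryCurve(np.full(16, 10.0), detected=det), None)

    def test_frequency_iteration_equals_spatial_iteration(self):
        """The per-bin update must match the damped time-stepped spatial system
        eta(u_x - 2u_{x-1} + u_{x-2}) + gamma(u_x - u_{x-1}) + K u_x = eta*q."""
        rng = np.random.default_rng(42)
        S, rows = 48, 120
        ridge_row = 60 + (8 * np.sin(2 * np.pi * np.arange(S) / S)).astype(int)
        e = np.zeros((rows, S))
        e[ridge_row, np.arange(S)] = 100.0
        p = SnakeParams(alpha=0.5, beta=1.0, gamma_d=1.0, eta=1.0, blur_sigma=1.0)
        y0 = 60.0 + rng.normal(0, 2, S)

        n_iter = 40
        out = evolve(BoundaryCurve(y0), e, SnakeParams(**{**p.__dict__, "max_iter": n_iter, "tol": 1e-300}))

        # independent spatial-domain oracle
        A = internal_matrix(p, S)
        M = (p.gamma_d + p.eta) * np.eye(S) + A
        a1, a2 = p.gamma_d + 2 * p.eta, -p.eta
        u1 = y0.copy()
        u2 = y0.copy()
        for _ in range(n_iter):
            q = spline_smooth(external_force(e, u1, blur_sigma=p.blur_sigma))
            u = np.linalg.solve(M, a1 * u1 + a2 * u2 + p.eta * q)
            u2, u1 = u1, u
        np.testing.assert_allclose(out.y, u1, atol=1e-9)

    def test_equilibrium_solves_static_snake_equation(self):
        """At convergence the contour satisfies (alpha*D2 + beta*D4) u = eta*q
        (with the B-spline-smoothed force), solved by an independent circulant
        linear system."""
        S, rows = 16, 80
        ridge_row = 40 + (5 * np.cos(2 * np.pi * np.arange(S) / S)).astype(int)
        e = np.zeros((rows, S))
        e[ridge_row, np.arange(S)] = 100.0
        p = SnakeParams(max_iter=20000, tol=1e-13)
        out = evolve(BoundaryCurve(np.full(S, 40.0)), e, p)
        u = out.y
        q = spline_smooth(external_force(e, u, blur_sigma=p.blur_sigma))
        A = internal_matrix(p, S)
        # A is singular (DC nullspace); pin the mean to the converged mean
        M = A + np.ones((S, S)) / S
        u_oracle = np.linalg.solve(M, p.eta * q + u.mean())
        np.testing.assert_allclose(u, u_oracle, atol=1e-6)

    def test_divergence_raises_named_iteration(self):
        init = BoundaryCurve(np.array([np.inf, 1.0, 1.0, 1.0, 1.0]))
        with pytest.raises(SnakeDivergenceError):
            evolve(init, None, SnakeParams(max_iter=5))


def test_bspline_spectrum_is_sampled_kernel_dft():
    S = 12
    kernel = np.zeros(S)
    kernel[0], kernel[1], kernel[-1] = 2 / 3, 1 / 6, 1 / 6
    np.testing.assert_allclose(bspline_spectrum(S), np.fft.fft(kernel).real,
                               atol=1e-12)
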