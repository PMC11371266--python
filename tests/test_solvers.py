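"""Dual prox, FBS, objectives/majorization and the outer refinement loops."""

import numpy as np
import pytest
from scipy.optimize import lsq_linear

from sparl import masks, operators as ops, solvers as sol
from sparl._ad import val


def _soft(z, g):
    return np.sign(z) * np.maximum(np.abs(z) - g, 0.0)


def _dense_of(L, shape):
    """Explicit matrix of an analysis operator on images of `shape`."""
    cols = []
    n = int(np.prod(shape))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        cols.append(val(L.apply(e.reshape(shape))).ravel())
    return np.stack(cols, axis=1)


class TestToleranceSchedule:
    def test_denoising_closed_form(self):
        s = sol.ToleranceSchedule("denoising")
        assert sol.eval_tolerance(s, 5) == pytest.approx(1e-5)
        assert sol.eval_tolerance(s, 1) == pytest.approx(1e-3 * 0.01 ** 0.2)
        assert sol.eval_tolerance(s, 6) == 1e-5
        # continuity across the branch switch
        assert sol.eval_tolerance(s, 5) == pytest.approx(sol.eval_tolerance(s, 6))

    def test_general_closed_form_and_continuity(self):
        s = sol.ToleranceSchedule("general")
        eps_fbs = s.fbs_tol(3)
        assert eps_fbs == pytest.approx(1e-3 * 0.01 ** (3 / 5))
        assert sol.eval_tolerance(s, 3, 50) == pytest.approx(eps_fbs / 3.0)
        assert sol.eval_tolerance(s, 3, 51) == pytest.approx(eps_fbs / 3.0)
        assert sol.eval_tolerance(s, 3, 1) == pytest.approx(
            3 * eps_fbs * (1 / 9) ** (1 / 50))

    def test_off_mode_never_stops(self):
        s = sol.ToleranceSchedule("off")
        assert sol.eval_tolerance(s, 1) < 0 and s.fbs_tol(1) < 0

    def test_invalid(self):
        with pytest.raises(ValueError):
            sol.ToleranceSchedule("sometimes")
        with pytest.raises(ValueError):
            sol.eval_tolerance(sol.ToleranceSchedule("denoising"), 0)


class TestProxWeightedL1:
    def test_identity_operator_is_soft_thresholding(self, rng):
        L = ops.MatrixOperator(np.eye(3))
        x, _, _ = sol.prox_weighted_l1(L, np.array([2.0, -0.5, 0.1]), 1.0,
                                       eps=1e-12, K_prox=3000)
        assert np.allclose(x, [1.0, 0.0, 0.0], atol=1e-6)
        for i in range(5):
            z = np.random.default_rng(i).standard_normal(12)
            g = 0.2 + 0.1 * i
            x, _, _ = sol.prox_weighted_l1(ops.MatrixOperator(np.eye(12)), z, g,
                                           eps=1e-12, K_prox=3000)
            assert np.allclose(x, _soft(z, g), atol=1e-6)

    def test_zero_gamma_returns_input(self, rng):
        z = rng.standard_normal(7)
        x, _, it = sol.prox_weighted_l1(ops.MatrixOperator(np.eye(7)), z, 0.0)
        assert np.array_equal(x, z) and it == 0

    def test_negative_gamma_raises(self):
        with pytest.raises(ValueError):
            sol.prox_weighted_l1(ops.MatrixOperator(np.eye(2)), np.zeros(2), -1.0)

    def test_dense_operator_against_box_qp_oracle(self):
        worst = 0.0
        for i in range(15):
            r = np.random.default_rng(100 + i)
            Lm = r.standard_normal((12, 8))
            z = r.standard_normal(8)
            gam = float(r.uniform(0.05, 0.5))
            x, _, _ = sol.prox_weighted_l1(ops.MatrixOperator(Lm), z, gam,
                                           eps=-1, K_prox=4000)
            res = lsq_linear(Lm.T, z, bounds=(-gam, gam), tol=1e-14)
            worst = max(worst, float(np.max(np.abs(x - (z - Lm.T @ res.x)))))
        assert worst < 1e-4

    def test_box_constraint_closed_form(self, rng):
        # over a box, the prox of gamma|.|_1 with L = Id clamps the soft threshold
        z = rng.standard_normal(20)
        x, _, _ = sol.prox_weighted_l1(ops.MatrixOperator(np.eye(20)), z, 0.3,
                                       X=("box", -0.25, 0.4), eps=1e-13, K_prox=4000)
        assert np.allclose(x, np.clip(_soft(z, 0.3), -0.25, 0.4), atol=1e-6)

    def test_dual_gradient_matches_finite_differences(self, rng):
        # the dual objective 1/2||L^T u - z||^2 (X = R^N): the update direction
        # used by the solver must be its gradient
        Lm = rng.standard_normal((10, 6))
        z = rng.standard_normal(6)
        u = rng.standard_normal(10)
        grad = Lm @ (Lm.T @ u - z)
        h = 1e-6
        for _ in range(5):
            d = rng.standard_normal(10)
            fp = 0.5 * np.sum((Lm.T @ (u + h * d) - z) ** 2)
            fm = 0.5 * np.sum((Lm.T @ (u - h * d) - z) ** 2)
            assert (fp - fm) / (2 * h) == pytest.approx(float(grad @ d), rel=1e-5)

    def test_optimality_sign_consistency(self, rng):
        # at convergence: u_i = gamma * sign((Lx)_i) on active coefficients,
        # i.e. z - x = gamma L^T sign(Lx) holds componentwise
        Lm = np.random.default_rng(7).standard_normal((10, 6))
        z = np.random.default_rng(8).standard_normal(6)
        gam = 0.25
        x, u, _ = sol.prox_weighted_l1(ops.MatrixOperator(Lm), z, gam,
                                       eps=-1, K_prox=6000)
        w = Lm @ x
        active = np.abs(w) > 1e-6
        assert np.all(np.abs(u[active] - gam * np.sign(w[active])) < 1e-4)
        assert np.all(np.abs(u) <= gam + 1e-12)
        assert np.allclose(z - x, Lm.T @ u, atol=1e-10)


class TestFBS:
    def test_zero_lam_identity_returns_measurements(self, rng):
        H = ops.IdentityModel((6, 6))
        y = rng.standard_normal((6, 6))
        W = ops.ConvOperator.random(1, 2, 1, 3, seed=0)
        x, info = sol.fbs_solve(H, y, ops.AnalysisOperator(W), 0.0,
                                np.zeros((6, 6)), sol.SolverConfig(lam=0.0))
        assert np.array_equal(val(x), y)
        assert info["fbs_iterations"] == 1

    def test_one_outer_step_is_exact_prox_for_identity(self, rng):
        # single FBS step with H = Id lands on prox_{lam||L.||_1}(y),
        # independently verified by the dense box-QP oracle
        H = ops.IdentityModel((6, 6))
        y = rng.standard_normal((6, 6))
        W = ops.ConvOperator.random(1, 2, 1, 3, constraint="zero_mean", seed=1)
        L = ops.AnalysisOperator(W)
        lam = 0.07
        cfg = sol.SolverConfig(lam=lam, K_FBS=1, K_prox=6000,
                               schedule=sol.ToleranceSchedule("off"))
        x1, _ = sol.fbs_solve(H, y, L, lam, rng.standard_normal((6, 6)), cfg)
        dense = _dense_of(L, (6, 6))
        res = lsq_linear(dense.T, y.ravel(), bounds=(-lam, lam), tol=1e-14)
        oracle = y.ravel() - dense.T @ res.x
        assert np.max(np.abs(val(x1).ravel() - oracle)) < 1e-6

    def test_dense_forward_model_matches_convex_oracle(self, rng):
        # small invertible H: compare the achieved objective with a long dual
        # solve of the equivalent problem via a fine proximal-gradient oracle
        n = 4
        A = np.eye(n * n) + 0.3 * rng.standard_normal((n * n, n * n)) / n
        H = ops.DenseModel(A, (n, n))
        y = H.apply(rng.random((n, n)))
        W = ops.ConvOperator.random(1, 2, 1, 3, constraint="zero_mean", seed=2)
        L = ops.AnalysisOperator(W)
        lam = 0.05
        cfg = sol.SolverConfig(lam=lam, K_FBS=1000, K_prox=500,
                               schedule=sol.ToleranceSchedule("general"))
        x, _ = sol.fbs_solve(H, y, L, lam, np.zeros((n, n)), cfg, k_out=6)
        fx = sol.objective_weighted_l1(val(x), H, y, lam, L)
        # oracle: plain (unaccelerated) proximal gradient, many iterations,
        # dense prox via the box-QP dual at machine precision
        dense = _dense_of(L, (n, n))
        alpha = 1.0 / H.sq_spectral_norm
        w = np.zeros(n * n)
        for _ in range(2000):
            z = w - alpha * (A.T @ (A @ w - y.ravel()))
            res = lsq_linear(dense.T, z, bounds=(-alpha * lam, alpha * lam), tol=1e-12)
            w = z - dense.T @ res.x
        f_oracle = 0.5 * np.sum((A @ w - y.ravel()) ** 2) + lam * np.sum(np.abs(dense @ w))
        assert fx <= f_oracle + 1e-5


class TestObjectives:
    def _gen(self, nc=3, circular=True, unit=True, seed=0):
        g = masks.MMRMaskGenerator.random(
            n_channels=nc, kernel_size=3, profile_init=("paper" if unit else "random"),
            padding=("circular" if circular else "zero"), seed=seed)
        if unit:
            g.sigma_knots = np.ones_like(g.sigma_knots)
        return g

    def test_objective_at_zero_is_half_norm_y(self, rng):
        g = self._gen(unit=False)
        H = ops.IdentityModel((8, 8))
        y = rng.standard_normal((8, 8))
        assert sol.objective_mmr(np.zeros((8, 8)), H, y, 0.3, g) == pytest.approx(
            0.5 * np.sum(y ** 2))

    def test_unit_profiles_circular_reduce_to_l1_analysis(self, rng):
        g = self._gen(unit=True, circular=True)
        H = ops.IdentityModel((8, 8))
        x, y = rng.standard_normal((8, 8)), rng.standard_normal((8, 8))
        lam = 0.2
        expected = 0.5 * np.sum((x - y) ** 2) + lam * np.sum(np.abs(val(g.W.apply(x))))
        assert sol.objective_mmr(x, H, y, lam, g) == pytest.approx(expected)

    def test_linear_potential_makes_surrogate_exact(self, rng):
        g = self._gen(unit=True, circular=False)
        H = ops.IdentityModel((8, 8))
        y = rng.standard_normal((8, 8))
        for _ in range(5):
            x, xk = rng.standard_normal((8, 8)), rng.standard_normal((8, 8))
            fv = sol.objective_mmr(x, H, y, 0.1, g)
            gv = sol.majorization_value(x, xk, H, y, 0.1, g)
            assert gv == pytest.approx(fv, rel=1e-12)

    def test_majorization_upper_bound_and_tightness(self, rng):
        g = self._gen(unit=False, circular=False, seed=3)
        H = ops.IdentityModel((8, 8))
        y = rng.standard_normal((8, 8))
        for _ in range(50):
            x, xk = 2 * rng.standard_normal((8, 8)), 2 * rng.standard_normal((8, 8))
            fv = sol.objective_mmr(x, H, y, 0.15, g)
            gv = sol.majorization_value(x, xk, H, y, 0.15, g)
            assert gv >= fv - 1e-10
            fk = sol.objective_mmr(xk, H, y, 0.15, g)
            tk = sol.majorization_value(xk, xk, H, y, 0.15, g)
            assert abs(tk - fk) <= 1e-10 * (1 + abs(fk))


class TestOuterLoops:
    def test_mmr_zero_lam_gives_least_squares(self, rng):
        g = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3, seed=1)
        H = ops.IdentityModel((8, 8))
        y = rng.standard_normal((8, 8))
        x, _ = sol.mmr_reconstruct(H, y, g, sol.SolverConfig(lam=0.0, K_out=2),
                                   compute_objective=False)
        assert np.allclose(val(x), y)

    def test_unit_profile_circular_masks_stay_all_ones(self, rng):
        g = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3,
                                          padding="circular", seed=1)
        g.sigma_knots = np.ones_like(g.sigma_knots)
        H = ops.IdentityModel((8, 8))
        y = rng.standard_normal((8, 8))
        cfg = sol.SolverConfig(lam=0.05, K_out=6, record_masks=True)
        x, tr = sol.mmr_reconstruct(H, y, g, cfg, compute_objective=False)
        for m in tr.masks:
            assert np.allclose(m, 1.0, atol=1e-12)
        # mask fixed point: after the first refinement the problem no longer
        # changes, so later steps move only within the inner tolerance
        assert tr.e[1] < 1e-3 and tr.e[-1] < 1e-4

    def test_mmr_descent_small_instances(self, rng):
        H = ops.IdentityModel((16, 16))
        for seed in range(5):
            g = masks.MMRMaskGenerator.random(n_channels=3, kernel_size=3,
                                              profile_init="random", seed=seed)
            y = np.clip(rng.random((16, 16)) + 0.1 * rng.standard_normal((16, 16)), 0, 1)
            _, tr = sol.mmr_reconstruct(H, y, g, sol.SolverConfig(lam=0.03))
            f = np.asarray(tr.f)
            assert np.all(np.diff(f) <= 1e-6 * (1 + np.abs(f[:-1])))

    def test_safi_zero_lam_least_squares(self, rng):
        g = masks.SAFIMaskGenerator.random(n_channels=2, kernel_size=3, seed=1)
        H = ops.IdentityModel((8, 8))
        y = rng.standard_normal((8, 8))
        x, _ = sol.safi_reconstruct(H, y, g, sol.SolverConfig(lam=0.0, K_out=2),
                                    compute_objective=False)
        assert np.allclose(val(x), y)

    def test_safi_iterates_respect_identity_radius(self, rng):
        g = masks.SAFIMaskGenerator.random(n_channels=3, kernel_size=3,
                                           spline_init="random", seed=2)
        H = ops.IdentityModel((16, 16))
        y = rng.standard_normal((16, 16))
        _, tr = sol.safi_reconstruct(H, y, g, sol.SolverConfig(lam=0.05),
                                     compute_objective=False)
        bound = 2.0 * np.linalg.norm(y)  # sigma_min = 1
        assert all(n <= bound + 1e-8 for n in tr.x_norm)

    def test_converged_point_is_stable_under_one_more_update(self, rng):
        g = masks.MMRMaskGenerator.random(n_channels=3, kernel_size=3,
                                          profile_init="random", seed=5)
        H = ops.IdentityModel((16, 16))
        y = np.clip(rng.random((16, 16)) + 0.1 * rng.standard_normal((16, 16)), 0, 1)
        eps_out = 1e-5
        cfg = sol.SolverConfig(lam=0.02, K_out=20, eps_out=eps_out)
        x_star, tr = sol.mmr_reconstruct(H, y, g, cfg, compute_objective=False)
        assert tr.e[-1] < eps_out
        # apply the update operator once more, inner problem solved tightly
        tight = sol.SolverConfig(lam=0.02, K_out=1, K_prox=3000,
                                 schedule=sol.ToleranceSchedule("off"))
        x_extra, _ = sol.mmr_reconstruct(H, y, g, tight,
                                         x_init=val(x_star), compute_objective=False)
        rel = np.linalg.norm(val(x_extra) - val(x_star)) / np.linalg.norm(val(x_star))
        assert rel < 10 * eps_out

    def test_scheme_dispatch_and_mismatch(self, rng):
        g = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3, seed=0)
        H = ops.IdentityModel((6, 6))
        y = rng.standard_normal((6, 6))
        with pytest.raises(ValueError):
            sol.safi_reconstruct(H, y, g, sol.SolverConfig(lam=0.1))
        x, tr = sol.reconstruct(H, y, g, sol.SolverConfig(lam=0.05), scheme="l1")
        assert val(x).shape == (6, 6) and len(tr.f) == 1
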