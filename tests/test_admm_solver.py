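import numpy as np
import pytest
from scipy.optimize import minimize

from nashseg.admm_solver import (
    GameState,
    SolveReport,
    bregman_update,
    run_ccz,
    run_game,
    shrink_anisotropic,
    shrink_isotropic,
    update_G,
    update_g,
)
from nashseg.grid_ops import VectorField, gradient
from nashseg.model_core import JacobianField, SolverParams, energy_E1, energy_E2, energy_ccz, jacobian

from _oracles import diff_matrices, laplacian_matrix


def random_state(rng, shape) -> GameState:
    rv = lambda: VectorField(rng.standard_normal(shape), rng.standard_normal(shape))  # noqa: E731
    return GameState(
        g=rng.standard_normal(shape),
        G=rv(),
        v=rv(),
        b1=rv(),
        w=JacobianField(rv(), rv()),
        b2=JacobianField(rv(), rv()),
    )


def g_subproblem_objective(g, state, f, p):
    """The image player's augmented quadratic (fidelity + smoothness +
    coupling + split penalty), written out independently."""
    dg = gradient(g, p.transform_mode)
    e = 0.5 * p.lambda1 * np.sum((f - g) ** 2)
    e += 0.5 * p.mu1 * (np.sum(dg.x**2) + np.sum(dg.y**2))
    e += 0.5 * p.xi1 * (np.sum((state.G.x - dg.x) ** 2) + np.sum((state.G.y - dg.y) ** 2))
    e += 0.5 * p.rho1 * (
        np.sum((state.v.x - dg.x - state.b1.x) ** 2)
        + np.sum((state.v.y - dg.y - state.b1.y) ** 2)
    )
    return e


def G_subproblem_objective(G, state, f, p):
    mode = p.transform_mode
    df = gradient(f, mode)
    dg = gradient(state.g, mode)
    J = jacobian(G, mode)
    e = 0.5 * p.lambda2 * (np.sum((df.x - G.x) ** 2) + np.sum((df.y - G.y) ** 2))
    e += 0.5 * p.mu2 * sum(np.sum(c**2) for c in J.channels())
    e += 0.5 * p.xi2 * (np.sum((G.x - dg.x) ** 2) + np.sum((G.y - dg.y) ** 2))
    for wc, Jc, bc in ((state.w.dGx, J.dGx, state.b2.dGx), (state.w.dGy, J.dGy, state.b2.dGy)):
        e += 0.5 * p.rho2 * (
            np.sum((wc.x - Jc.x - bc.x) ** 2) + np.sum((wc.y - Jc.y - bc.y) ** 2)
        )
    return e


class TestUpdateG1:
    def test_constant_image_zero_splits_returns_f(self):
        f = np.full((8, 8), 77.0)
        state = GameState.initial(f)
        p = SolverParams()
        np.testing.assert_allclose(update_g(state, f, p), f, rtol=1e-13)

    @pytest.mark.parametrize("mode", ["periodic", "symmetric"])
    def test_matches_dense_solve(self, rng, mode):
        shape = (8, 8)
        f = rng.standard_normal(shape)
        state = random_state(rng, shape)
        p = SolverParams(lambda1=0.7, mu1=0.3, xi1=0.9, rho1=1.1, transform_mode=mode)
        Dx, Dy = diff_matrices(*shape, mode)
        L = laplacian_matrix(*shape, mode)
        A = p.lambda1 * np.eye(f.size) + (p.mu1 + p.xi1 + p.rho1) * L
        rhs = (
            p.lambda1 * f.ravel()
            + p.xi1 * (Dx.T @ state.G.x.ravel() + Dy.T @ state.G.y.ravel())
            + p.rho1
            * (
                Dx.T @ (state.v.x - state.b1.x).ravel()
                + Dy.T @ (state.v.y - state.b1.y).ravel()
            )
        )
        expected = np.linalg.solve(A, rhs)
        np.testing.assert_allclose(update_g(state, f, p).ravel(), expected, rtol=1e-8)

    def test_is_minimiser_against_random_perturbations(self, rng):
        shape = (8, 8)
        f = rng.standard_normal(shape)
        state = random_state(rng, shape)
        p = SolverParams(lambda1=0.5, mu1=0.2, xi1=0.4, rho1=0.8)
        g_star = update_g(state, f, p)
        base = g_subproblem_objective(g_star, state, f, p)
        for _ in range(100):
            perturbed = g_star + rng.standard_normal(shape) * rng.uniform(1e-3, 1.0)
            assert g_subproblem_objective(perturbed, state, f, p) > base


class TestShrinkIsotropic:
    def test_zero_input_gives_zero(self):
        s = VectorField(np.zeros((5, 5)), np.zeros((5, 5)))
        out = shrink_isotropic(s, 1.0)
        assert np.all(out.x == 0) and np.all(out.y == 0)

    def test_three_four_five_triangle(self):
        s = VectorField(np.array([[3.0]]), np.array([[4.0]]))
        out = shrink_isotropic(s, 1.0)
        assert out.x[0, 0] == pytest.approx(2.4, rel=1e-12)
        assert out.y[0, 0] == pytest.approx(3.2, rel=1e-12)

    def test_magnitude_below_kappa_is_annihilated(self):
        s = VectorField(np.array([[0.3]]), np.array([[0.4]]))
        out = shrink_isotropic(s, 1.0)
        assert out.x[0, 0] == 0.0 and out.y[0, 0] == 0.0

    @pytest.mark.parametrize("kappa", [0.1, 1.0, 10.0])
    def test_matches_proximal_oracle(self, rng, kappa):
        for _ in range(30):
            sx, sy = rng.standard_normal(2) * 5
            out = shrink_isotropic(
                VectorField(np.array([[sx]]), np.array([[sy]])), kappa
            )
            obj = lambda z: kappa * np.hypot(*z) + 0.5 * ((z[0] - sx) ** 2 + (z[1] - sy) ** 2)  # noqa: E731
            res = minimize(obj, x0=[sx, sy], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14})
            assert out.x[0, 0] == pytest.approx(res.x[0], abs=1e-6)
            assert out.y[0, 0] == pytest.approx(res.x[1], abs=1e-6)

    def test_nonpositive_kappa_raises(self):
        s = VectorField(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="kappa"):
            shrink_isotropic(s, 0.0)


class TestUpdateG2:
    def test_zero_rhs_gives_zero_field(self):
        f = np.full((8, 8), 3.0)
        state = GameState.initial(f)
        state.g = np.full((8, 8), 9.0)
        G = update_G(state, f, SolverParams())
        np.testing.assert_allclose(G.x, 0.0, atol=1e-13)
        np.testing.assert_allclose(G.y, 0.0, atol=1e-13)

    @pytest.mark.parametrize("mode", ["periodic", "symmetric"])
    def test_matches_dense_solve(self, rng, mode):
        shape = (8, 8)
        f = rng.standard_normal(shape)
        state = random_state(rng, shape)
        p = SolverParams(lambda2=0.5, mu2=0.8, xi2=0.6, rho2=1.3, transform_mode=mode)
        Dx, Dy = diff_matrices(*shape, mode)
        L = laplacian_matrix(*shape, mode)
        A = (p.lambda2 + p.xi2) * np.eye(f.size) + (p.mu2 + p.rho2) * L
        G = update_G(state, f, p)
        for comp, Dc, wc, bc in (
            ("x", Dx, state.w.dGx, state.b2.dGx),
            ("y", Dy, state.w.dGy, state.b2.dGy),
        ):
            rhs = (
                p.lambda2 * (Dc @ f.ravel())
                + p.xi2 * (Dc @ state.g.ravel())
                + p.rho2
                * (Dx.T @ (wc.x - bc.x).ravel() + Dy.T @ (wc.y - bc.y).ravel())
            )
            np.testing.assert_allclose(
                getattr(G, comp).ravel(), np.linalg.solve(A, rhs), rtol=1e-8
            )

    def test_descent_on_G_subproblem(self, rng):
        shape = (8, 8)
        f = rng.standard_normal(shape)
        state = random_state(rng, shape)
        p = SolverParams(lambda2=0.5, mu2=0.8, xi2=0.6, rho2=1.3)
        before = G_subproblem_objective(state.G, state, f, p)
        after = G_subproblem_objective(update_G(state, f, p), state, f, p)
        assert after < before


class TestShrinkAnisotropic:
    def test_zero_input(self):
        z = VectorField(np.zeros((3, 3)), np.zeros((3, 3)))
        out = shrink_anisotropic(JacobianField(z, z), 1.0)
        assert all(np.all(c == 0) for c in out.channels())

    def test_soft_threshold_values(self):
        chan = np.array([[2.5, -0.5]])
        r = JacobianField(
            VectorField(chan, np.zeros_like(chan)),
            VectorField(np.zeros_like(chan), np.zeros_like(chan)),
        )
        out = shrink_anisotropic(r, 1.0)
        assert out.dGx.x[0, 0] == pytest.approx(1.5)
        assert out.dGx.x[0, 1] == 0.0

    @pytest.mark.parametrize("kappa", [0.1, 1.0, 10.0])
    def test_matches_scalar_proximal_oracle(self, rng, kappa):
        for _ in range(30):
            r = float(rng.standard_normal() * 5)
            chan = np.array([[r]])
            z = np.zeros_like(chan)
            out = shrink_anisotropic(
                JacobianField(VectorField(chan, z), VectorField(z, z)), kappa
            )
            obj = lambda w: kappa * abs(w[0]) + 0.5 * (w[0] - r) ** 2  # noqa: E731
            res = minimize(obj, x0=[r], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14})
            assert out.dGx.x[0, 0] == pytest.approx(res.x[0], abs=1e-6)


class TestBregmanUpdate:
    def test_satisfied_constraint_stays_zero(self):
        z = np.zeros((4, 4))
        t = VectorField(np.ones((4, 4)), np.ones((4, 4)))
        out = bregman_update(VectorField(z, z), t, t)
        assert np.all(out.x == 0) and np.all(out.y == 0)

    def test_arithmetic(self):
        mk = lambda c: VectorField(np.full((3, 3), c), np.full((3, 3), c))  # noqa: E731
        out = bregman_update(mk(1.0), mk(3.0), mk(2.0))
        assert np.all(out.x == 2.0) and np.all(out.y == 2.0)

    def test_jacobian_kind(self):
        mk = lambda c: JacobianField(  # noqa: E731
            VectorField(np.full((3, 3), c), np.full((3, 3), c)),
            VectorField(np.full((3, 3), c), np.full((3, 3), c)),
        )
        out = bregman_update(mk(1.0), mk(3.0), mk(2.0))
        assert all(np.all(c == 2.0) for c in out.channels())

    def test_shape_mismatch_raises(self):
        a = VectorField(np.zeros((3, 3)), np.zeros((3, 3)))
        b = VectorField(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="mismatch"):
            bregman_update(a, b, b)

    def test_split_residual_shrinks_over_iterations(self, two_phase_phantom, tuned_params):
        _, noisy, _ = two_phase_phantom
        p = tuned_params
        state, _ = run_game(noisy, p)
        dg = gradient(state.g, p.transform_mode)
        final = np.sqrt(np.sum((dg.x - state.v.x) ** 2) + np.sum((dg.y - state.v.y) ** 2))
        # residual of the very first iteration, recomputed from the start
        p1 = SolverParams(**{**p.__dict__, "max_outer": 1, "tol": 1e-300})
        s1, _ = run_game(noisy, p1)
        dg1 = gradient(s1.g, p.transform_mode)
        first = np.sqrt(np.sum((dg1.x - s1.v.x) ** 2) + np.sum((dg1.y - s1.v.y) ** 2))
        assert final < first


class TestRunGame:
    def test_constant_image_fixed_point(self):
        f = np.full((16, 16), 42.0)
        state, report = run_game(f, SolverParams())
        assert report.iterations_run <= 2
        assert report.converged
        np.testing.assert_allclose(state.g, f, rtol=1e-12)
        np.testing.assert_allclose(state.G.x, 0.0, atol=1e-12)
        np.testing.assert_allclose(state.G.y, 0.0, atol=1e-12)
        np.testing.assert_array_equal(state.v.x, 0.0)
        np.testing.assert_array_equal(state.b1.x, 0.0)

    def test_determinism_bit_identical(self, two_phase_phantom, tuned_params):
        _, noisy, _ = two_phase_phantom
        s1, _ = run_game(noisy, tuned_params)
        s2, _ = run_game(noisy, tuned_params)
        assert s1.g.tobytes() == s2.g.tobytes()
        assert s1.G.x.tobytes() == s2.G.x.tobytes()
        assert s1.G.y.tobytes() == s2.G.y.tobytes()

    def test_descent_and_convergence_on_noisy_phantom(self, two_phase_phantom, tuned_params):
        _, noisy, _ = two_phase_phantom
        p = tuned_params
        state, report = run_game(noisy, p)
        assert report.converged
        assert report.relative_changes[-1] <= p.tol
        init_state = GameState.initial(noisy)
        e_init = energy_E1(noisy, init_state.g, init_state.G, p) + energy_E2(
            noisy, init_state.G, init_state.g, p
        )
        e_final = report.E1_trace[-1] + report.E2_trace[-1]
        assert e_final < e_init

    def test_report_invariants(self, two_phase_phantom, tuned_params):
        _, noisy, _ = two_phase_phantom
        _, report = run_game(noisy, tuned_params)
        assert len(report.relative_changes) == report.iterations_run
        assert len(report.E1_trace) == report.iterations_run
        if report.converged:
            assert report.relative_changes[-1] <= tuned_params.tol

    def test_non_finite_input_raises(self):
        f = np.full((8, 8), 1.0)
        f[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            run_game(f, SolverParams())

    def test_non_2d_raises(self):
        with pytest.raises(ValueError, match="2-D"):
            run_game(np.zeros(16), SolverParams())


class TestRunCCZ:
    def test_constant_image(self):
        f = np.full((16, 16), 9.0)
        g, report = run_ccz(f, SolverParams())
        np.testing.assert_allclose(g, f, rtol=1e-12)
        assert report.converged

    def test_large_lambda_reproduces_input(self, two_phase_phantom):
        _, noisy, _ = two_phase_phantom
        p = SolverParams(lambda1=1e4, mu1=0.01, rho1=0.1, tol=1e-8)
        g, _ = run_ccz(noisy, p)
        assert np.linalg.norm(g - noisy) / np.linalg.norm(noisy) < 0.01

    def test_descent_on_noisy_input(self, rng):
        f = np.full((32, 32), 100.0) + rng.normal(0, 25, (32, 32))
        p = SolverParams(lambda1=0.05, mu1=0.01, rho1=0.1, tol=1e-6)
        g, _ = run_ccz(f, p)
        assert energy_ccz(f, g, p) < energy_ccz(f, f, p)


def test_solve_report_serialises():
    rep = SolveReport(iterations_run=2, relative_changes=[0.5, 0.1], converged=False)
    d = rep.to_dict()
    assert d["iterations_run"] == 2 and d["converged"] is False
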