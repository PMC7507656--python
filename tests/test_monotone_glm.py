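"""Constraint construction and the IRLS-as-QP constrained logistic fit."""

import numpy as np
import pytest
import statsmodels.api as sm

from monopaf.monotone_glm import (
    ConvergenceControl,
    TensorSplineModel,
    build_monotone_constraints,
    fit_monotone_spline,
    irls_qp_fit,
)
from monopaf.splines import BasisDef, KnotSpec, eval_basis, make_knots, tensor_design
from monopaf.simulation import MODEL_A, MODEL_B, generate_dataset

QUARTIC_KNOTS = (0.0, 0.25, 0.5, 0.75, 1.0)


class TestConstraintMatrix:
    def test_minimal_case(self):
        cs = build_monotone_constraints(2, 1)
        np.testing.assert_array_equal(cs.A, [[-1.0, 1.0]])

    def test_row_counts(self):
        assert build_monotone_constraints(6, 6).n_constraints == 30
        assert build_monotone_constraints(6, 6, constrain_x=True).n_constraints == 60
        assert build_monotone_constraints(3, 4, extra_dims=2).A.shape == (8, 14)

    def test_each_row_one_plus_one_minus(self):
        cs = build_monotone_constraints(5, 4, extra_dims=2, constrain_x=True)
        tensor = cs.A[:, :20]
        assert np.all((cs.A[:, 20:] == 0))
        assert np.all(np.sum(tensor == 1.0, axis=1) == 1)
        assert np.all(np.sum(tensor == -1.0, axis=1) == 1)
        # constant surfaces are feasible with zero slack
        np.testing.assert_allclose(cs.A @ np.r_[np.ones(20), 0.3, -0.5], 0.0)

    def test_p_below_two_raises(self):
        with pytest.raises(ValueError):
            build_monotone_constraints(1, 3)

    def test_feasible_coefficients_give_monotone_surface(self):
        """Coefficient monotonicity along p implies a surface nondecreasing
        in z on a dense grid (grid-evaluation oracle)."""
        basis = BasisDef(knots=QUARTIC_KNOTS, degree=2)
        P = Q = basis.n_basis
        rng = np.random.default_rng(5)
        # random feasible B: cumulative sums of nonnegative increments along p
        B = np.cumsum(np.vstack([rng.normal(size=(1, Q)),
                                 rng.uniform(size=(P - 1, Q))]), axis=0)
        cs = build_monotone_constraints(P, Q)
        assert (cs.A @ B.flatten(order="F")).min() >= 0
        grid = np.linspace(0, 1, 50)
        model = TensorSplineModel(basis, basis, B.flatten(order="F"))
        for xv in grid:
            f = model.linear_predictor(grid, np.full(50, xv))
            assert np.all(np.diff(f) >= -1e-10)


class TestIRLSFit:
    def test_beta_zero_predicts_half(self):
        basis = BasisDef(knots=QUARTIC_KNOTS, degree=2)
        model = TensorSplineModel(basis, basis, np.zeros(36), np.zeros(1))
        p = model.predict_prob([0.2, 0.8], [0.1, 0.9], np.zeros((2, 1)))
        np.testing.assert_allclose(p, 0.5)

    def test_predict_matches_double_sum_oracle(self):
        basis = BasisDef(knots=QUARTIC_KNOTS, degree=2)
        rng = np.random.default_rng(9)
        B = rng.normal(size=(6, 6))
        model = TensorSplineModel(basis, basis, B.flatten(order="F"))
        z = rng.uniform(size=30)
        x = rng.uniform(size=30)
        psi = eval_basis(basis, z)
        phi = eval_basis(basis, x)
        direct = 1.0 / (1.0 + np.exp(-np.einsum("np,pq,nq->n", psi, B, phi)))
        np.testing.assert_allclose(model.predict_prob(z, x), direct, atol=1e-12)

    def test_unconstrained_fit_matches_statsmodels_glm(self, steep_cohort):
        """With inactive constraints the constrained optimum is the MLE; both
        must match an independent GLM fit on the identical design columns."""
        y, z, x = steep_cohort
        spec = KnotSpec(probs=(0.0, 0.5, 1.0), degree=2)
        ctrl = ConvergenceControl(tol=1e-10, max_iter=200)
        fit = fit_monotone_spline(y, z, x, knot_spec=spec, control=ctrl)
        assert fit.converged
        assert fit.active_constraints.size == 0
        D = fit.model.design_matrix(z, x)
        ref = sm.GLM(y, D, family=sm.families.Binomial()).fit(tol=1e-12)
        np.testing.assert_allclose(fit.beta_hat, ref.params, atol=1e-4)

    def test_flat_truth_yields_flat_surface(self):
        """When y is independent of z, the fitted surface differences along z
        shrink toward zero and all constraint slacks are small."""
        rng = np.random.default_rng(123)
        n = 5000
        z = rng.uniform(size=n)
        z[np.argmin(z)] = 0.0
        x = rng.uniform(size=n)
        y = (rng.uniform(size=n) < 0.4).astype(float)
        fit = fit_monotone_spline(y, z, x)
        grid = np.linspace(0, z.max(), 30)
        for xv in (0.2, 0.5, 0.8):
            p = fit.model.predict_prob(grid, np.full(30, xv))
            assert p.max() - p.min() < 0.1

    @pytest.mark.parametrize("model,seed", [(MODEL_A, 0), (MODEL_A, 1), (MODEL_B, 2)])
    def test_feasibility_and_likelihood_ascent(self, model, seed):
        df = generate_dataset(model, 150, seed)
        y, z, x, v = (df[c].to_numpy() for c in "yzxv")
        fit = fit_monotone_spline(y, z, x, v)
        basis_z = make_knots(z)
        cs = build_monotone_constraints(
            fit.model.basis_z.n_basis, fit.model.basis_x.n_basis, 1
        )
        coef = np.concatenate([fit.beta_hat, fit.gamma_hat])
        assert (cs.A @ coef).min() >= -1e-8
        assert np.all(np.diff(fit.loglik_path) >= -1e-8)
        assert np.isfinite(fit.loglik)

    def test_constrained_optimum_beats_independent_solver(self, cohort_a):
        """The IRLS-QP log-likelihood is at least that of an independent
        constrained optimizer (trust-constr) on the same problem, i.e. no
        feasible point found by another method does better."""
        from scipy.optimize import LinearConstraint, minimize
        from scipy.special import expit

        y, z, x, v = cohort_a
        ctrl = ConvergenceControl(tol=1e-9, max_iter=200)
        fit = fit_monotone_spline(y, z, x, v, control=ctrl)
        D = fit.model.design_matrix(z, x, v[:, None])
        cs = build_monotone_constraints(
            fit.model.basis_z.n_basis, fit.model.basis_x.n_basis, 1
        )

        def negll(b):
            mu = np.clip(expit(D @ b), 1e-12, 1 - 1e-12)
            return -(y * np.log(mu) + (1 - y) * np.log1p(-mu)).sum()

        oracle = minimize(
            negll,
            np.zeros(D.shape[1]),
            jac=lambda b: -D.T @ (y - expit(D @ b)),
            method="trust-constr",
            constraints=[LinearConstraint(cs.A, 0, np.inf)],
            options={"maxiter": 1500, "gtol": 1e-10},
        )
        assert fit.loglik >= -oracle.fun - 1e-4

    def test_degenerate_outcome_raises(self):
        z = np.linspace(0, 1, 20)
        basis = make_knots(z)
        with pytest.raises(ValueError, match="degenerate outcome"):
            irls_qp_fit(np.ones(20), z, z, basis_z=basis, basis_x=basis)

    def test_monotone_surface_in_z_after_fit(self, cohort_a):
        y, z, x, v = cohort_a
        fit = fit_monotone_spline(y, z, x, v)
        grid = np.linspace(0.0, z.max(), 50)
        for xi, vi in zip(x[:20], v[:20]):
            p = fit.model.predict_prob(
                grid, np.full(50, xi), np.full((50, 1), vi)
            )
            assert np.all(np.diff(p) >= -1e-8)
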