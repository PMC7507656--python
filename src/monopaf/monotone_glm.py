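"""Monotonicity-constrained tensor-product B-spline logistic regression.

The log odds of the binary outcome are modelled as

    logit P(Y=1 | z, x, v) = psi(z)' B phi(x) + v' gamma
                           = (phi(x)' (x) psi(z)') vec B + v' gamma,

where ``psi`` and ``phi`` are clamped B-spline bases for the exposure ``z``
and the confounder ``x``, ``B`` is the P x Q coefficient matrix, and any
additional covariates ``v`` enter additively and linearly on the logit scale.
No separate intercept is used: the tensor basis is a partition of unity and
already spans constants.

Monotonicity of the surface in ``z`` at every ``x`` is enforced through the
sufficient condition that the coefficients are nondecreasing along the
exposure index for every confounder basis index, ``b[p+1,q] >= b[p,q]``:
because ``phi_q >= 0``, the profile coefficients ``c_p(x) = sum_q b[p,q]
phi_q(x)`` are then nondecreasing in ``p``, and B-splines preserve coefficient
monotonicity.  These inequalities form ``A beta >= 0`` with one +1 and one -1
per row.  The maximum likelihood fit under the constraint is computed by
iteratively reweighted least squares in which each weighted least-squares
step is solved as a quadratic program over the constraint cone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._qp import solve_qp
from .splines import BasisDef, KnotSpec, eval_basis, make_knots, tensor_design

__all__ = [
    "ConstraintSet",
    "ConvergenceControl",
    "TensorSplineModel",
    "FitResult",
    "build_monotone_constraints",
    "irls_qp_fit",
    "fit_monotone_spline",
]


@dataclass(frozen=True)
class ConstraintSet:
    """Linear inequalities ``A beta >= 0`` encoding surface monotonicity.

    ``A`` has one row per coefficient difference, entries in {-1, 0, +1}, and
    all-zero columns for any unconstrained extra-covariate coefficients.
    ``directions`` records which predictors are constrained ("z" or "zx").
    """

    A: np.ndarray
    directions: str
    P: int
    Q: int
    extra_dims: int = 0

    @property
    def n_constraints(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class ConvergenceControl:
    """IRLS controls: tolerances, iteration cap, probability clip, ridge."""

    tol: float = 1e-6           # max |beta_new - beta_old| for convergence
    loglik_tol: float = 1e-8    # relative log-likelihood change for convergence
    max_iter: int = 50
    max_halvings: int = 10      # step halvings when a QP step lowers the loglik
    clip: float = 1e-10         # fitted-probability clip when forming weights
    ridge: float = 1e-8         # base ridge added if the Hessian Cholesky fails


def build_monotone_constraints(
    P: int, Q: int, extra_dims: int = 0, constrain_x: bool = False
) -> ConstraintSet:
    """Build the difference constraints for monotonicity in z (optionally x).

    Rows encode ``b[p+1,q] - b[p,q] >= 0`` for p = 0..P-2 and every q
    ((P-1)*Q rows).  With ``constrain_x`` the analogous ``b[p,q+1] - b[p,q]
    >= 0`` rows are appended (P*(Q-1) more).  Columns for the ``extra_dims``
    unconstrained covariate coefficients are zero.
    """
    if P < 2:
        raise ValueError("P must be >= 2: no monotone direction to constrain")
    if Q < 1:
        raise ValueError("Q must be >= 1")
    ncol = P * Q + extra_dims
    rows = []
    for q in range(Q):
        for p in range(P - 1):
            row = np.zeros(ncol)
            row[q * P + p] = -1.0
            row[q * P + p + 1] = 1.0
            rows.append(row)
    directions = "z"
    if constrain_x:
        for q in range(Q - 1):
            for p in range(P):
                row = np.zeros(ncol)
                row[q * P + p] = -1.0
                row[(q + 1) * P + p] = 1.0
                rows.append(row)
        directions = "zx"
    return ConstraintSet(
        A=np.array(rows), directions=directions, P=P, Q=Q, extra_dims=extra_dims
    )


@dataclass
class TensorSplineModel:
    """A fitted (or hypothesized) tensor-spline logistic surface."""

    basis_z: BasisDef
    basis_x: BasisDef
    beta: np.ndarray                      # vec B, length P*Q, column-stacked
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        expected = self.basis_z.n_basis * self.basis_x.n_basis
        if self.beta.size != expected:
            raise ValueError(
                "beta length %d != P*Q = %d" % (self.beta.size, expected)
            )

    @property
    def B(self) -> np.ndarray:
        """Coefficient matrix with B[p, q] = coefficient of psi_p * phi_q."""
        return self.beta.reshape(self.basis_z.n_basis, self.basis_x.n_basis, order="F")

    def design_matrix(
        self, z: np.ndarray, x: np.ndarray, v: np.ndarray | None = None
    ) -> np.ndarray:
        D = tensor_design(eval_basis(self.basis_z, z), eval_basis(self.basis_x, x))
        if self.gamma.size:
            if v is None:
                raise ValueError("model has extra covariates but v not supplied")
            v = np.atleast_2d(np.asarray(v, dtype=float))
            if v.shape[0] != D.shape[0]:
                v = v.T
            D = np.hstack([D, v])
        return D

    def linear_predictor(
        self, z: np.ndarray, x: np.ndarray, v: np.ndarray | None = None
    ) -> np.ndarray:
        coef = np.concatenate([self.beta, self.gamma])
        return self.design_matrix(z, x, v) @ coef

    def predict_prob(
        self, z: np.ndarray, x: np.ndarray, v: np.ndarray | None = None
    ) -> np.ndarray:
        """Fitted probabilities expit(f(z, x) + v'gamma); errors out of range."""
        return expit(self.linear_predictor(z, x, v))


@dataclass
class FitResult:
    """Outcome of a constrained (or unconstrained) IRLS fit."""

    model: TensorSplineModel
    converged: bool
    n_iter: int
    loglik: float
    active_constraints: np.ndarray
    prob_clipped: bool            # any fitted probability hit the clip bounds
    ridge_used: float             # largest Hessian ridge needed across steps
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def beta_hat(self) -> np.ndarray:
        return self.model.beta

    @property
    def gamma_hat(self) -> np.ndarray:
        return self.model.gamma

    def predict_prob(self, z, x, v=None):
        return self.model.predict_prob(z, x, v)


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))


def irls_qp_fit(
    y: np.ndarray,
    z: np.ndarray,
    x: np.ndarray,
    v: np.ndarray | None = None,
    *,
    basis_z: BasisDef,
    basis_x: BasisDef,
    constraints: ConstraintSet | None = None,
    control: ConvergenceControl | None = None,
) -> FitResult:
    """Fit the tensor-spline logistic model by IRLS with QP steps.

    Starting from ``beta = 0`` (probability 1/2 everywhere, feasible for the
    difference constraints), each iteration solves

        min_b  0.5 b'(D'WD)b - (D'W r)'b   s.t.  A b >= 0

    with ``W`` the current variance weights and ``r`` the working response.
    A step that would lower the log-likelihood is halved (up to
    ``control.max_halvings`` times); halving preserves feasibility because the
    constraint cone is convex.  Reaching ``max_iter`` returns
    ``converged=False`` rather than raising.
    """
    control = control or ConvergenceControl()
    y = np.asarray(y, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all y equal %d" % int(y[0]))

    P, Q = basis_z.n_basis, basis_x.n_basis
    extra = 0
    if v is not None:
        v = np.atleast_2d(np.asarray(v, dtype=float))
        if v.shape[0] != y.size:
            v = v.T
        extra = v.shape[1]
    template = TensorSplineModel(
        basis_z=basis_z, basis_x=basis_x, beta=np.zeros(P * Q), gamma=np.zeros(extra)
    )
    D = template.design_matrix(z, x, v)
    ncoef = D.shape[1]

    A = None
    if constraints is not None and constraints.n_constraints:
        A = constraints.A
        if A.shape[1] != ncoef:
            raise ValueError(
                "constraint matrix has %d columns, design has %d"
                % (A.shape[1], ncoef)
            )

    clip = control.clip
    coef = np.zeros(ncoef)
    eta = D @ coef
    mu = np.clip(expit(eta), clip, 1.0 - clip)
    ll = _bernoulli_loglik(y, mu)

    converged = False
    clipped_any = False
    max_ridge = 0.0
    active = np.empty(0, dtype=int)
    lam = np.empty(0)
    n_iter = 0
    ll_path = [ll]
    for n_iter in range(1, control.max_iter + 1):
        w = mu * (1.0 - mu)
        r = eta + (y - mu) / w
        Dw = D * w[:, None]
        G = D.T @ Dw
        a = Dw.T @ r
        try:
            qp = solve_qp(G, a, A, base_ridge=control.ridge)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                "QP step failed at IRLS iteration %d: %s" % (n_iter, err)
            ) from err
        max_ridge = max(max_ridge, qp.ridge)
        lam = qp.lam

        step = qp.x - coef
        new_coef, new_eta, new_mu, new_ll = coef, eta, mu, ll
        t = 1.0
        for _ in range(control.max_halvings + 1):
            cand = coef + t * step
            cand_eta = D @ cand
            raw_mu = expit(cand_eta)
            cand_mu = np.clip(raw_mu, clip, 1.0 - clip)
            cand_ll = _bernoulli_loglik(y, cand_mu)
            if cand_ll >= ll - 1e-10:
                new_coef, new_eta, new_mu, new_ll = cand, cand_eta, cand_mu, cand_ll
                clipped_any = clipped_any or bool(
                    (raw_mu <= clip).any() or (raw_mu >= 1.0 - clip).any()
                )
                break
            t *= 0.5
        else:
            # no halving recovered ascent; keep the previous iterate and stop
            converged = False
            break

        delta = float(np.max(np.abs(new_coef - coef)))
        rel_ll = abs(new_ll - ll) / (abs(ll) + 1.0)
        coef, eta, mu, ll = new_coef, new_eta, new_mu, new_ll
        ll_path.append(ll)
        if delta < control.tol or rel_ll < control.loglik_tol:
            converged = True
            break

    if A is not None:
        # binding = carrying a positive multiplier at the final QP step AND
        # sitting at its bound; zero-slack rows with no force are not binding
        slack = A @ coef
        active = np.flatnonzero((lam > 1e-8) & (slack < 1e-6))

    model = TensorSplineModel(
        basis_z=basis_z,
        basis_x=basis_x,
        beta=coef[: P * Q],
        gamma=coef[P * Q :],
    )
    return FitResult(
        model=model,
        converged=converged,
        n_iter=n_iter,
        loglik=ll,
        active_constraints=active,
        prob_clipped=clipped_any,
        ridge_used=max_ridge,
        loglik_path=np.asarray(ll_path),
    )


def fit_monotone_spline(
    y: np.ndarray,
    z: np.ndarray,
    x: np.ndarray,
    v: np.ndarray | None = None,
    *,
    knot_spec: KnotSpec = KnotSpec(),
    constrain_x: bool = False,
    constrained: bool = True,
    control: ConvergenceControl | None = None,
    cover_z: float | None = None,
) -> FitResult:
    """Convenience front end: knots from the data, then the constrained fit.

    Knots for each predictor are placed at the ``knot_spec`` quantiles of its
    unique observed values.  ``constrained=False`` gives the conventional
    unconstrained B-splines fit on the identical design.  ``cover_z`` extends
    the exposure basis range to contain a fixed reference level so the fit
    can always be evaluated there (needed under resampling).
    """
    basis_z = make_knots(np.asarray(z, dtype=float), knot_spec, cover=cover_z)
    basis_x = make_knots(np.asarray(x, dtype=float), knot_spec)
    extra = 0
    if v is not None:
        varr = np.atleast_2d(np.asarray(v, dtype=float))
        extra = varr.shape[1] if varr.shape[0] == np.asarray(y).size else varr.shape[0]
    constraints = None
    if constrained:
        constraints = build_monotone_constraints(
            basis_z.n_basis, basis_x.n_basis, extra_dims=extra, constrain_x=constrain_x
        )
    return irls_qp_fit(
        y, z, x, v,
        basis_z=basis_z,
        basis_x=basis_x,
        constraints=constraints,
        control=control,
    )
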