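"""Strictly convex quadratic programming under homogeneous linear inequalities.

Solves ``min_x 0.5 x'Gx - a'x  s.t.  Cx >= 0`` for positive-definite ``G``.
The Lagrangian dual of this QP is itself a nonnegatively constrained least
squares problem: with the Cholesky factor ``G = LL'`` and stationarity
``x = G^{-1}(a + C'lam)``, maximizing the dual is

    min_{lam >= 0} || (L^{-1}C') lam + L^{-1}a ||^2,

which the Lawson-Hanson active-set routine (scipy.optimize.nnls) solves
exactly.  Strong duality holds for convex QPs, so the recovered primal point
is the exact constrained minimizer.  A small ridge is added to ``G`` (and
escalated) if the Cholesky factorization fails.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import nnls

__all__ = ["QPResult", "solve_qp"]


class QPResult(NamedTuple):
    x: np.ndarray           # primal solution
    lam: np.ndarray         # dual variables (KKT multipliers), lam >= 0
    active: np.ndarray      # indices with lam > 0 (constraints at their bound)
    ridge: float            # ridge actually added to G (0 if none needed)


def solve_qp(
    G: np.ndarray,
    a: np.ndarray,
    C: np.ndarray | None = None,
    *,
    base_ridge: float = 1e-8,
    max_ridge_tries: int = 6,
) -> QPResult:
    """Minimize ``0.5 x'Gx - a'x`` subject to ``Cx >= 0``.

    Parameters
    ----------
    G
        Symmetric positive-(semi)definite Hessian.  If its Cholesky fails,
        ``ridge * I`` is added with ``ridge`` escalated geometrically.
    a
        Linear term (the gradient of the objective at 0 is ``-a``).
    C
        Constraint matrix, one row per inequality; ``None`` or empty means
        unconstrained.
    """
    G = np.asarray(G, dtype=float)
    a = np.asarray(a, dtype=float)
    n = a.shape[0]

    ridge = 0.0
    c_and_lower = None
    for attempt in range(max_ridge_tries + 1):
        try:
            c_and_lower = cho_factor(
                G + ridge * np.eye(n) if ridge else G, lower=True
            )
            break
        except np.linalg.LinAlgError:
            ridge = base_ridge * (100.0 ** attempt)
    if c_and_lower is None:
        raise np.linalg.LinAlgError("QP Hessian not positive definite even with ridge")

    if C is None or len(C) == 0:
        x = cho_solve(c_and_lower, a)
        return QPResult(x=x, lam=np.empty(0), active=np.empty(0, dtype=int), ridge=ridge)

    C = np.asarray(C, dtype=float)
    L = np.tril(c_and_lower[0])
    # E = L^{-1} C',  f = L^{-1} a
    E = solve_triangular(L, C.T, lower=True)
    f = solve_triangular(L, a, lower=True)
    lam, _ = nnls(E, -f)
    # x = L'^{-1} (E lam + f)
    x = solve_triangular(L.T, E @ lam + f, lower=False)
    active = np.flatnonzero(lam > 0)
    return QPResult(x=x, lam=lam, active=active, ridge=ridge)
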