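"""Univariate B-spline bases with data-driven knots and tensor-product designs.

Knots are placed at quantiles of the *unique* values of each predictor
(quartiles by default), boundary knots are replicated ``degree + 1`` times
(clamped construction), so the basis is a partition of unity on the full data
range.  The bivariate design row for an observation is the Kronecker product
``phi(x)' (x) psi(z)'`` of the two univariate basis rows, matching the
column-stacked (Fortran-order) vectorization of the coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["KnotSpec", "BasisDef", "make_knots", "eval_basis", "tensor_design"]

#: Quartile knot probabilities, the package default.
QUARTILES = (0.0, 0.25, 0.5, 0.75, 1.0)

#: Tertile knot probabilities, the main alternative placement.
TERTILES = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


@dataclass(frozen=True)
class KnotSpec:
    """Quantile probabilities and polynomial degree defining a spline basis.

    Parameters
    ----------
    probs
        Strictly increasing quantile probabilities in [0, 1]; must start at 0
        and end at 1 so the boundary knots span the data range.
    degree
        Polynomial degree of the B-splines (2 = quadratic, the default).
    """

    probs: tuple[float, ...] = QUARTILES
    degree: int = 2

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        if len(probs) < 2:
            raise ValueError("need at least two quantile probabilities")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ValueError("probs must be strictly increasing")
        if probs[0] != 0.0 or probs[-1] != 1.0:
            raise ValueError("probs must start at 0 and end at 1")
        if not (isinstance(self.degree, (int, np.integer)) and self.degree >= 0):
            raise ValueError("degree must be a non-negative integer")


@dataclass(frozen=True)
class BasisDef:
    """A concrete univariate B-spline basis on a fixed knot vector.

    ``knots`` holds the distinct (boundary + interior) knots in the units of
    the predictor; the clamped full knot vector replicates each boundary knot
    ``degree + 1`` times.  ``n_basis`` equals
    ``(number of distinct knots - 1) + degree``.
    """

    knots: tuple[float, ...]
    degree: int
    full_knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        kts = np.asarray(self.knots, dtype=float)
        if kts.size < 2 or np.any(np.diff(kts) <= 0):
            raise ValueError("knots must be at least two strictly increasing values")
        full = np.concatenate(
            [np.repeat(kts[0], self.degree), kts, np.repeat(kts[-1], self.degree)]
        )
        object.__setattr__(self, "knots", tuple(kts))
        object.__setattr__(self, "full_knots", full)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1 + self.degree

    @property
    def lo(self) -> float:
        return self.knots[0]

    @property
    def hi(self) -> float:
        return self.knots[-1]


def make_knots(
    values: np.ndarray,
    spec: KnotSpec = KnotSpec(),
    cover: float | None = None,
) -> BasisDef:
    """Place knots at quantiles of the deduplicated predictor values.

    Quantiles use the linear-interpolation convention.  Coincident quantiles
    are collapsed to a single knot; if collapsing leaves fewer than
    ``degree + 1`` basis functions the basis is too degenerate to use and an
    error is raised.

    Parameters
    ----------
    values
        Observed predictor values (duplicates allowed).
    spec
        Quantile probabilities and degree.
    cover
        Optional point the basis range must contain (the boundary knots are
        extended to it if needed).  Used when the model must be evaluated at
        a fixed reference level — e.g. exposure 0 — that a bootstrap resample
        may not happen to contain.

    Returns
    -------
    BasisDef
        The basis definition with ``n_basis = (#distinct knots - 1) + degree``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty predictor vector")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("degenerate predictor: fewer than 2 distinct values")
    knots = np.quantile(uniq, spec.probs)
    if cover is not None:
        knots[0] = min(knots[0], cover)
        knots[-1] = max(knots[-1], cover)
    knots = np.unique(knots)
    basis = BasisDef(knots=tuple(knots), degree=spec.degree)
    if basis.n_basis < spec.degree + 1:
        raise ValueError(
            "knot collapse left only %d basis functions (< degree + 1 = %d)"
            % (basis.n_basis, spec.degree + 1)
        )
    return basis


def eval_basis(basis: BasisDef, t: np.ndarray) -> np.ndarray:
    """Evaluate all basis functions at the points ``t``.

    Returns the dense n x n_basis matrix of basis values.  Points outside the
    knot range raise (no extrapolation): downstream prediction, including the
    counterfactual evaluation at exposure 0, must stay inside the range the
    basis was built on.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.size and (t.min() < basis.lo or t.max() > basis.hi):
        raise ValueError(
            "evaluation points outside knot range [%g, %g]" % (basis.lo, basis.hi)
        )
    M = BSpline.design_matrix(t, basis.full_knots, basis.degree, extrapolate=False)
    return M.toarray()


def tensor_design(psi_rows: np.ndarray, phi_rows: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product ``phi_i' (x) psi_i'`` of two basis matrices.

    Column ordering is confounder-major: column ``q * P + p`` (0-based) holds
    ``phi_q * psi_p``, so the flattened coefficient vector is the
    column-stacked ``vec B`` with ``B[p, q]`` the coefficient of
    ``psi_p(z) * phi_q(x)``.
    """
    psi_rows = np.asarray(psi_rows, dtype=float)
    phi_rows = np.asarray(phi_rows, dtype=float)
    if psi_rows.ndim != 2 or phi_rows.ndim != 2:
        raise ValueError("basis matrices must be 2-D")
    n = psi_rows.shape[0]
    if phi_rows.shape[0] != n:
        raise ValueError(
            "row-count mismatch: %d vs %d" % (n, phi_rows.shape[0])
        )
    P = psi_rows.shape[1]
    Q = phi_rows.shape[1]
    out = np.einsum("nq,np->nqp", phi_rows, psi_rows)
    return out.reshape(n, Q * P)
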