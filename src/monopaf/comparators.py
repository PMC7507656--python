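"""Baseline PAF estimators: parametric logistic regression and unconstrained
B-splines, plus the censoring transform used when reporting them.

The logistic comparator uses the interaction model
``logit P(Y=1) = b0 + b1 z + b2 x + b3 x z + v'gamma``.  The conventional
B-splines comparator (conB) uses the identical tensor-spline design as the
monotone fit but drops the inequality constraints; its well-known instability
(fitted probabilities numerically 0 or 1 at small n) is surfaced through fit
flags, never hidden.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .monotone_glm import ConvergenceControl, FitResult, fit_monotone_spline
from .splines import KnotSpec

__all__ = ["LogitModel", "fit_logit", "fit_conB", "censor_estimate"]


class LogitModel:
    """Fitted logistic regression with columns {1, z, x, x*z, v...}."""

    def __init__(self, params: np.ndarray, converged: bool, loglik: float):
        self.params = np.asarray(params, dtype=float)
        self.converged = converged
        self.loglik = loglik

    @staticmethod
    def _design(z: np.ndarray, x: np.ndarray, v: np.ndarray | None) -> np.ndarray:
        z = np.asarray(z, dtype=float).ravel()
        x = np.asarray(x, dtype=float).ravel()
        cols = [np.ones_like(z), z, x, x * z]
        if v is not None:
            v2 = np.atleast_2d(np.asarray(v, dtype=float))
            if v2.shape[0] != z.size:
                v2 = v2.T
            cols.extend(v2.T)
        return np.column_stack(cols)

    def predict_prob(
        self, z: np.ndarray, x: np.ndarray, v: np.ndarray | None = None
    ) -> np.ndarray:
        from scipy.special import expit

        return expit(self._design(z, x, v) @ self.params)


def fit_logit(
    y: np.ndarray,
    z: np.ndarray,
    x: np.ndarray,
    v: np.ndarray | None = None,
) -> LogitModel:
    """Maximum-likelihood logistic regression with a z-x interaction.

    Perfect separation is reported as a warning and the coefficients are
    returned as the fitting routine left them.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = LogitModel._design(z, x, v)
    with warnings.catch_warnings():
        warnings.simplefilter("always", PerfectSeparationWarning)
        res = sm.GLM(y, D, family=sm.families.Binomial()).fit()
    return LogitModel(
        params=res.params, converged=bool(res.converged), loglik=float(res.llf)
    )


def fit_conB(
    y: np.ndarray,
    z: np.ndarray,
    x: np.ndarray,
    v: np.ndarray | None = None,
    knot_spec: KnotSpec = KnotSpec(),
    control: ConvergenceControl | None = None,
) -> FitResult:
    """Unconstrained tensor B-spline logistic fit on the monotone fit's design.

    Fitted by the same IRLS engine with an empty constraint set so the two
    approaches differ only in the inequality rows.  Non-convergence or clipped
    probabilities are flagged on the returned :class:`FitResult`.
    """
    return fit_monotone_spline(
        y, z, x, v, knot_spec=knot_spec, constrained=False, control=control
    )


def censor_estimate(paf: float) -> float:
    """Censor a raw PAF estimate at 0 (if negative) or 1 (if above 1).

    NaN propagates as missing.
    """
    return float(np.clip(paf, 0.0, 1.0))
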