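"""Plug-in estimation of the population attributable fraction (PAF).

The PAF of an exposure Z for a binary outcome Y is the proportion of cases
that would be eliminated if the exposure were removed,

    PAF = 1 - P(Y0 = 1) / P(Y = 1),

where Y0 is the potential outcome with the exposure set to its reference
level (0 by default).  Under ignorable treatment assignment given the
measured covariates, the sample plug-in estimator averages, over observed
cases only, one minus the ratio of the fitted probability at the reference
exposure to the fitted probability at the observed exposure.  Confidence
intervals are percentile bootstrap: the full estimation pipeline (including
knot selection) is refitted on each resample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate

__all__ = ["PafEstimate", "estimate_paf", "bootstrap_ci", "true_paf"]

# denominators below this signal a numerically collapsed fit (probabilities
# indistinguishable from 0), for which the ratio estimator is meaningless
_DENOM_FLOOR = 1e-12


@dataclass
class PafEstimate:
    """A PAF point estimate with optional percentile-bootstrap interval."""

    point: float
    n_cases: int
    in_unit_interval: bool
    ci_low: float | None = None
    ci_high: float | None = None
    boot_reps: np.ndarray | None = None
    n_boot_failed: int = 0
    n_boot_out_of_range: int = 0
    level: float | None = None

    def to_dict(self) -> dict:
        d = {
            "point": self.point,
            "n_cases": self.n_cases,
            "in_unit_interval": self.in_unit_interval,
        }
        if self.ci_low is not None:
            d.update(
                ci_low=self.ci_low,
                ci_high=self.ci_high,
                level=self.level,
                n_boot=int(self.boot_reps.size),
                n_boot_failed=self.n_boot_failed,
                n_boot_out_of_range=self.n_boot_out_of_range,
            )
        return d


def estimate_paf(
    model,
    y: np.ndarray,
    z: np.ndarray,
    x: np.ndarray,
    v: np.ndarray | None = None,
    exposure_ref: float = 0.0,
) -> PafEstimate:
    """Plug-in PAF from any fitted model exposing ``predict_prob(z, x, v)``.

    Over the cases (y = 1) only,

        PAF_hat = mean_i [ 1 - P_hat(Y=1 | Z=ref, x_i, v_i)
                             / P_hat(Y=1 | Z=z_i, x_i, v_i) ].

    No censoring is applied here; ``in_unit_interval`` records whether the
    raw estimate landed in [0, 1].
    """
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    cases = y == 1.0
    n_cases = int(cases.sum())
    if n_cases == 0:
        raise ValueError("no cases (y = 1) in the data; PAF undefined")

    zc = z[cases]
    xc = x[cases]
    vc = None
    if v is not None:
        v2 = np.atleast_2d(np.asarray(v, dtype=float))
        if v2.shape[0] != y.size:
            v2 = v2.T
        vc = v2[cases]

    p_obs = np.asarray(model.predict_prob(zc, xc, vc), dtype=float)
    p_ref = np.asarray(
        model.predict_prob(np.full(n_cases, float(exposure_ref)), xc, vc), dtype=float
    )
    if np.min(p_obs) < _DENOM_FLOOR:
        raise ValueError(
            "unstable fit: fitted case probability below %g" % _DENOM_FLOOR
        )
    terms = 1.0 - p_ref / p_obs
    # roundoff guard: a monotone fit guarantees each term >= 0 in exact
    # arithmetic, but a surface flat in z evaluates p_ref and p_obs through
    # different basis rows and can differ by machine epsilon; snap only those.
    terms[(terms < 0.0) & (terms > -1e-9)] = 0.0
    point = float(np.mean(terms))
    return PafEstimate(
        point=point,
        n_cases=n_cases,
        in_unit_interval=bool(0.0 <= point <= 1.0),
    )


def bootstrap_ci(
    y: np.ndarray,
    z: np.ndarray,
    x: np.ndarray,
    v: np.ndarray | None,
    estimator: Callable[..., float],
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    max_fail_frac: float = 0.2,
) -> PafEstimate:
    """Percentile-bootstrap CI for a PAF estimation pipeline.

    ``estimator(y, z, x, v) -> float`` must run the *entire* pipeline on the
    sample it is given — including recomputing knots — and return the raw
    (uncensored) point estimate.  Rows are resampled with replacement ``B``
    times; the interval is the empirical (1-level)/2 and 1-(1-level)/2
    quantiles of the successful replicates.  Replicates whose refit raises
    are dropped and counted; more than ``max_fail_frac`` failures aborts.
    Out-of-[0,1] replicates are counted but never clamped.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    varr = None
    if v is not None:
        varr = np.atleast_2d(np.asarray(v, dtype=float))
        if varr.shape[0] != y.size:
            varr = varr.T
    n = y.size

    point = float(estimator(y, z, x, varr))

    reps = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            est = float(
                estimator(y[idx], z[idx], x[idx], None if varr is None else varr[idx])
            )
        except Exception:
            n_failed += 1
            continue
        reps.append(est)
    if n_failed > max_fail_frac * B:
        raise RuntimeError(
            "bootstrap aborted: %d of %d refits failed" % (n_failed, B)
        )
    reps = np.asarray(reps)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return PafEstimate(
        point=point,
        n_cases=int((y == 1.0).sum()),
        in_unit_interval=bool(0.0 <= point <= 1.0),
        ci_low=float(lo),
        ci_high=float(hi),
        boot_reps=reps,
        n_boot_failed=n_failed,
        n_boot_out_of_range=int(((reps < 0.0) | (reps > 1.0)).sum()),
        level=level,
    )


def true_paf(
    prob_fn: Callable[[float, float, float], float],
    z_support: tuple[float, float] = (0.0, 1.0),
    x_support: tuple[float, float] = (0.0, 1.0),
    v_values: Sequence[float] = (0.0, 1.0),
    v_probs: Sequence[float] = (0.5, 0.5),
    exposure_ref: float = 0.0,
    epsabs: float = 1e-9,
) -> float:
    """Population PAF of a known probability model by numerical integration.

    Computes ``1 - E[prob_fn(ref, X, V)] / E[prob_fn(Z, X, V)]`` with Z and X
    independent uniform on their supports and V discrete with the given
    probabilities (default Bernoulli(1/2)).  Expectations use adaptive
    quadrature with absolute tolerance well below 1e-6.
    """
    z0, z1 = z_support
    x0, x1 = x_support
    if not np.isclose(sum(v_probs), 1.0):
        raise ValueError("v_probs must sum to 1")

    num = 0.0
    den = 0.0
    for vv, pv in zip(v_values, v_probs):
        n_int, _ = integrate.quad(
            lambda x: prob_fn(exposure_ref, x, vv), x0, x1, epsabs=epsabs
        )
        num += pv * n_int / (x1 - x0)
        d_int, _ = integrate.dblquad(
            lambda x, zz: prob_fn(zz, x, vv), z0, z1, x0, x1, epsabs=epsabs
        )
        den += pv * d_int / ((x1 - x0) * (z1 - z0))
    if den <= 0.0:
        raise ValueError("overall event probability is non-positive")
    return 1.0 - num / den
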