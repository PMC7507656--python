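# Methods

## The estimand

The population attributable fraction (PAF) of a continuous exposure Z for a
binary outcome Y is the proportion of cases that would be eliminated if the
exposure were removed,

    PAF = 1 − P(Y₀ = 1) / P(Y = 1),

where Y₀ is the potential outcome with Z set to the reference level (0 by
default).  Identification requires that all confounders of the
exposure–outcome relationship are measured: given the measured covariates,
the counterfactual risk at Z = 0 equals the observed risk among the
unexposed (ignorable treatment assignment).  Under that assumption the PAF
can be written as an average over the diseased subpopulation,

    PAF = E[ 1 − P(Y=1 | Z=0, X, V) / P(Y=1 | Z=z, X, V) | Y = 1 ],

and the plug-in estimator replaces the conditional probabilities with fitted
values and averages over the observed cases.  Two properties follow
immediately: the estimate is a case-weighted average of terms 1 − p₀/p₁,
each of which lies in [0, 1] exactly when the fitted probability is
nondecreasing in the exposure; and any non-monotone fit can push terms below
0, producing nonsensical negative PAF estimates.

## The probability model

The disease probability surface is modelled semiparametrically on the logit
scale as a tensor product of univariate quadratic B-splines in the exposure
z and an interacting confounder x:

    logit P(Y=1 | z, x, v) = ψ(z)′ B φ(x) + v′γ
                           = (φ(x)′ ⊗ ψ(z)′) vec B + v′γ.

* ψ and φ are clamped B-spline bases (boundary knots replicated degree+1
  times), degree 2 by default, with knots at the quartiles
  {0, ¼, ½, ¾, 1} of the *unique* observed values of each predictor
  (linear-interpolation quantiles).  Five distinct knots and degree 2 give
  P = Q = 6 basis functions per margin.  Tertiles or any other probability
  vector can be configured.
* The tensor basis is a partition of unity, so it spans constants and no
  separate intercept is used (one would be collinear).
* Any further covariates v enter additively and linearly on the logit scale,
  unconstrained.  This is the simplest adjustment consistent with the
  benchmark mechanisms, where v is a binary nuisance covariate with an
  additive effect; a user needing flexible adjustment in v can expand v into
  basis columns before fitting.
* Evaluation outside the knot range is an error, not an extrapolation: the
  counterfactual term needs P̂ at z = 0, so 0 must lie inside the exposure
  basis range.  Under bootstrap resampling a resample can lose all
  zero-exposure rows, so the refitting pipeline extends the boundary knot to
  the reference level (`cover_z`); knot *placement* remains data-driven.

## Monotonicity constraints

Monotonicity of the surface in z at every x is imposed through the
sufficient condition that coefficients are nondecreasing along the exposure
index for every confounder basis index:

    b[p+1, q] − b[p, q] ≥ 0   for p = 1..P−1, q = 1..Q,

written as A β ≥ 0 with one +1 and one −1 per row and zero columns for γ.
Because φ_q ≥ 0, the profile coefficients c_p(x) = Σ_q b[p,q] φ_q(x) are
then nondecreasing in p, and B-splines preserve coefficient monotonicity, so
the fitted surface is nondecreasing in z at every x.  The condition is
sufficient, not necessary: there exist monotone surfaces whose coefficients
are not monotone, so the feasible set is a (slightly) conservative cone.
Constant surfaces are feasible with zero slack.

The same construction optionally adds b[p, q+1] − b[p, q] ≥ 0 (monotone in
x as well).  The simulation benchmark fits the monotone estimator under
*both* constraints, because every benchmark mechanism is nondecreasing in
both predictors — the same substantive assumption motivating the method in
the intended applications, where risk is believed monotone in both scales.
The double constraint matters in practice: with only the z-constraint, the
confounder-boundary coefficients are weakly identified at small n, fitted
probabilities at sparse corners collapse toward 0, and the PAF estimate
acquires a pronounced upward bias.

## Fitting: IRLS with quadratic-programming steps

The Bernoulli log-likelihood is maximized subject to A β ≥ 0 by iteratively
reweighted least squares in which each weighted least-squares step is solved
as an inequality-constrained quadratic program

    min_β ½ β′(D′WD)β − (D′W r)′β   s.t.  A β ≥ 0,

with D the design (tensor columns plus v columns), W the current variance
weights μ(1−μ), and r the working response η + (y−μ)/W.

Each QP is solved exactly through its Lagrangian dual: with the Cholesky
factor G = LL′ of the Hessian, the dual is the nonnegative least-squares
problem min_{λ≥0} ‖(L⁻¹A′)λ + L⁻¹a‖², solved by the Lawson–Hanson
active-set algorithm; the primal solution is recovered from stationarity.
Strong duality holds for convex QPs, so this is exact, and it is verified in
the test suite against an independent SLSQP solve and against a
bound-reparameterized least-squares oracle on the monotone cone.

Numerical choices:

* start at β = 0 (probability ½ everywhere; feasible, since constant
  surfaces have zero slack);
* fitted probabilities are clipped to [1e−10, 1−1e−10] when forming weights
  and the log-likelihood (clipping is reported via a `prob_clipped` flag —
  relevant mainly for the *unconstrained* comparator, which is known to
  saturate at small n);
* a step that would lower the log-likelihood is halved, up to 10 times;
  halving preserves feasibility because the cone is convex;
* convergence when max |Δβ| < 1e−6 or the relative log-likelihood change is
  below 1e−8, capped at 50 iterations; hitting the cap returns
  `converged=False` rather than raising;
* if the Hessian Cholesky fails, a ridge starting at 1e−8·I is added and
  escalated geometrically.

Near-separated data put the MLE at infinity along feasible rays; the clipped
likelihood plateaus there, the iteration stops on the likelihood criterion,
and the reported optimum attains a log-likelihood at least as high as an
independent constrained optimizer (tested).  Fitted probabilities, and hence
the PAF, are stable along such rays even though individual coefficients are
not.  `active_constraints` reports the rows carrying a positive multiplier
at the final QP step.

## PAF estimation and the bootstrap

The plug-in estimate averages 1 − P̂(Y=1|Z=0, xᵢ, vᵢ)/P̂(Y=1|Z=zᵢ, xᵢ, vᵢ)
over cases.  No censoring is applied; an `in_unit_interval` flag records
whether the raw value landed in [0, 1].  A denominator below 1e−12 raises an
"unstable fit" error — that only occurs when an unconstrained fit has
numerically collapsed.  One floating-point guard exists: a fit exactly flat
in z evaluates the two probabilities through different basis rows, so terms
can land at −1e−16; terms in (−1e−9, 0) are snapped to 0.  Genuinely
negative estimates (from non-monotone fits) are orders of magnitude larger
and pass through untouched.

Confidence intervals are percentile bootstrap: rows are resampled with
replacement, the entire pipeline — knot selection included — is refitted on
each resample, and the interval is the 2.5%/97.5% quantiles of the replicate
estimates (1000 replicates by default).  Replicates whose refit raises are
dropped and counted; more than 20% failures aborts.  Out-of-[0,1] replicates
are counted but never clamped, so the interval honestly reflects an unstable
estimator.

The population PAF of a known mechanism (`true_paf`) is computed by adaptive
quadrature of the ratio of expectations over the stated covariate
distributions (absolute tolerance well below 1e−6), and is cross-checked in
the tests against a 10⁷-draw Monte-Carlo estimate.

## Comparators

* `logit`: maximum-likelihood logistic regression with columns
  {1, z, x, x·z, v}, via statsmodels.  The covariate set mirrors the
  parametric interaction model the semiparametric surface generalizes; v
  enters as a linear main effect.
* `conB`: the identical tensor-spline design fitted by the same IRLS engine
  with an empty constraint set, so the two fits differ only in the
  inequality rows.  Its instability at small n (saturated probabilities,
  non-convergence) is surfaced via flags.
* `censor_estimate`: clamps a raw estimate to [0, 1]; idempotent,
  order-preserving, NaN-propagating.  Used only when reporting the
  unconstrained comparators.

## The simulation benchmark

Mechanisms (Z, X independent Uniform[0,1]; V ~ Bernoulli(½); the smallest
exposure draw replaced by exactly 0 so the reference level is always in
sample):

| Mechanism | success probability                  | population PAF |
|-----------|--------------------------------------|----------------|
| A         | 0.1 + 0.4z + 0.3x − 0.2xz + 0.2v     | 0.3000         |
| B         | 2(0.1 + 2·log(z/2+1))·x/3 + 0.3v     | 0.4404         |
| C         | 0.8·√(z+0.1)·x² + 0.1v               | 0.4616         |

All three probabilities are specified directly on the probability scale (so
every estimator's logit-scale model is misspecified to some degree) and are
nondecreasing in both z and x.  The generator emulates a cross-sectional
cohort with a continuous exposure, one interacting confounder and one binary
covariate; it does not emulate measurement error, missingness, discrete
bounded scales (the intended applications often use integer questionnaire
scores), or dependent sampling — conclusions from passing tests transfer to
real data only insofar as those features are absent or handled upstream.

The study grid crosses mechanism × sample size (100, 200) × estimator, all
estimators seeing the same replicates.  Reported per cell: the proportion of
raw estimates inside [0, 1]; and |bias|, variance and MSE of the raw and the
censored estimates against the mechanism's population PAF.  Variance uses
the population convention (divide by the replicate count) so that
MSE = bias² + variance holds exactly on the same replicate vector.
Replicates where an estimator fails outright are excluded from that
estimator's moments and counted.  Per-replicate RNG streams are derived from
the master seed and a (mechanism, sample-size, replicate) counter, so runs
are reproducible and cells are independent of which estimators are enabled.

The default test suite and the verification runs use 100–200 replicates per
cell rather than 1000; at 200 replicates the Monte-Carlo standard error of a
cell's MSE is roughly 6% of its value, which is the resolution quoted
wherever those runs are compared against reference values.  The full
1000-replicate grid is available through `monopaf simulate --reps 1000`.

## Known limitations

* The coefficient-difference cone is sufficient but not necessary for
  monotonicity; fits are mildly conservative relative to the exact monotone
  function class.
* The monotone estimator's PAF carries a finite-sample upward bias driven by
  underestimation of the counterfactual probability at the exposure
  boundary; it shrinks with n and with the double constraint but does not
  vanish.
* Inference is bootstrap-only; no asymptotic standard errors are provided
  for the constrained fit.
* Single continuous exposure, logit link, Bernoulli outcomes only.
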