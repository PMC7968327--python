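# Methods

## Model and assumptions

`rshift` fits linear confirmatory factor models with mean structure to
two-occasion questionnaire data.  Observed scores stack both occasions
into one p = 16 vector; the implied moments are

    Sigma(theta) = Lambda Phi Lambda' + Theta,     mu(theta) = tau + Lambda kappa

where `Lambda` (16 x 4) holds the loadings of the eight scales on
GenPHYS and GenMENT at each occasion, `Theta` the residual variances plus
the declared residual covariances (each scale with itself across
occasions; RP–RE within occasions, two role-limitation scales with
overlapping wording), `Phi` the factor covariance matrix and `kappa` the
factor means.  Scores are treated as continuous and, for maximum
likelihood, multivariate normal; SF-36 scale scores are bounded and
discrete in reality, which is why a robust scaled chi-square is offered
(below).

Identification fixes factor means at 0 and variances at 1 at *both*
occasions in the unconstrained model.  When loadings (and intercepts)
become invariant across occasions, the occasion-2 factor variances (and
means) are freed instead — the only convention consistent with the
88 → 108 degrees-of-freedom transition of the model sequence.

`Phi` is parameterized as log-standard-deviations plus correlations
(internally `atanh`-transformed), so the step-4 constraint "equal factor
correlations at both occasions despite unequal variances" is a plain
linear parameter equality.  Residual variances are optimized on the log
scale, which prevents Heywood crashes by construction.  Equality classes
share one free coordinate, so constraints hold exactly.

## Estimation

The discrepancy is the normal-theory ML fit function with mean structure,

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p + (m - mu)' Sigma^-1 (m - mu),

minimized over the free coordinates with analytic gradients; the
chi-square convention is T = (n - 1) F (Wishart likelihood; at n = 203
the difference from n·F is immaterial and the cross-check against the
lava R package bridges the conventions explicitly).  Optimization runs
L-BFGS-B followed by a Newton polish using a finite-difference Hessian of
the analytic gradient; convergence requires a gradient infinity-norm
below 1e-8 (configurable), with anything below 1e-5 — which perturbs T in
the 1e-10 range — still accepted as converged.  A fit warm-started from a
neighboring model that stalls is retried from the documented default
starting values (loadings = indicator SD, intercepts = indicator mean,
residual variances = half the indicator variance, correlations = 0.3) and
the better solution kept.  Standard errors come from the inverse observed
information, delta-transformed to the reporting scale.

**Robust scaling.**  With raw data the distribution-free fourth-moment
covariance `Gamma` of the sample moment vector is estimated and the
scaling factor c = tr(U Gamma)/df computed, with U the residual weight of
the ML estimator at the solution; under exact normality c = 1 (verified
analytically in the tests).  Scaled difference tests use the
Satorra–Bentler construction cd = (df0 c0 - df1 c1)/(df0 - df1),
TRd = (T0 - T1)/cd; a negative TRd is reported with a warning and not
rejected, and cd <= 0 is flagged as a strict-correction failure.  When
only moments are supplied, MLR falls back to c = 1 with a logged notice.

**Modification indices** are 1-df score tests: with the full-coordinate
gradient G and observed information H at the restricted solution, the
statistic for adding direction d to the model space is
(n-1)/2 · (d'G)² / (d'Hd − d'HA (A'HA)⁻¹ A'Hd), where A spans the current
free directions.  For small violations this approximates the chi-square
drop of an actual refit (asserted in the tests); the expected parameter
change is the corresponding Newton step.  Observed (not expected)
information is a documented choice.

## The 4-step procedure

Defaults follow the published analysis: overall alpha 0.05; step-3
release tests at 0.05/8 = 0.00625 (Bonferroni over the eight scales —
the printed convention, not the number of tested constraints; the
denominator is configurable); step-4 factor-level tests at unadjusted
0.05.  Step 3 exhausts equality releases (loadings, intercepts, residual
variances) before considering occasion-2 cross-loading additions
(reconceptualization candidates); each phase stops at the first
non-significant top candidate, and a reverted candidate is never retried.
Step 4 tests correlation invariance (one within-occasion equality), then
variance invariance jointly across factors, then mean invariance per
factor — the per-factor mean tests double as the significance tests of
adjusted change.

## Fit indices

CFI, TLI, SRMR (covariance-based, means excluded — the conventional
variant; a mean-inclusive alternative was considered and not adopted
because the acceptance thresholds quoted for the procedure refer to the
covariance SRMR) and RMSEA with a 90% CI from inverting the noncentral
chi-square in its noncentrality parameter.  The gate applies the strict
inequalities CFI, TLI > 0.9, SRMR < 0.1, RMSEA < 0.08.  When a scaling
factor is active the indices use the scaled statistic; both statistics
are retained in the report.

## Effect sizes

For scale j on factor f, the occasion-1 model-implied SD
(`sqrt(lambda_j² psi_f + theta_j)`) standardizes the Model-4 parameter
differences: adjusted change = lambda_j·d_kappa_f / SD; RS effect =
(d_tau_j + d_lambda_j·kappa_f(t2)) / SD, which is zero for invariant
intercepts and loadings and identically zero at group level for
non-uniform recalibration; observed change = RS + adjusted by
construction.  The occasion-1 implied SD is the default because it
reproduces the published SF decomposition (RS ≈ 0.36, adjusted ≈ −0.10,
observed ≈ 0.26) from the final-model estimates; pooled and
observed-sample SD conventions are config options.  Factor-level effect
sizes standardize d_kappa by the occasion-1 factor SD (= 1).  No simple
convention reproduces the 0.37/−0.21 factor-level values quoted in the
source analysis from its own parameter table; the documented convention
yields 0.234/−0.165 and the discrepancy is left visible rather than
tuned away.  Cohen anchors: |d| ≥ 0.2/0.5/0.8 small/medium/large.

## Synthetic-data generator

`default_generating_model()` is the published final-model solution read
forward as a data-generating process: shared loadings (17.557, 29.074,
13.761, 18.159, 14.339, 12.508, 12.664, 13.713), occasion-1 intercepts
and residual variances as printed, an SF intercept of 87.290 at
follow-up (uniform recalibration of +7.241), RP/BP follow-up residual
variances 492.01/125.94, factor means (0, 0, +0.234, −0.165), variances
(1, 1, 1.136, 0.781) and the printed 4 x 4 factor correlation matrix
(positive definite, smallest eigenvalue 0.0097).  Residual covariances
are not printed in the source table; they default to zero in the
generator but stay free in every fitted model, so recovery targets do not
depend on invented values.  `inject_rs` plants additional effects of any
of the four RS types at occasion 2, composably.

Two caveats inherited from the source table: the RP *pre-test* residual
variance is printed as 77.51 although the surrounding discussion says RP
and BP residual variances decreased at follow-up (492.01 would contradict
that; the printed value may have lost a digit).  The generator follows
the table as printed and the value is overridable.  Second, data are
multivariate normal (optionally scaled-t via `simulate_scaled_t` to
exercise the robust path) and unbounded; real scale scores are bounded
0–100, discrete, and skewed.  `truncate_to_scale_range` exists for
bounded-realism demonstrations but is off by default because clamping
breaks the normality the ML fit assumes.  Passing tests on this generator
therefore demonstrates correctness of the procedure's logic and
estimation, not robustness to the distributional quirks of real SF-36
data.

## Calibration properties

Under the no-RS generator (Gaussian, ML estimator, 500 seeded
replicates):

* at n = 203, no single constraint is falsely released more often than
  0.00625 plus binomial noise — the per-candidate rate the Bonferroni
  correction targets.  The *family-wise* probability of at least one
  false release is ≈ 17%, as expected when a max-modification-index
  search scans ~40 candidates at a per-test alpha of 0.05/8; the
  correction controls per-candidate, not family-wise, error.
* the 20-df overall difference test rejects at 4.2% at n = 1000 but
  ≈ 8% at n = 203: the likelihood-ratio difference is mildly
  anticonservative when 64 parameters are estimated from 203
  observations, a finite-sample property of the statistic itself (the
  engine's chi-square matches the independent lava implementation to
  five decimals on such draws), not an implementation artifact.

Monte-Carlo problem sizes in the test suite (500 replicates at n = 203
and n = 1000; 60-replicate unbiasedness probes; 200k-row
law-of-large-numbers checks) were chosen to keep the full suite in the
minutes range while leaving the binomial noise bands meaningful.

## Degenerate inputs and edge behavior

Saturated (0-df) models return T = 0 and no scaling factor; the
independence baseline is a factorless model (free means and variances);
non-positive-definite regions of the parameter space are penalized rather
than crashed into; a non-converged fit refuses downstream difference
tests; empty datasets, sub-minimum sample sizes (default 100), missing
columns and non-numeric cells raise typed errors naming the offender.
Incomplete rows are dropped (complete-case analysis, tally logged);
out-of-range values warn but are retained.

## Limitations

Two occasions only; no missing-data FIML; no ordinal/categorical
estimators (WLSMV) or bootstrap standard errors; no multi-group models
for predictors of response shift; group-level detection only — individual
appraisal processes are outside scope.  The modification-index variant
and chi-square convention of other SEM software differ in details, so
third-party results may differ in the second or third decimal even on
identical data.
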