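# Methods

## The problem

Two-wave panel studies of burnout/exhaustion commonly fit a cross-lagged
panel model (CLPM) and read the adjusted lagged path — the effect of a
predictor at wave 1 on the outcome at wave 2, adjusting for the outcome at
wave 1 — as evidence of a prospective, often implicitly causal, effect.
That path is vulnerable to a well-known artifact: if the measured wave-1
outcome contains a residual that is correlated with the predictor, and
residuals regress toward zero between occasions, the adjusted lagged effect
can be nonzero with no direct effect at all.

This package implements a *scrutiny* pipeline for such claims.  Because
standardized regression effects are functions of correlations alone, a
claimed effect can be reanalyzed from nothing but the study's sample size
and the six pairwise correlations among predictor and outcome at two waves
(P1, P2, E1, E2): simulate standardized data matched to those correlations,
fit four complementary structural models, and ask whether their focal
effects tell a mutually consistent causal story.

## The four models

All models are fitted to the same n x 4 (or n x 3) standardized data by
normal-theory maximum likelihood.

**A — CLPM** (saturated, df = 0).  E2 ~ P1 + E1 and P2 ~ P1 + E1, with free
exogenous covariance P1–E1 and residual covariance P2–E2.  Focal path:
P1 → E2.  Its population value in terms of correlations is

    beta_A = (r_P1E2 - r_P1E1 * r_E1E2) / (1 - r_P1E1^2).

**B — reversed CLPM** (saturated over P1, E1, E2).  E1 ~ P1 + E2.  Under a
genuine prospective effect, conditioning on the *future* outcome should
flip the sign of the predictor's coefficient; a same-signed B is the first
red flag.  beta_B applies the formula above with the outcome waves
exchanged.

**C — latent change score model** (saturated, df = 0).  E2 = E1 + dE and
P2 = P1 + dP with unit fixed loadings and zero wave-2 residuals; dE ~ P1
and dP ~ E1.  The change disturbances covary freely with each other and
with their own construct's wave-1 score.  Under this parameterization the
standardized focal effect P1 → dE equals the difference-score regression

    beta_C = (r_P1E2 - r_P1E1) / sqrt(2 * (1 - r_E1E2)).

A genuine increasing effect should make beta_C positive (decreasing:
negative); an opposite-signed beta_C is the second red flag.  A
`proportional_change=True` variant replaces the disturbance–baseline
covariances with explicit change-on-baseline regressions (same saturated
fit, different focal interpretation); it is off by default because the
difference-score form is the quantity the verdict logic reasons about.

**D — artifactualness model** (df = 6).  No direct predictor–outcome paths:
P1/P2 load on a construct factor gP and E1/E2 on gE (all loadings fixed to
1), gP and gE load on a single second-order "general negativity" factor
gNeg (the gE loading fixed to +1 or −1 according to the sign of the
observed wave-1 cross-correlation), and same-occasion scores share one
state covariance.  Free parameters (4): var(gNeg), one indicator residual
variance per construct (equality-constrained within construct), and the
state covariance.  Good fit of this model shows the data are *compatible*
with a process that has no direct effects.  The df of 6 is also what the
reported (chi-square, N, RMSEA) pairs of the misfitting rows back-calculate
to; alternative 4-parameter patterns can be supplied as `SemSpec` JSON
without code changes.

## Verdict rule

The qualitative expectations are operationalized as (alpha = 0.05, CFI
cutoff 0.95, both configurable):

* `consistent_with_genuine` — A significant, sign(B) = −sign(A), C
  significant with sign(C) = sign(A);
* `artifactual_pattern` — A significant, sign(B) = sign(A), C
  non-significant or opposite-signed, and model D's CFI at or above the
  cutoff;
* `inconclusive` — everything else, including the hedged borderline case
  of a significant A with a non-significant same-signed C.

The rule is deterministic given the fitted estimates, invariant to
recoding the predictor as −P, and deliberately speaks of a *pattern*: good
fit of model D shows compatibility with a no-direct-effect process, not
proof of one, and a genuine effect combined with strong exogenous baseline
correlation can itself mask the time-reversal sign flip (see the
counterexample test in `tests/test_synthetic.py`).

## Simulation

`sample_mvn` draws zero-mean multivariate-normal data.  In **exact** mode
the draws are whitened by their own sample covariance factor and recolored
by the Cholesky factor of the target, so the sample correlation matrix
(denominator-n convention) equals the target to ~1e-15 and every column has
mean 0, SD 1.  Standardized effects are then deterministic functions of the
target matrix — re-running with another seed changes fitted effects by less
than 1e-8 — which is what makes a correlation-matched reanalysis equivalent
to having the original data for every standardized quantity.  **stochastic**
mode draws i.i.d. rows and is used for the Monte-Carlo experiments, where
sampling variability is the point.  No missing values are generated.

## The ML engine

Models are held in RAM form (path matrix A, covariance matrix S, observed
selector F); Sigma(theta) = F (I−A)^{-1} S (I−A)^{-T} F'.  The discrepancy
log|Sigma| + tr(S_sample Sigma^{-1}) − log|S_sample| − p is minimized by
BFGS with analytic gradients (dSigma assembled from the RAM derivative
dB = B dA B).  Numerical choices:

* **Convergence**: largest absolute unscaled-parameter change between
  iterations < 1e-4, or gradient max-norm < 1e-8; iteration cap 1000;
  non-convergence raises after two deterministic jittered restarts.
* **Start values**: 0.1 for paths and covariances, 0.5 x mean diagonal of
  the sample matrix for variances; overridable per label.
* **Positive definiteness**: variance-type parameters (labels appearing
  only on the S diagonal) are log-transformed during iteration; a non-PD
  Sigma evaluates to +inf and the line search backtracks.
* **Chi-square**: n x F_min (normal-likelihood convention; `"n-1"`
  available).  The sample covariance uses denominator n consistently, so
  exact-mode standardized data hand the optimizer the correlation matrix
  itself.
* **Standard errors**: expected information,
  Info = (n/2) tr(Sigma^{-1} dSigma_k Sigma^{-1} dSigma_l), inverted at the
  optimum; a rank-deficient information matrix raises an identification
  error.  All 95% CIs are Wald intervals (±1.96 SE); the CI-construction
  behind the original tables is unstated, and coverage of the Wald choice
  is verified by simulation (93–97% at n = 1000).
* **Standardization of focal effects** uses the fitted model's implied
  variances (delta-method SEs over the full parameter covariance), so
  exact and stochastic data share one code path; for the LCSM this divides
  the raw path by the implied SD of the latent change, sqrt(2(1 − r_E1E2)).
* **Fit indices**: CFI/TLI against the analytic independence baseline
  (chi2_b = −n log det R), both truncated at 1; RMSEA =
  sqrt(max(chi2 − df, 0)/(df n)) with the 90% CI from inverting the
  noncentral chi-square cdf in the noncentrality parameter; SRMR over the
  p(p+1)/2 unique standardized residuals including the diagonal (dialects
  differ; this one is fixed and documented).  RMSEA/TLI are reported as NaN
  for saturated models.

## Synthetic truth models

`GenuineDGP` is a linear-Gaussian two-wave process: P2 and E2 are generated
from (P1, E1) through stability and cross paths, residual variances solved
in closed form for unit total variances, so implied correlations are exact.
Defaults: stabilities 0.5, true prospective effect cross_pe = 0.2, no
reverse effect, and exogenous wave-1 correlation r0 = 0.  The r0 = 0
default isolates the causal mechanism: the lagged formula recovers cross_pe
for any r0, but the time-reversal sign flip is guaranteed only when the
baseline association is itself produced by the causal path (the reversed
numerator r0(1 − cp² − se² − se·cp·r0) − cp·se turns positive once r0
exceeds roughly cp·se/(1 − cp² − se²)).  That boundary is itself tested.

`ArtifactualDGP` is model D as a generator: defaults var_gneg = 0.3,
residuals 0.7 (unit variances without rescaling; other values are
standardized analytically), state covariance 0.1, giving cross-construct
correlations of 0.3/0.4 and stabilities of 0.3 — within the range typical
of self-report predictor–outcome panels.  Its true direct effect is zero,
yet the population CLPM focal effect is ~0.21: the artifact, available in
closed form.

`recovery_experiment` pushes stochastic replicates of either DGP through
the full scrutiny pipeline and reports bias/RMSE of the CLPM focal effect,
Wald-CI coverage, spurious-significance and verdict rates, and mean model-D
fit.  What these simulations do *not* emulate: non-normal marginals,
missing data, measurement non-invariance across waves, more than two waves
per fitted model, or covariate adjustment as practiced in the original
studies — so passing recovery tests validates the pipeline's logic under
its own assumptions, not any claim about a particular real dataset.

## Problem sizes and reproducibility

The oracle-agreement check uses 1000 random positive-definite correlation
matrices at n = 200 (exact mode); the two recovery experiments use 500
stochastic replicates at n = 1000, sizes at which verdict rates are stable
to a percentage point or two across seeds.  All randomness flows through
explicit integer seeds; exact-mode results are bit-reproducible.

## Known limitations

* The embedded descriptive table carries the printed integer percentages
  and rounded ages; means computed from it can differ in the last decimal
  from means of the unrounded source values (49.17 vs 49.1 for % male,
  36.6 vs 36.4 for age).
* The six correlations per reanalyzed study are not embedded (they are not
  printed; they live in the study's public deposit) — the pipeline runs on
  user-supplied or synthetic correlations.
* Robust/scaled test statistics, mean structures, missing-data estimation
  and categorical indicators are out of scope.
* A verdict is a consistency pattern among fallible models, not a causal
  discovery procedure.
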