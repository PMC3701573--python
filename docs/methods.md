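# Methods

`exglyc` implements a complete development-and-validation pipeline for a
predictive model of the acute change in blood glucose with a bout of
exercise in adults with type 2 diabetes on oral medication. The outcome is
`delta = post_glucose − pre_glucose` in mmol/L, measured with
self-monitoring glucometers. This note records the models, the numerical
choices, and the limits of what the synthetic cohort can demonstrate.

## The prediction model

The core model is a linear mixed model over repeated exercise sessions
*j* of subjects *i*:

    delta_ij = x_ij' beta + b0_i + b1_i * pre_ij + eps_ij,
    (b0_i, b1_i) ~ N(0, G),  eps_ij ~ N(0, sigma^2)

with a random intercept per subject always, and (when the structure tests
support it) a random slope on pre-exercise glucose — subjects differ both
in their baseline response and in how strongly their starting glucose
drives the drop. An alternative structure, random intercepts over the
levels of a between-subject covariate (e.g. HbA1c) crossed with the
subject intercepts, is supported for the structure tests.

Candidate fixed effects are the twelve session/subject covariates:
pre-exercise glucose (mmol/L), minutes since the last meal (linear), a
non-linear transform of those minutes, the postprandial dummy
(≤ 120 min), HbA1c (%), exercise duration (min), mean heart rate as % of
the age-adjusted maximum (220 − age), sulfonylurea and metformin dummies,
age, session number, and sex.

### The minutes-since-eating transform

For minutes `t ≤ 180` the transform is `sin(pi * t / 180)` — a half-sine
rising to 1 at 90 min and back to 0 at 180 min, mimicking the postprandial
insulin excursion. For `t > 180` it declines linearly to −1 at `t_max`,
the longest fast observed in the data in scope, representing growing
counter-regulatory (glycogenolytic) influence. Design choices worth
recording:

* The sine branch operates on `t/180`, not raw minutes: a sine of raw
  minutes times pi would oscillate with a 2-minute period, which cannot be
  the intended physiology. With `t/180 ∈ [0, 1]` the "normalize to 0–1"
  step is the identity.
* The fasting branch is anchored at 180 (not at the smallest observed
  value above 180) so the two branches meet continuously at zero.
* `t_max` is recomputed from each training set during validation. A test
  session whose fast exceeds the training `t_max` is capped at the −1
  floor; a dataset with no fast beyond 180 min falls back to a 420-min
  anchor so the branch stays defined.

## Estimation: ML via EM

All mixed models are fit by maximum likelihood (not REML): the pipeline
leans on likelihood-ratio tests across different fixed-effect sets and on
BIC, both of which need comparable ML log-likelihoods.

The EM treats the stacked random effects `b` as missing data. Each
iteration computes the posterior mean/covariance of `b` (E-step), updates
`G`, the extra-grouping variance, and `sigma^2` in closed form (M-step),
and updates `beta` by GLS — every step ascends the marginal likelihood, so
the log-likelihood trace is non-decreasing, and this is asserted on every
fit. Plain EM is notoriously slow near variance boundaries, so the default
step is parameter-expanded EM (PX-EM): the complete-data model is expanded
with a working linear map on the random effects, the M-step solves for the
fixed effects and the working map jointly, and the reduction step folds the
map back into `G`. PX-EM retains EM's monotonicity and typically converges
in tens of iterations where plain EM needs thousands; when its normal
equations are singular (variances at the floor) the code falls back to the
plain EM step.

Numerical choices: convergence at relative log-likelihood change `1e-8`,
at most 500 iterations (`converged` flag otherwise); variances floored at
`1e-10`; all n×n algebra avoided via Woodbury / matrix-determinant-lemma
identities (cost per iteration O(q^3 + n·q) for q random effects). On
exactly noiseless data the residual variance hits its floor and the
likelihood diverges; iteration then stops at the floor rather than
asserting monotonicity against float noise. With a single training subject
(possible in the smallest validation folds) the fit proceeds with a
warning; the variance components are then barely identified but the
predictions remain defined.

Likelihood-ratio tests for random structure use the naive chi-square with
df = parameter-count difference. For variance components on the boundary
this is conservative (the correct reference is a chi-bar-square mixture);
the null-calibration test asserts conservatism only, and df is reported so
either convention can be audited.

## Variable selection: mixed-effects LASSO

Selection minimizes `−loglik(beta, theta) + lambda * sum |beta_j|` over
the *penalized* candidates, with pre-exercise glucose, %AAMHR, and
duration forced (unpenalized) as previously established predictors. Block
coordinate descent alternates exact soft-thresholding updates for `beta`
(the negative log-likelihood is quadratic in `beta` given the variance
parameters) with EM updates for the variance parameters run to partial
convergence — a single EM sweep per cycle stalls near variance boundaries.
Predictors are standardized to unit variance internally (the L1 penalty is
scale-sensitive); coefficients are reported on the original scale.

The penalty is parameterized in Lagrangian form rather than as an explicit
constraint on the coefficient-norm budget; both trace the same path. The
grid starts at the smallest multiple of 0.1 (on the standardized scale) at
which the penalized support is empty — estimated from the stationarity
condition at the forced-only fit and verified by fitting — and decreases
in 0.1 decrements to exactly 0, with warm starts. BIC counts nonzero
fixed effects + variance parameters + 1 (residual). The BIC-minimizing
support (ties to the sparser model) is refit unpenalized ("relaxed") for
reporting, since shrunken coefficients are not comparable with the
importance estimates presented beside them.

## Relative importance: LMG

LMG attributes the OLS R² to individual predictors by averaging each
predictor's sequential R² contribution over all orderings of entry.
Because ordinary R² ignores repeated measures, shares are computed on
first-session rows only — one independent row per subject. The
all-orderings average is computed exactly over subsets (2^p regressions
instead of p! orderings); shares sum to the full-model R² and this
identity is asserted on every call. Predictors constant across first
sessions (session number, by construction) carry no share. Bootstrap 95%
percentile intervals resample subjects (the exchangeable unit) with
replacement, 1000 replicates by default; degenerate replicates (constant
outcome) are skipped and counted.

## Validation against glucometer error

A prediction is *accurate* when it differs from the actual change by no
more than the regulatory accuracy band of self-monitoring meters at the
measured post-exercise value: ±0.83 mmol/L when that value is below
4.2 mmol/L, ±20% of it otherwise. The band is anchored on the actual
post-exercise measurement (the quantity the predicted change implies), and
ties at the band edge count as within error. Exactly 4.2 mmol/L uses the
20% branch ("below 4.2" strict).

* **Leave-one-out CV** is leave-one-*session*-out: each session is
  predicted from a refit on all other sessions, so the held-out subject's
  remaining sessions still inform its random effects — the only reading
  compatible with subject-level prediction, and the analogue of the
  prospective protocol.
* **Prospective validation** refits, for every subject × session, on that
  subject's strictly earlier sessions plus all sessions of all other
  subjects, and predicts the session of interest. First sessions get the
  population prediction. The refits warm-start from the same subject's
  previous-session fit — a function of strictly earlier data only — so the
  no-leakage guarantee (deleting any future session leaves a prediction
  bit-identical) holds exactly, and is asserted in the tests. The selected
  support and random structure are fixed from development; coefficients
  are re-estimated per training set.

Summaries: accuracy overall and by prandial state (the overall rate is
exactly the prediction-weighted combination of the two), the utility count
(subjects with ≤1 error among sessions numbered above 3; subjects with no
such sessions count vacuously and are logged), and per-subject absolute
error distributions (median, quartiles by midpoint interpolation, 1.5·IQR
whiskers), sorted by median absolute error with ties broken by subject id.
An alternative sort by within-subject SD of pre-exercise glucose supports
the supplementary view. Variance explained on the test set uses the
marginal/conditional R² decomposition for mixed models, computed from an
intercepts-only refit because the decomposition is not defined under
random slopes.

## Post-hoc error model

A mixed-effects logistic regression asks who the model errs for: outcome =
model error, covariates sex, metformin, and the rolling within-subject SDs
of pre- and post-exercise glucose over strictly earlier sessions (sessions
with fewer than two prior sessions are excluded rather than imputed), plus
a random intercept per subject. The marginal likelihood integrates the
intercept by adaptive Gauss–Hermite quadrature, 15 nodes by default: per
subject the nodes are shifted to the posterior mode (Newton; the log-joint
is strictly concave) and scaled by the Laplace curvature. Estimates are
stable from 15 to 31 nodes to better than 1e-3, and the implementation
reproduces lme4's `glmer(nAGQ=15)` log-likelihood to full printed
precision on a shared simulation. Continuous covariates are mean-centered
and SD-scaled, so odds ratios are per 1-SD change for an otherwise average
individual; dummies are centered but kept on their natural scale. CIs are
Wald on the log-odds scale from a numerical Hessian. A coefficient
exceeding 15 on the standardized scale triggers a separation error rather
than a meaningless estimate.

## The synthetic cohort generator

The generator is the package's test bed: it emulates the *statistical*
structure of a pooled exercise-trial cohort, not glucose physiology.

Subject covariates are truncated normals / Bernoullis with defaults set to
the development cohort's published marginals: age 54.3 (7.9) years, HbA1c
7.1 (1.8) % (truncated above 3), 67.8% male, 60.7% metformin, 69.6%
sulfonylurea. Each subject carries a habitual pre-exercise glucose mean
(9.5 mmol/L overall, between-subject SD 2.6) and a within-subject SD
(mean 1.8), and a random intercept/slope pair drawn jointly. Sessions are
independent given the subject: meal timing is a two-component uniform
mixture — `U(10, 120)` minutes with weight 0.803 (the postprandial
fraction), else `U(121, 420)` — which guarantees both prandial states and
spans the published mean ± SD; duration is N(44.7, 14.6) truncated above
5 min; %AAMHR N(72.5, 3.7) truncated to (30, 100); pre-exercise glucose
truncated above 0.5 mmol/L. A second preset
(`prospective_cohort_config`) carries the test cohort's marginals (36%
postprandial, lower glycemia, 93.6% metformin, 38.3% sulfonylurea,
shorter and slightly more intense sessions, 47 subjects).

The outcome model applies the published fixed-effect coefficients
(pre-exercise glucose −0.46, minutes since eating 0.002, non-linear
minutes −0.1, postprandial 1.2, HbA1c 0.24, duration −0.024, sulfonylurea
−0.2, age −0.004, session number −0.06; sex and metformin 0). The %AAMHR
coefficient is 0.0183 per percentage point: the published value of 1.83
can only be physiologic on the proportion (0–1) scale, since 1.83 per
percentage point would imply a ±7 mmol/L swing per SD of heart-rate
intensity. The fixed intercept is 0, which already yields a mean drop of
≈1.9 mmol/L per session at the default covariates.

No variance components are published, so the defaults were calibrated once
against the quantities that are: fixed effects explaining roughly
two-thirds and fixed-plus-subject effects roughly three-quarters of
outcome variance, and a clearly significant random slope on pre-exercise
glucose (likelihood ratio of order 30 at 56 subjects × ~9 sessions).
This gives residual SD 1.05 mmol/L, random-intercept SD 2.0 mmol/L,
random-slope SD 0.25, and intercept–slope correlation −0.9. The strong
negative correlation is deliberate: it makes the subject-level variance
`Var(b0 + b1·pre)` smallest near the cohort's mean glycemia and larger at
the extremes, which is both how random-slope heterogeneity presents in
longitudinal glycemia data and the only way to keep total between-subject
variance physiologic while the slope variance is genuinely detectable.
Post-exercise glucose is floored at 0.3 mmol/L so measured values stay
positive.

Optional measurement noise perturbs pre- and post-exercise glucose
independently, uniform on the meter accuracy band of the true value —
the band is all that is specified for such meters, and uniform is the
maximum-entropy choice on a bounded interval. The switch defaults to off:
the emulated measurements are what a meter would report already, and the
switch exists to study the sensitivity of accuracy metrics to meter error.

What the generator does **not** emulate: insulin and meal-composition
dynamics, within-subject correlation of meal timing or duration across
sessions (sessions are exchangeable given the subject), exercise-type
differences (aerobic vs resistance), medication changes over time, and
any genuine association between subject attributes and model error —
so a near-unit odds ratio from the post-hoc error model on synthetic data
is the expected, honest outcome, and passing tests demonstrate correctness
of the machinery, not clinical performance on real cohorts.

## Problem sizes and scenario configs

The test suite exercises each property at the smallest size where it is
informative: parameter recovery at 100 subjects × 8 sessions; null
calibration of the random-slope test with 1000 replicates of 15 × 5;
selection behavior over 20 seeded runs at 56 subjects × 9 sessions;
cross-validation limits at 15 × 4 over a 4-point residual-noise grid. The
selection-power scenario (`selection_stress_config`) amplifies the
nl-minutes and HbA1c effects and lowers the noise because the property
under test is that *strong* effects are found; the null scenario zeroes
every penalized coefficient. Both are named scenario configs, distinct
from the cohort defaults. `scripts/acceptance.py` runs the full
development (56 subjects) and test (47 subjects) workflows at the
emulated cohorts' actual sizes.

## Known limitations

* The chi-square reference for boundary variance tests is conservative;
  no chi-bar-square correction is applied.
* The LASSO penalty scale depends on sample size (the objective is the
  summed, not averaged, negative log-likelihood), so penalty values are
  not transferable across datasets; only the selected support and the
  BIC-minimization behavior are.
* The LMG step is exact but exponential in the number of predictors
  (capped at 15).
* Prospective refits fix the selected support; selection is not re-run
  per training set.
* The logistic error model fits no random slopes and performs no
  selection over its covariates.
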