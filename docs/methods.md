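# Methods

## Setting and model

The package targets the standard attrition problem in multi-wave cohorts: a
baseline survey enrolls *n* participants with a mixed set of categorical and
continuous covariates, and at each later wave some fraction fails to
respond. Participation at wave *k* is modelled as a Bernoulli outcome with

    logit P(continue_i) = β₀ + β' X_i ,

fit by maximum-likelihood logistic regression on baseline covariates only —
dropout is assumed to depend on observed baseline information (a
missing-at-random-style assumption; informative dropout driven by
unobserved factors is out of reach of any reweighting built from baseline
data). Respondents receive the stabilized weight `sw_i = p̄/p̂_i` with `p̄`
the marginal continuation proportion. The numerator is unconditional: a
conditional (covariate-dependent) numerator is only needed when weights are
combined across time or with treatment weights, which this package does not
do (single-wave weights, re-fit per wave).

### Variable preparation

Penalized screening and the participation fits consume a fully categorical,
fully observed design: continuous candidates are cut into interval
categories (default: quintiles of the observed distribution,
user-overridable cutpoints) and item missingness is recoded into an
explicit `missing` level per variable. Intervals are half-open `[a, b)`
with the final interval closed, so a value at a cutpoint lands in the upper
bin. The missing-category device keeps every participant in the model —
important because prediction is needed for *all* baseline participants,
including those who later dropped out — at the cost of the usual caveats
about categorization (information loss) and missing-indicator methods
(potential bias when missingness is informative for the covariate effect).

### Selection arms

*Curated*: the investigator-supplied list is validated against the
dictionary and used verbatim; the packaged default list has 18 entries.

*LASSO screening*: per context theme, an L1-penalized logistic regression
(dummy-encoded predictors, centered and scaled to unit variance so
coefficient magnitudes are comparable) is tuned by stratified 10-fold
cross-validation over a 12-point log-spaced penalty grid, selecting the
penalty with minimum mean CV deviance (not the 1-SE rule). Variables are
scored by the maximum absolute coefficient over their levels — one
influential level retains the whole variable — and ranked; zero-scored
variables are dropped; ties break by dictionary order. A forward pass
starts from the top three (all, if fewer) and adds the next-ranked variable
one at a time, comparing the new in-sample AUROC with the previous model's
by the two-sided paired DeLong test; the first addition with p > 0.05 is
**excluded** and the pass stops. Exclude-and-stop rather than
include-and-stop is a genuine judgment call — a non-significant ROC change
is read as "this variable did not help", so it is left out. The ROC gate is
evaluated in-sample, which is optimistic; with candidate sets this small the
practical effect is limited, but it is a known source of optimism. Theme
winners are pooled into one LASSO whose penalty is re-tuned by CV, and the
surviving variables enter the final unpenalized fit. An all-zero pooled fit
falls back to an intercept-only model with a warning.

### Diagnostics

Discrimination: AUROC computed as the Mann–Whitney probability (ties count
half), with variance and the paired-comparison test from DeLong's
structural components; CIs are plain normal intervals clipped to [0, 1] (no
logit transform). Calibration: Hosmer–Lemeshow over deciles of predicted
risk (ties to the lower bin; degenerate bins merged into a neighbor with a
warning; df = effective bins − 2), mean calibration (equal to the observed
rate by the score equation for any ML logistic fit with intercept evaluated
on its training data — used as an exact test), and a lowess-smoothed
calibration curve (span 0.75 by default; smoothing affects plots only,
never selection). The lowess fit is evaluated at the data points and
interpolated onto an even grid, which is robust to heavily tied
predictions.

### Weights and balance

Weights are computed for **all** baseline participants; analyses consume
the responder subset. Truncation clamps to the empirical 0.5th/99.5th
percentile bounds of the full weight vector (linear-interpolation
quantiles; the convention is configurable because the count of altered
weights at this sample size — typically ~1% of n — is sensitive to it).
One-sided truncation is available via `low_pct=0`.

Balance is measured by the absolute standardized difference, with
categorical variables summarized by the maximum over level-wise
dichotomies (conservative; the multivariate Mahalanobis variant is out of
scope) and complete cases per variable. The weighted comparison weights
continuers by `p̄/p̂` and drop-outs by the mirror `(1−p̄)/(1−p̂)`: both
groups are then reweighted toward the baseline covariate distribution, and
under a saturated participation model the weighted difference is exactly
zero — an identity the test suite asserts. Weighting only the continuers
(available as `mode="responders_only"`) cannot drive the between-group
difference below roughly `p̄` times its unweighted value even with a
perfect model, because the comparison group remains shifted; it is provided
for sensitivity analysis, not as the performance criterion. Percentages are
reported to one decimal.

## Synthetic cohort generator

The generator defines the study conditions for every test and for the
acceptance script. Defaults: n = 3,351 participants; 127 baseline variables
allocated across the seven themes (24/15/12/14/22/22/18), mixing named
survey-style variables (education, income, home ownership, maternal age,
depression score, cigarettes per day, …) with filler variables; 15
variables carry the `demographic` role and enter the balance table. Each
variable loads on its theme's shared standard-normal factor with loading
0.4, inducing realistic within-theme correlation; categorical variables
(2–6 levels) arise by thresholding the latent at fixed marginal
probabilities; item missingness is injected completely at random at
per-variable rates drawn uniformly from [0, 4.4%].

Dropout is covariate-driven: five variables — education, income, maternal
age, depression score, cigarettes per day — carry nonzero effects on the
participation logit (level effects for categorical drivers, standardized
slopes for continuous ones), with magnitudes chosen once so that the
unweighted maximum standardized difference across the demographic variables
averages in the 25–30% band at the default sample size. Attrition is
monotone by default (a participant lost at one wave stays lost; returning
participants can be enabled by flag), and the per-wave intercept is found
by bisection (tolerance 1e-4 on the expected rate) so marginal continuation
hits 59.4% at the first follow-up and 55/50/45% of baseline at the three
later waves — the later-wave targets are plausible placeholders, not
literature values, and are config-overridable. The generating mechanism is
stored verbatim alongside the data for parameter-recovery tests.

What the generator does *not* emulate: the marginal distributions of real
survey instruments, informative (missing-not-at-random) item missingness,
non-monotone response patterns, twins/multiple births, or
administrative shocks to single waves. Passing tests therefore demonstrate
that the pipeline behaves correctly when its assumptions hold — dropout
driven by observed baseline covariates through a logistic mechanism — not
that weighting removes bias in any particular real cohort.

## Numerical choices

* Penalized fits: scikit-learn `LogisticRegressionCV` (liblinear, L1,
  neg-log-loss scoring); fold assignment stratified and seeded, so results
  are bit-reproducible given the seed. Constant design columns are dropped
  with a logged warning.
* Unpenalized fits: statsmodels GLM/Binomial; on non-convergence or
  separation (non-finite or absurdly large coefficients) the fit falls back
  to a ridge-stabilized logistic regression (L2, C = 100) with a warning.
* Degenerate predicted probabilities: weights refuse p̂ = 0 anywhere and
  p̂ = 1 for an actual drop-out (both would produce infinite weights);
  p̂ = 1 for an all-responding stratum of a saturated model is legitimate
  and accepted.
* Seeds: a single run seed fans out to stage seeds by fixed offsets, so
  pipeline stages can be re-run in isolation; every stochastic routine
  takes an explicit seed.

## Problem sizes used in the test suite

The suite exercises the full default scenario (n = 3,351, 127 variables)
for the end-to-end properties, an 8-seed replicate set for the
selection-recovery regression (all five true drivers retained in ≥ 80% of
seeds; one seed typically misses education), n = 50,000 with a compact
13-variable dictionary for parameter recovery (within 3 SE), and
10,000-replicate paired bootstraps as the oracle for the DeLong test.
Majority-vote simulation checks use 5–7 seeds.

## Known limitations

* The ROC-gated forward pass is evaluated in-sample and the gate's
  stopping semantics (exclude-and-stop) is one of two defensible readings.
* The Hosmer–Lemeshow p-value of the final in-sample fit can be modestly
  significant at this sample size because the selected model slightly
  overfits its own selection data; calibration-in-the-large is exact by
  construction.
* Balance of rare categorical levels (prevalence of a few percent) is noisy
  at n ≈ 3,000; weighted standardized differences of 5–9% on such levels
  are mostly sampling noise, which is why the conventional 10% threshold —
  not zero — is the criterion.
* Continuous dropout drivers are modelled through their quintile
  categories; the residual within-bin imbalance is small but nonzero.
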