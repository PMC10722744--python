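# attriweight

Non-response (inverse-probability-of-participation) weights for longitudinal
cohorts with attrition.

Prospective cohorts lose participants over time, and when dropout is driven
by baseline characteristics the respondents at later waves no longer
resemble the sample that was enrolled — a recipe for selection bias in any
downstream exposure–outcome analysis. One remedy is to model each
participant's probability of continuing from baseline covariates and weight
the respondents by the inverse of that probability, so that people who
resemble the drop-outs count for more. This package implements that whole
workflow for epidemiologists and biostatisticians working with multi-wave
cohort data: variable preparation, two variable-selection arms, logistic
participation models with discrimination/calibration diagnostics,
stabilized truncated weights, and standardized-difference balance checks —
plus a synthetic multi-wave pregnancy-cohort generator so the pipeline can
be exercised and tested end to end without access to restricted cohort
data.

## The model

For wave *k*, let `Y_i = 1` if participant *i* continues and let `X_i` be
their baseline covariates. A logistic participation model

    logit P(Y_i = 1 | X_i) = β₀ + β'X_i

yields predicted probabilities `p̂_i`, and each respondent receives the
**stabilized weight**

    sw_i = p̄ / p̂_i,

where `p̄` is the marginal continuation proportion. Stabilization keeps the
responder-mean near 1 with smaller variance than the raw `1/p̂_i` weights;
weights are truncated at the empirical 0.5th/99.5th percentiles to cap the
influence of extreme values.

Two ways of choosing `X` are supported:

* **curated (a-priori)** — investigators supply the list; no data-driven
  filtering;
* **LASSO screening** — baseline variables are grouped into seven context
  themes (sociodemographic, pregnancy history, conception history, prenatal
  care, lifestyle/health-care use, mental health/social support, substance
  use); within each theme an L1-penalized logistic regression with 10-fold
  cross-validation screens candidates, variables are ranked by largest
  standardized dummy coefficient, and a forward pass (starting from the top
  three) keeps adding the next-ranked variable while the model AUROC changes
  significantly under the paired DeLong test. Theme winners are pooled into
  one final LASSO, whose survivors enter an unpenalized ML logistic fit.

Weight performance is judged by the absolute standardized difference

    d = (m₁ − m₀) / sqrt((s₁² + s₀²)/2)

of each demographic variable between continuers and drop-outs (levels of
categorical variables as dichotomies, summarized by the max), with and
without weights; |d| < 10% is conventionally negligible. In the weighted
comparison continuers carry `p̄/p̂` and drop-outs the mirror
`(1−p̄)/(1−p̂)`, so both groups are reweighted toward the baseline
distribution and a saturated model balances them exactly.

## Worked example

```python
from attriweight import (GeneratorConfig, ParticipationModel, generate_cohort,
                         prepare_for_modelling)

# default synthetic scenario: n = 3,351, 127 baseline variables,
# covariate-driven monotone dropout over four waves (3y/5y/8y/covid)
table, specs, truth = generate_cohort(GeneratorConfig(seed=1))
ptable, pspecs = prepare_for_modelling(table, specs)

res = ParticipationModel.from_lasso_selection(ptable, pspecs, "3y", seed=1).fit()
disc = res.discrimination()
print(f"AUROC {disc.auroc:.2f} (95% CI {disc.ci_low:.2f}-{disc.ci_high:.2f})")

ws = res.weights()                       # stabilized, truncated at 0.5/99.5
print(ws.summary()["before_truncation"], ws.n_altered)

rep = res.balance()                      # standardized differences, %
print(f"unweighted max {rep.max_abs('unweighted'):.1f}% -> "
      f"weighted max {rep.max_abs('lasso'):.1f}%")
```

Output:

```
AUROC 0.69 (95% CI 0.67-0.71)
{'mean': 1.0, 'sd': 0.32, 'min': 0.63, 'max': 4.45} 34
unweighted max 24.7% -> weighted max 8.1%
```

The selection recovers all five variables that truly drive dropout in the
simulated cohort (education, income, maternal age, depression score,
cigarettes per day) among 14 retained variables; discrimination is fair
(AUROC 0.69), the stabilized weights average 1.00, truncation touches 34 of
3,351 weights, and weighting pulls the worst demographic imbalance from
~25% down to ~8% — below the 10% negligibility threshold at every one of
the four waves (`res.balance()` / `multiwave_balance`).

A command-line surface mirrors the library:

```sh
attriweight simulate --n 3351 --seed 1 --out sim/
attriweight run --seed 1 --out runs/demo        # full pipeline, both arms
```

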