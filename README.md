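# exglyc

Development and validation of a predictive model of the **acute blood-glucose
response to exercise in type 2 diabetes**, as a tested, reusable Python
pipeline.

Moderate exercise acutely lowers blood glucose in most adults with type 2
diabetes, but by how much varies with the person, their medication, how
recently they ate, and how hard and long they exercise. A model that
predicts the change for *this person, this session* — from data they
already have (last HbA1c, a pre-exercise finger-stick, a watch heart
rate) — could make self-management concrete: "a 40-minute walk now will
likely drop you by about 2 mmol/L." `exglyc` implements the full
statistical workflow such a model needs, end to end, exercised on a
seeded synthetic cohort generator so every stage is testable without
access to trial data.

## The model and the workflow

The outcome is the per-session glucose change `Δ = post − pre` (mmol/L),
modelled with a linear mixed model over subjects' repeated sessions:

    Δ_ij = x_ij'β + b0_i + b1_i · pre_ij + ε_ij,
    (b0_i, b1_i) ~ N(0, G),   ε_ij ~ N(0, σ²)

The pipeline stages, each an importable module:

| stage | module | method |
|---|---|---|
| synthetic cohorts | `exglyc.cohort` | seeded generative model of subjects, sessions, outcomes |
| features | `exglyc.features` | non-linear minutes-since-eating transform, prandial dummy, %AAMHR, design matrix |
| mixed models | `exglyc.lmm` | ML via (parameter-expanded) EM; LR tests; BIC; marginal/conditional R²; BLUP prediction |
| selection | `exglyc.lasso` | mixed-effects LASSO with forced predictors, 0.1-decrement penalty grid, BIC choice |
| importance | `exglyc.importance` | exact LMG R² decomposition, subject-resampling bootstrap CIs |
| validation | `exglyc.validation` | glucometer-error accuracy bands, leave-one-session-out CV, prospective per-session protocol |
| error model | `exglyc.error_model` | logistic mixed model of prediction error (adaptive Gauss–Hermite) |
| orchestration | `exglyc.pipeline`, `exglyc.cli` | `develop` / `test` workflows, artifacts, seeds, `exglyc` console script |

A prediction counts as *accurate* when it is within the self-monitoring
glucometer accuracy band of the truth: ±0.83 mmol/L when measured glucose
is below 4.2 mmol/L, ±20% otherwise — errors smaller than the meter's own
error are not meaningful to a user.

## Worked example

Generate a cohort and ask whether subjects differ in their sensitivity to
pre-exercise glucose (`examples/02_fit_mixed_model.py`):

```python
from exglyc import (CANDIDATE_PREDICTORS, CohortConfig, RandomSpec, build_design,
                    fit_lmm, generate_cohort, likelihood_ratio_test, r2_nakagawa)

subjects, sessions = generate_cohort(CohortConfig(seed=1))
design = build_design(sessions, subjects, CANDIDATE_PREDICTORS)
intercepts = fit_lmm(design)
slopes = fit_lmm(design, RandomSpec(slope_terms=("pre_glucose",)))
lr, df, p = likelihood_ratio_test(intercepts, slopes)
marginal, conditional = r2_nakagawa(intercepts)
```

The full script (`examples/02_fit_mixed_model.py`) prints, for this
56-subject, 453-session cohort:

```
random slope for pre-exercise glucose: LR = 44.7, df = 2, p = 1.9e-10
variance explained: fixed effects 48.5%, fixed + subject effects 74.7%
```

The likelihood-ratio test says subject-specific slopes on pre-exercise
glucose clearly improve fit — people differ in how strongly their starting
glucose drives the drop — and the fixed effects alone explain about half
the outcome variance, rising to three-quarters once subject effects are
included. The fitted pre-glucose coefficient is ≈ −0.45: each extra
mmol/L of starting glucose predicts an extra ~0.45 mmol/L drop.

The `examples/` directory walks through every capability one script at a
time: cohort simulation, model fitting and structure tests, LASSO
selection, LMG importance, prospective validation, and the post-hoc error
model. The same workflows are available from a shell:

```bash
exglyc simulate --seed 1 --out sessions.csv
exglyc develop  --input sessions.csv --out dev/
exglyc test     --input test.csv --model dev/model.yaml --out test_out/
```

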