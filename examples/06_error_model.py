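"""Post-hoc model of who the predictions fail for.

After prospective validation, fits a mixed-effects logistic regression of
model error (prediction outside the meter band) on sex, metformin status,
and the rolling within-subject SDs of pre- and post-exercise glucose.
Odds ratios are per 1-SD change for an otherwise average individual.
"""

from exglyc import ModelSpec, generate_cohort, prospective_validate
from exglyc.cohort import prospective_cohort_config
from exglyc.error_model import fit_logistic_glmm, rolling_sd_features

subjects, sessions = generate_cohort(prospective_cohort_config(seed=2))
spec = ModelSpec(predictors=("pre_glucose", "minutes_since_meal", "nl_minutes",
                             "postprandial", "hba1c", "duration", "pct_aamhr"))
report = prospective_validate(sessions, subjects, spec)

features = rolling_sd_features(sessions)
key = ["subject_id", "session_number"]
records = report.records.merge(features[key + ["sd_pre", "sd_post"]], on=key)
records = records.merge(subjects[["subject_id", "sex", "metformin"]], on="subject_id")

fit = fit_logistic_glmm(records)

print(f"fit on {fit.n_obs} predictions from {fit.n_subjects} subjects "
      f"(sessions with <2 prior sessions excluded)")
print(f"random-intercept variance: {fit.random_intercept_variance:.3f}\n")
print("odds of a model error (95% Wald CI):")
print(fit.to_frame().round(2).to_string())
print("\nAn odds ratio above 1 for sd_pre means individuals with more variable"
      " pre-exercise glucose are harder to predict.")
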