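"""Generate a synthetic exercise cohort and inspect its structure.

Draws 56 subjects with type 2 diabetes and their repeated exercise
sessions from the default generative model, then prints the cohort
marginals (these should sit near the configured means) and the first few
session rows.
"""

from exglyc import CohortConfig, generate_cohort

config = CohortConfig(seed=1)
subjects, sessions = generate_cohort(config)

print(f"{len(subjects)} subjects, {len(sessions)} exercise sessions\n")
print("subject-level marginals (mean):")
print(subjects[["age", "hba1c", "glucose_mean"]].mean().round(2).to_string())
print(f"male fraction: {(subjects['sex'] == 'male').mean():.2f}")
print(f"postprandial fraction: {(sessions['minutes_since_meal'] <= 120).mean():.2f}\n")
print("first session rows:")
print(sessions.head(3).round(2).to_string(index=False))
print("\nMean glucose change with exercise:"
      f" {(sessions['post_glucose'] - sessions['pre_glucose']).mean():.2f} mmol/L"
      " (a typical acute exercise-induced drop).")
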