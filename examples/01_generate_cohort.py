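"""Generate a synthetic smart-scale cohort and inspect its ground truth.

The generator emulates free-living self-weighing: ~40% of days measured,
multi-week breaks, diurnal variation, slow drift coupled to adherence, and
three classes of contamination with exact per-record labels.
"""

from selfweigh import emulate_cohort_profile, generate_cohort

config = emulate_cohort_profile(seed=1, n_users=50)
records, profiles, truth = generate_cohort(config)

print(f"users: {len(profiles)}, records: {len(records)}")
print(f"label counts:\n{truth.labels['label'].value_counts().to_string()}")
frac_break = (truth.users['n_breaks'] >= 1).mean()
print(f"users with >=1 break of >=30 days: {100 * frac_break:.1f}%")
print(f"BMI groups:\n{truth.users['bmi_group'].value_counts().to_string()}")

# Every record carries exactly one label, so cleaning recovery can be scored
# exactly; 'clean' rows are the truth the pipeline must preserve.
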