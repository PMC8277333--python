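"""Derive the study variables from a cleaned cohort.

Per user: follow-up, initial/final weight (first/last 7-day means of daily
minima), weight change, self-weighing frequency, BMI group and breaks;
per consecutive pair of measurements: day gap, weight change per day,
frequency category and morning/evening combination.
"""

from selfweigh import emulate_cohort_profile, generate_cohort, run_pipeline

records, profiles, _ = generate_cohort(emulate_cohort_profile(seed=3, n_users=50))
result = run_pipeline(records, profiles)

m = result.metrics
print(f"eligible users: {len(m)}")
print(f"mean follow-up: {m['follow_up_days'].mean():.0f} days")
print(f"mean % days with a measurement: {m['pct_days_measured'].mean():.1f}")
print(f"mean measurements/week: {m['per_week'].mean():.2f}")
print(f"mean weight change: {m['weight_change_kg'].mean():+.2f} kg")
print(f"BMI groups:\n{m['bmi_group'].value_counts().to_string()}")

p = result.pairs
print(f"\nconsecutive-measurement pairs: {len(p)}")
print("frequency categories (share of pairs):")
print((p["freq_category"].value_counts(normalize=True) * 100).round(1).to_string())
print(f"pairs flagged >20% change/day (excluded from models): {int(p['excluded'].sum())}")

b = result.breaks
print(f"\nbreaks of >=30 days: {len(b)}; median duration {b['duration_days'].median():.0f} days; "
      f"median weight change {b['weight_change_kg'].median():+.2f} kg")
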