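# Methods

`selfweigh` processes longitudinal body-weight streams from consumer smart
scales — irregularly sampled, contaminated, free-living data — into
analysis-ready variables, and fits the standard models relating
self-weighing frequency to weight change. This note documents the models,
the conventions chosen where the published rules are underspecified, and
what the synthetic cohorts do and do not establish.

## Cleaning pipeline

Raw records are `(user, timestamp, weight)`. "Day" always means the
calendar date in the user's own IANA timezone; exact-duplicate rows are
collapsed at read time as transmission artifacts. Four record-level stages
run in a fixed order:

1. **Floor.** Weights strictly below 30 kg are removed (no human body
   weight; typically objects weighed on the scale).
2. **Rolling-MAD screen.** For each measurement, a centred window of 30
   samples (truncated, not shrunk, at series edges: the window slides to
   stay inside the series) yields a rolling median and median absolute
   deviation. A measurement is removed when
   |w − median| / (1.4826 · MAD) > 4. Conventions the published rule does
   not state, fixed here: the window is centred (not trailing), and the MAD
   is scaled by the normal-consistency constant 1.4826 so the threshold is
   in robust-z units. When the window MAD is zero the screen flags nothing,
   unless the window still contains ≥3 distinct values, in which case the
   window standard deviation replaces the scaled MAD (a constant-valued
   window should never flag, but a window whose spread is hidden from the
   MAD by a majority value still can).
3. **Neighbour-vote screen.** Each surviving measurement *i* is compared
   with up to 4 surviving neighbours *j* (2 preceding, 2 succeeding). *j*
   votes against *i* iff |w_i − w_j| / w_j > 0.03 + 0.001·(days between the
   two local calendar dates). Measurements with ≥3 votes are candidates;
   the one with the most votes is removed (ties: larger Σ_j |w_i − w_j|
   over its neighbours, then the later timestamp), neighbours and votes are
   recomputed, and the loop repeats until no candidate remains.
   Conventions fixed here: the vote denominator is the *neighbour's*
   weight; same-day pairs have day difference 0; a measurement with fewer
   than 3 surviving neighbours (series edges, very short series) cannot be
   flagged by this screen — the MAD screen still covers edges; the
   tie-break sums are rounded to 9 decimals so that tie resolution does not
   depend on floating-point summation order. The alternative reading in
   which votes come from consecutive-pair differences spanning *i* (rather
   than direct *i*-vs-*j* comparisons) is not implemented.
4. **Daily minima.** One record per user-day is kept: the day's minimum
   surviving weight (ties: earlier timestamp), suppressing diurnal
   variation and clothing/carried-object effects. The retained record
   keeps the timestamp of the minimum measurement.

The four stages are **cycled to a fixed point**: dropping intraday
duplicates tightens the dispersion the screens see, so a second pass over
the daily-minimum series can legitimately flag points that passed on the
raw stream. Iterating until a full cycle removes nothing makes the
pipeline idempotent — re-cleaning its own output removes nothing — which
also makes the ledger well defined: every input record ends up exactly once
in either the retained set or the removal ledger, with one reason code
(`below_floor`, `mad_outlier`, `vote_outlier`, `intraday_duplicate`).

**Eligibility.** Users are excluded (one reason each, fixed precedence:
missing profile → span < 365 days → fewer than 30 raw measurements → age
outside [18, 100] → height outside [1.40, 2.10] m → first-week BMI < 18.5
→ more than 10 original daily minima removed → fewer than 30 clean
observations). First-week BMI uses the mean retained daily minimum over
the first 7 calendar days and the profile height. "Original daily minima
removed" compares the per-day minimum records of the raw stream (before
any processing) with the outlier screens' removals: a day counts when its
original minimum record was removed by floor/MAD/vote.

## Derived variables

* `follow_up_days` = last − first retained measurement date. Rate
  denominators (`pct_days_measured`, `per_week`) use the inclusive count
  `follow_up_days + 1`, so a perfectly daily series scores exactly 100%
  and 7 measurements/week, and `per_week = pct_days_measured × 7/100`
  whenever each measuring day contributes one retained record.
* Initial (final) weight: mean daily minimum over the first (last) 7
  calendar days of follow-up; a window needs ≥1 measurement, not 7.
  `weight_change_kg` = final − initial (negative = loss);
  `weight_change_pct` = 100·Δ/initial; `max_weight_change_kg` = the most
  negative running change, min over days of (weight − initial).
* BMI = initial weight / height²; groups normal [18.5, 25), overweight
  [25, 30), obese [30, ∞).
* **Breaks**: gaps of ≥30 days between consecutive retained measurements;
  across-break change = first-after − last-before; user-level means over
  all breaks.
* **Pairs**: for each consecutive pair of daily minima, gap in days (≥1),
  change per day (kg, and as a fraction of the earlier weight), frequency
  category from the *intervening* day count (gap − 1): 0 → daily, 1 →
  every other day, 2 → 2-4/week, 3–7 → 1-2/week, 8–14 → every other week,
  15–29 → monthly, ≥30 → less than monthly. Reading the category bounds
  as intervening days is an interpretation: "daily = 0 days between" must
  coexist with division by a day difference of ≥1, and 14 intervening days
  is assigned to the finer bin to keep the categories a partition.
  Morning = local time in [05:00, 13:00); the pair's time-of-day
  combination is previous-then-current (`morning-evening` = previous in
  the morning, current in the evening); weekday is the later measurement's.
  Pairs with |fractional change per day| > 0.20 are flagged `excluded` —
  kept in the table, dropped from the temporal models.

## Statistical models

Estimation delegates to scipy/statsmodels; the package's contribution is
the pipeline feeding it.

* Group summaries: means (SD) or medians (IQR) per BMI group; χ² without
  continuity correction for counts, one-way ANOVA for means,
  Kruskal-Wallis for skewed variables. Tests run across the groups present
  with ≥2 users each, otherwise marked not applicable.
* Correlations: Pearson r of weight change (kg) on % measuring days,
  Spearman ρ for break duration vs break gain (computed on user-level mean
  break duration and mean gain), overall and per BMI group; two-sided,
  α = 0.05, no multiplicity correction. Zero-variance input returns NaN
  with a warning.
* Interaction OLS: `weight_change ~ frequency × BMI group` with treatment
  contrasts, normal weight as reference; adjusted variant adds sex, age,
  initial BMI, follow-up duration. A rank-deficient design raises an error
  naming the collinear columns.
* Temporal LME: `change_per_day ~ gap` with a per-subject random intercept
  and random slope on the gap; REML by default (a flag switches to ML —
  the estimation criterion is a package default, not an attributed
  choice). The categorical variant replaces the gap with the frequency
  category (reference: daily; random intercept only, a slope on a category
  set being unidentified), optionally interacted with BMI group; adjusted
  variants add sex, age, initial BMI, weekday, and the time-of-day
  combination as unordered categoricals. Optimisation tries L-BFGS, then
  Powell, then CG; a fit is accepted only if it converged with finite,
  sane fixed-effect standard errors. A singular random-effects covariance
  (common here: between-user variance in per-day changes is tiny) falls
  back to the random-intercept model with a warning. A constant outcome
  short-circuits to the exact OLS limit (all effects and variances zero).

## Synthetic cohort generator

Real vendor streams are proprietary, so cohorts are simulated with known
ground truth. Per user:

* **Adherence** is a two-state regime process: in the active regime each
  day is a measuring day with per-user probability p_i (drawn around 0.48,
  SD 0.23); a break regime starts with hazard 0.0025/day and lasts
  ~N(70, 35) days, truncated at ≥30. A two-state process is essential:
  i.i.d. daily coin flips at ~40% cannot produce ≥30-day gaps in the
  majority of users. With these defaults the overall measuring-day share
  lands near 40% and most users have at least one break.
* **Follow-up** ~N(1085, 420) days, minimum 366; the first and last day
  are forced measuring days so the follow-up span is the intended one.
* **Weight**: baseline ~N(82, 19) kg (≥42), height ~N(1.74, 0.09) m.
  Latent weight evolves between measuring days as drift·Δt plus a
  short-gap ratchet (an extra 0.001·g² kg across a gap of g < 30 days —
  equivalently, the per-day change grows by 0.001 kg/day per day of gap,
  the planted temporal-gap effect) plus, across each ≥30-day gap, a break
  gain of (0.015 kg/day × BMI-group multiplier 0.65/1.0/1.5 + noise) ×
  duration — the planted break effect, proportional to duration and
  largest in the obese group. Per-user drift ~N(−0.8, 2.0) kg/year plus a
  coupling term −3.0·(p_i − 0.48) kg/year, the planted negative
  frequency–weight-change association.
* **Measurements**: 1 + Poisson(0.3) per measuring day; times from a
  morning (~07:30) / evening (~21:00) mixture with per-user preference,
  evening draws spilling past midnight to exercise the 5 am boundary;
  evening measurements carry a +1.0 kg diurnal offset; measurement noise
  SD 0.5 kg.
* **Contamination**, injected post hoc on otherwise clean records so
  labels stay unambiguous: sub-30 kg errors (0.1%), other-person
  measurements (offset ~N(22, 6) kg, random sign; 0.15%), carried-object
  spikes (+U(5, 15) kg; 0.25%). The ~0.5% total keeps the share of users
  tripping the >10-removed-minima exclusion at a few percent, matching the
  near-98% inclusion rate such cohorts show after cleaning. Artifacts
  smaller than the screens' detection floor (a ~2.5 kg carried object) are
  deliberately out of the preset: the recovery checks quantify the screens
  against artifacts they are designed to catch.
* Identical config and seed give byte-identical CSV output; per-user
  streams use spawned, order-independent seed sequences.

What the generator does **not** model: real within-person weight dynamics
(the drift + ratchet + break-gain form is a stand-in, not an estimate),
demographic realism beyond age/height/sex/timezone, measurement-device
bias, or behavioural feedback (e.g. weight gain causing the break rather
than coinciding with it). Passing recovery tests therefore shows the
pipeline recovers what was planted under these assumptions — not that the
published effect sizes are reproduced, which would require the proprietary
data. The cohort's mean weight change is not a calibrated target and can
sit slightly positive under the defaults.

## Problem sizes and numerical choices

The bundled checks run the cleaning-recovery scoring on a 500-user preset
cohort, parameter recovery at 3000 simulated users (OLS) and 50 replicates
of 300 users × 20 pairs (LME coverage), and the end-to-end sign recovery
on one seeded 2000-user cohort; the acceptance script uses an 800-user
cohort and 30 LME replicates. The gap-slope LME in the sign-recovery test
is fitted on a seeded 600-user subset of the cohort's pairs — the slope is
a cohort-level fixed effect and the subset keeps the optimizer fast.
Tolerances: OLS equals the normal-equations solution to 1e-8 relative;
the zero-random-variance LME matches the OLS slope to 1e-4; recovery
bounds (≥95% artifact removal, ≤1% clean removal, ±20% interaction
recovery, ≥90% CI coverage) are fixed a priori.

## Known limitations

* The vote screen's published wording is ambiguous about the comparison
  set; only the direct neighbour-comparison reading is implemented.
* A trailing (rather than centred) MAD window, or an unscaled MAD, would
  remove a somewhat different set of points; the choice here is recorded,
  not inferred as anyone's intent.
* Days with all measurements removed leave a gap in the daily series (no
  imputation); retained weights are never smoothed.
* The eligibility precedence order affects only which *single* reason is
  reported for multiply-excludable users, not who is excluded.
* MixedLM random-slope fits on cohorts where the true slope variance is
  ~0 routinely hit the boundary; the documented intercept-only fallback is
  then the reported model.
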