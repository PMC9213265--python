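# Methods

This note documents the models and procedures implemented in `opiclaims`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real claims data.

## Data model

A claims bundle holds three tables — patients (id, sex, birth year, end of
data), diagnoses (id, ICD-10 code, date), prescriptions (id, drug code,
start date, days supplied, daily dose in the drug's own milligrams,
dispensed units) — plus a drug dictionary (role and OME conversion factor
per drug code) and a code map from ICD-10 prefixes to analysis covariates.
Dates are ISO-8601 on disk; every day interval is closed and 1-based, so a
prescription starting on day *s* for *d* days covers days *s* … *s*+*d*−1.
Raw tables stay pre-conversion: morphine-equivalent arithmetic happens only
in the episode builder.

Treatment events (operative treatment, radiotherapy, chemotherapy, nerve
block) have no table of their own; they ride in the diagnosis table as
procedure-context codes (defaults: Z98, Z51.0, Z51.1, Z51.8). This is a
declared convention of the package, configurable through the code map, not
a claim about any specific billing system. Likewise the comorbidity and
cancer-site prefix map is a documented default (back pain M54\*, spinal
stenosis M48.0, bone metastasis C79.5, secondary malignant neoplasm
C77–C79, …), fully overridable via `code_map.json`.

## Episode construction

The exposure unit is the index-anchored prescription episode. Eligibility:
≥ 1 cancer diagnosis, ≥ 1 opioid prescription (oral or transdermal; the
drug dictionary's `base_opioid`/`rescue_opioid` roles — injectables are
simply absent from those roles and therefore invisible) on or after the
first cancer diagnosis, and ≥ 730 days from index date to end of data.
Death and administrative censoring are treated identically by that
criterion; the cut-off applies regardless of cause.

Coverage is the union of the closed coverage intervals of *all* opioid
prescriptions from the index date onward — switching opioids or adding a
second opioid never interrupts an episode, and overlapping supplies are not
stockpiled (the union, not the sum, defines coverage, because the episode
end is defined by the last *covered* day). Uncovered days are counted
strictly between coverage intervals (end-of-coverage to next start, the
standard persistence-window convention); the first uncovered run of
**≥ 30 days** ends the episode, so a 29-day run bridges and an exactly
30-day run terminates. The episode end is capped at the patient's end of
data. A brute-force day-grid simulator (mark covered days, scan for the
first 30-day uncovered run) is kept alongside as a test oracle; the
interval-merge builder must agree with it on randomized prescription sets,
including forced 29/30-day boundaries.

### OME dosing

Total OME = Σ daily_dose_mg × factor × days_supplied over convertible
opioid prescriptions starting within the episode; the mean divides by the
full episode duration (covered-gap days included), on the 30 mg oral
morphine reference. Default factors (config-overridable): morphine oral
1.0, morphine suppository 1.5, oxycodone 1.5, fentanyl transdermal 100,
tapentadol 0.3, hydromorphone 5.0; fentanyl sublingual/buccal tablets and
methadone carry no factor and contribute zero milligrams without poisoning
the sum. The dose is non-calculable only when the episode contains no
convertible opioid at all. Prescriptions issued inside the episode count
their full dispensed quantity even if the supply overruns a death-capped
end date — claims record dispensing, not consumption.

## Cohort classification

With thresholds (183 d, 120 mg/day, 730 d), classification is:
non-calculable dose → excluded; duration < 183 → control (dose plays no
role for controls); mean ≥ 120 → case I (< 730 d) or case II (≥ 730 d);
otherwise excluded as long-term low-dose. Long low-dose patients are
reported in the flow report but sit outside the ordered outcome, matching
the attrition arithmetic of the published workflow this reimplements. All
inequalities are strict/inclusive exactly as written; ties at thresholds
therefore classify deterministically.

Covariate windows: diagnosis-based flags (sites, metastasis, comorbidities)
are true on any matching record; drug-class and treatment flags are
windowed — `pre_` strictly before the index date, `dur_` from index date
through episode end inclusive. Age uses year precision (claims convention).

## Inference

**Dunnett.** Pooled-variance t statistics for each case group against the
shared control; the two-sided familywise-adjusted p for contrast *i* is
1 − P(max_j |T_j| ≤ |t_i|) under the central multivariate t with
correlation √(λ_i λ_j), λ_i = n_i/(n_i+n₀), integrated numerically
(fixed-seed quasi-Monte-Carlo rectangle probabilities, accuracy ~1e-4).
Zero pooled variance yields p = 1 with a warning; groups with fewer than
two observations are reported as not-computable.

**Steel.** Wilcoxon rank sums with midranks per case-vs-control pair,
standardized with the tie-corrected variance (binary 0/1 factors are
handled by the midrank machinery, where the test reduces to a proportion
comparison), jointly adjusted through the same equicoordinate rectangle of
the correlated multivariate normal. No small-sample exact tables are used;
a permutation mode (null distribution of max_j |Z_j| under pooled
relabelling) provides an exact-style alternative and serves as the test
oracle. The plain large-sample form (no continuity correction) is used.

**Proportional odds.** P(Y ≥ k|x) = logistic(α_k + xᵀβ) with strictly
decreasing cutpoints α₁ > α₂, so positive β means higher odds of case
membership and exp(β) is the cumulative odds ratio. (Software that models
P(Y ≤ k) prints the same fit with opposite-signed, reversed cutpoints;
our orientation keeps Table-2-style signs.) The fit is a damped Newton
ascent: analytic gradient, observed information by central differences of
that gradient, step-halving guaranteeing a non-decreasing log-likelihood,
convergence at gradient norm < 1e-6 (about the square root of achievable
floating-point likelihood precision at n ≈ 10⁴). Standard errors come from
the inverse observed information; CIs are Wald, exponentiated to the OR
scale. Non-convergence raises an error carrying the iteration trace, and
estimates diverging beyond |logit| > 30 are reported as separation rather
than returned as spuriously "converged" numbers.

**Variable selection.** Step 1 admits continuous factors significant
(p < 0.05) in *both* case-vs-control comparisons and categorical factors
additionally required to reach ≥ 5% incidence in control or either case
group; the alternative "significant OR prevalent" reading of that filter is
exposed as `step1_mode="union"`. Step 2 applies declared collinear pairs
(default: bone metastasis drops in favour of distant metastasis;
psychiatric diagnoses drop in favour of the corresponding drug classes),
forced inclusions "from a clinical perspective" and forced exclusions —
judgment-based steps that cannot be fully automated, so every decision is
written to an audit log with its reason.

## Synthetic claims generator

The generator works backwards from the outcome model so planted effects are
recoverable end to end: per patient (one RNG stream per (seed, index), so
bundles are reproducible and stable under n changes) it draws binary risk
factors from configured prevalences, draws the ordinal group from the
proportional-odds model with the configured β and cutpoints, then
materializes an episode in the group's duration/dose band — lognormal
durations truncated to [1, 183) for controls and [183, 730)/[730, cap) for
cases, lognormal mean doses truncated at ≥ 120 mg/day for cases — and tiles
it with prescriptions (7–30 day supplies, within-episode uncovered gaps on
[0, 29] days, last supply ending exactly on the true end date). Defaults
(intercepts (−4.6, −4.8), β from 0.3 to 0.9 on back pain, distant
metastasis, during-episode gabapentinoid/SNRI/non-opioid-analgesic/
chemotherapy, a 25% long-low-dose stratum and a 0.4% non-convertible-only
stratum) give group shares of roughly 71 / 0.6 / 3.5 / 25 per cent,
echoing the attrition structure of real hospital-claims cohorts. Rescue
status per group (rescue only / base only / both) and dispensing intensity
are configurable; rescue dispensings are placed on already-covered days so
they never extend the episode.

What the generator does *not* emulate: visit-level billing detail, dose
titration within an episode, informative censoring by death, diagnostic
miscoding, care fragmentation across hospitals, or correlation between
risk factors beyond the bone→distant metastasis implication. Passing
recovery tests therefore demonstrates the pipeline's internal correctness —
that episode construction, dosing, classification and regression invert the
generative process — not robustness to those real-data pathologies.

## Numerical conventions and problem sizes

Percentages print at one decimal, half-up. The test suite sizes are chosen
to keep the full run in minutes on one core: 10,000 random prescription
sets for the episode oracle, a 5,000-patient zero-gap bundle for exact
label recovery, 50,000 rows for point recovery of β = log 2 (observed
|error| < 0.05 ≈ 1.4 standard errors), 500 replicates at n = 2,000 for CI
coverage, and 10,000-replicate global nulls (n = 100/20/60, mimicking the
heavy group imbalance of the study design) for familywise error of Dunnett
and Steel within three Monte-Carlo standard errors of 0.05.
`scripts/acceptance.py` uses a 4,000-patient bundle and 2,000-replicate
nulls and reports every quantity it measures.

## Known limitations

* "Number of rescue medication uses" counts dispensed units; ingestion is
  unobservable in claims. Units of non-convertible rescue drugs count
  toward frequency while their milligrams are excluded from dose.
* Only the first, index-anchored episode per patient is analysed.
* Step 2 of variable selection encodes judgment as configuration; defaults
  mirror the published analysis but are not a substitute for clinical
  review.
* The Steel adjustment relies on the large-sample normal approximation;
  for very small groups use the permutation mode.
* The 730-day follow-up criterion removes patients dying early, a known
  selection effect of this study design that the package reproduces rather
  than corrects.
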