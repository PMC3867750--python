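# Methods

This note documents the models and procedures `dietval` implements, the
defaults it ships, and the choices made where the design was genuinely
open. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Study model

The package targets a two-period child cohort design: each subject
records diet and wears a vertical-axis hip accelerometer for two
seven-day windows ("baseline" and "intervention"). The unit of analysis
throughout is the **subject-period**; a subject contributes up to two
records, and repeated-measures dependence is handled explicitly (variance
components in the Bland–Altman analysis, a random intercept in the mixed
model).

## Accelerometer processing

* **Non-wear.** A maximal run of ≥ 20 consecutive zero-count minutes is
  non-wear. Sleep is handled identically (children wear the monitor
  24 h/day; overnight zeros form long runs), so no separate sleep
  algorithm exists. Zero runs touching the stream boundaries also count
  as non-wear when long enough — otherwise boundary sleep would dilute
  cpm.
* **Valid days.** A calendar day (stream-local time) is valid with
  ≥ 780 wear minutes (13 h); partial first/last dates participate and
  normally fail. A recording is acceptable with ≥ 4 valid days including
  ≥ 3 weekdays and ≥ 1 weekend day (Saturday/Sunday).
* **Mean cpm.** Default is the unweighted mean of the valid days' daily
  cpm, weighting days equally; `cpm_method="pooled"` (total counts over
  total wear minutes) is exposed because published analyses rarely state
  which was used. The two differ only when wear time varies across days.

## Energy expenditure

* **BMR** uses age/sex-banded linear equations in weight (kg) and height
  (m), MJ/day. The bundled table (`data/henry_bmr.yaml`) transcribes the
  Henry (2005) Oxford weight-and-height coefficients; the
  weight-and-height form was chosen over weight-only because height is an
  input of the intended calculation. The table is injected, versioned and
  carries its citation, and tests needing exact BMR values inject a
  synthetic table so the suite does not depend on the transcription.
* **AEE** is the children's prediction equation
  66.847 + 0.953·cpm − 176.91·gender (kcal/day), converted at
  4.184 kJ/kcal. Gender coding is 0 = boy, 1 = girl: the negative
  coefficient then gives girls the lower AEE, consistent with boys'
  higher TEE in this age group. The equation is evaluated exactly as
  printed; negative predictions (possible for girls below ~115 cpm) are
  reported with a warning rather than clamped, with clamping left to the
  caller.
* **TEE.** DIT is defined as 10% of TEE, which makes TEE = AEE + BMR + DIT
  circular; the algebraic closure TEE = (AEE + BMR)/0.9 is the unique
  solution consistent with both statements and is used everywhere.

## Intake and classification

Mean EI is the unweighted mean over *complete* recording days (MJ/day);
incomplete days are excluded, not imputed, mirroring field systems that
auto-close unrecorded days. Validity requires ≥ 3 complete weekdays and
≥ 1 weekend day. Illness is recorded per day and aggregated to the
subject-period with any().

Reporter classes use fixed EI:TEE cut-offs: under < 78%, over > 122%,
with both boundaries classifying as acceptable (the band is read as a
closed interval). Individualized Goldberg-style cut-offs are out of
scope; the bounds are configurable instead. Weight status uses the
international (IOTF) child BMI cut-offs with linear interpolation between
the tabulated half-year ages; a BMI exactly on a threshold takes the
heavier category.

Reporter-group comparisons (the characteristics table) run all three
pairwise tests per variable — Welch *t* for continuous, chi-squared
without continuity correction for categorical — and assign compact
significance letters so classes share a letter iff not significantly
different at 5%. Tests are unadjusted by default (a Bonferroni flag
exists); single-member classes suppress letters with a warning.

## Agreement statistics

* **Paired t** on EI − TEE per period and pooled. Zero-variance
  differences degenerate to p = 1 (mean 0) or p → 0, with a warning.
* **Bland–Altman for repeated measurements.** With differences d_ij
  (subject i, period j), MSW and MSB are the one-way ANOVA mean squares,
  m₀ the average replication count, σ²_b = max(0, (MSB − MSW)/m₀)
  (negative estimates truncate to zero, standard ANOVA practice), and
  SD_corrected = √(σ²_b + MSW). Limits of agreement are
  mean ± 2·SD_corrected — multiplier 2, not 1.96, configurable. When
  every subject contributes a single difference the estimator collapses
  exactly to the classic sample-SD form (flagged in the result).
* **Quartile cross-classification.** Quartiles are assigned from average
  ranks cut at n/4, n/2, 3n/4 (upper-inclusive) — deterministic and
  stable under permutations and monotone transforms. Agreement is
  summarized as same / same-or-adjacent / two-apart / opposite quartile
  shares plus unweighted Cohen's κ with its large-sample null-SE p-value.
* **ICC.** Repeatability of EI between periods is the two-way
  mixed-effects, absolute-agreement, single-measure ICC(A,1), with the
  McGraw–Wong F-based confidence interval. The variant is a declared
  choice (the convention in test–retest work); consistency-type ICCs
  would ignore a period-level shift in level, which is exactly what an
  intervention could induce.

## Mixed model

Response is EI:TEE × 100 (percentage points). Fixed effects: illness
(not-ill vs ill ≥ 1 day), sex (boy vs girl), BMI, age, parental education
dichotomized (codes 1–2 "mainly practical" vs 3–4 "mainly theoretical")
and period, plus all two-way interactions; random intercept per subject;
REML estimation via statsmodels' MixedLM with design assembly owned by
the package. Backward elimination drops the least significant interaction
with p > 0.05, refits, then prunes main effects not contained in retained
interactions; hierarchy is never violated.

Inference uses t statistics on residual degrees of freedom
(n_obs − rank X). A Satterthwaite approximation was considered; with two
observations per subject at the cohort sizes targeted here the t quantiles
differ by well under 1%, and the simpler rule is exactly reproducible.
Degenerate designs degrade deliberately: one observation per subject (no
estimable random intercept) or a perfectly deterministic response fall
back to OLS, flagged in the result; constant or collinear covariates
raise an error naming the term.

## Synthetic cohort

The generator reproduces the study conditions so that downstream
estimates can be checked against known truth.

* **Cohort** (defaults): n = 81, 58% girls, age 10.3 ± 0.6 y, height
  144.0 ± 7.2 cm, BMI 17.0 ± 2.4 kg/m², parental education sampled at
  4/54/9/33%. Weight is derived as BMI × height², so the BMI covariate is
  controlled exactly.
* **Reporting-bias model.** True EI:TEE (%) per subject-period is
  additive on the percentage scale:
  r = 100 + 10.73·(1 − ill) + (−9.96)·boy + (−3.65)·(BMI − 17) + u + ε,
  with u ~ N(0, 15²) shared across periods and ε ~ N(0, 17²) per period.
  The additive-percentage form matches how such covariate effects are
  reported in this literature. The between/within split (15/17) is a free
  parameter chosen to give a total ratio SD near 22–23% and an intake
  repeatability ICC in the moderate (~0.45) range; no published
  decomposition exists to pin it down further. Illness prevalence
  defaults to 33% (baseline) and 18% (intervention).
* **Count streams.** 7 calendar days starting on a Monday; zeros from
  22:00 to 06:30 (sleep), 0–2 inserted non-wear gaps of 20–60 min per
  waking day (Poisson mean 0.7), waking counts gamma-distributed around a
  per-subject latent level (cpm ~ N(500, 150²) between subjects,
  minute-level SD 250, 8% sedentary zero minutes). 500 cpm with these
  BMRs puts AEE near 20% of TEE, the realistic low-activity winter
  regime for this age group. With all noise knobs at zero the waking
  counts are constant, making the cpm chain exactly checkable.
* **Diet records.** 7 days whose mean energy is exactly (r/100)·TEE_true;
  day-to-day spread CV 20% renormalized to preserve the mean; 1% of days
  incomplete; ill subject-periods carry at least one illness-flagged day.
* **Determinism.** Every random draw comes from a named substream keyed
  on (seed, purpose, subject, period), so the same configuration is
  byte-identical across runs and any entity can be regenerated in
  isolation.

What the generator does **not** emulate: activity-intensity structure
within the day beyond sleep/wake (no bouts, no school-day rhythm),
triaxial signals, food-item composition, digit preference or other
human recording artifacts, and correlation between activity level and
reporting accuracy. Passing tests therefore demonstrate the statistical
machinery and its calibration under the stated generative model — not
that any particular field instrument is unbiased.

## Problem sizes in routine checks

The simulation-based checks run at the design's own scale: parameter
recovery uses 200 replicate studies of 81 subjects × 2 periods (intake
and truth only, count streams elided since they contribute only ~0.1%
noise to TEE), and misreporter-rate calibration uses 2 000
subject-periods. Oracle-equivalence checks use 100 random 2 000-epoch
streams and 50 random Bland–Altman instances.

## Known limitations

* The AEE equation is linear in cpm and can go negative for girls at very
  low activity; the pipeline reports it faithfully.
* BMR coefficients and BMI cut-offs are transcriptions of published
  constant tables; swap in your own YAML via `bmr_table_path` /
  `weight_cutoff_path` to use other references.
* The mixed model assumes a single random intercept (no random slopes)
  and Gaussian residuals; p-values use a residual-df t approximation.
* Quartile cut points follow one fixed tie-breaking convention; other
  software may split ties differently on heavily tied data.
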