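# Methods

## Overview

`ctlar` projects lifetime radiation-induced cancer incidence from one year of
national CT utilization. The causal chain it implements: each examination
deposits absorbed dose in organs; organ dose raises site-specific cancer
rates according to dose–response models fitted to irradiated cohorts; excess
rates accumulated over the remaining lifetime, discounted by competing
mortality and a minimum-latency ramp, give a per-examination lifetime
attributable risk (LAR); multiplying by national examination counts (less
exams in the last year of life) gives projected future cancers.

The pipeline works on 418 strata — 2 sexes × (8 adult age groups × 18 adult
CT categories + 5 pediatric age groups × 13 pediatric categories) — the
granularity at which organ doses are averaged and risks evaluated.

## Synthetic registry

Real exam-level dose registries are proprietary, so the package generates
one with the statistical structure the analysis assumes. Defaults emulate
published national utilization summaries; everything is configuration.

* **Demographics.** Patients draw a (sex, age-group) cell from a marginal
  derived from published exam counts by sex and age divided by mean exams per
  patient; age is uniform within the group. The pediatric share of generated
  exams is 3.3% by construction.
* **Exams per patient.** 1 + Poisson(m − 1) per patient, cell means m from
  1.12 to 1.66 — the median is 1 in every cell, matching utilization data,
  and the national mean is ≈1.51.
* **Categories.** Per-cell categorical mix; the default is head-dominant in
  children (52% of pediatric exams) and abdomen/pelvis-dominant in adults
  (33%), with synthetic within-region dose-tier splits. The 26-name category
  vocabulary (5 shared, 13 adult-only, 8 child-only) is this package's
  construction; only its shape (18 adult / 13 child applicable) is fixed.
* **Organ doses.** Within a stratum, each of 18 organs draws from a lognormal
  moment-matched to the stratum's configured (mean, SD). Lognormal is this
  package's choice: doses are strictly positive and right-skewed, matching
  dosimetry practice, and only mean/SD summaries are available to match. The
  default dose table is parametric — region base dose × tier multiplier
  (low 0.45 / routine 1.0 / high 1.8) × age factor (head doses peak in
  infancy at 1.4×; trunk doses scale with body size from 0.45× in infants to
  ~1.08× in older adults) × a ±2% sex factor, with region-specific relative
  organ weights — overridden exactly by a set of published per-stratum
  mean (SD) anchor doses (e.g. routine-head brain dose 48.0 [27.3] mGy in
  boys 5–9). Default SD is 0.58× the mean, the typical coefficient of
  variation in the anchors.
* **Flags.** 28.5% of exams are multiphase (descriptive only — doses are
  per-exam totals over all phases); a per-patient last-year-of-life flag uses
  the cell probabilities below; ~2.4% of exams carry exclusion reasons
  (biopsy/procedure, PET, research).
* **Last year of life.** Published anchors (1.4%/0.5% girls/boys 1–4;
  35.1%/44.4% women/men 90–99; sex means 9.4%/12.1%, overall 10.6%) are
  interpolated with a smooth increasing curve; the exam-weighted means of the
  default map sit near the published sex means. The 2-year map used by one
  sensitivity scenario is synthetic: 1.6× the 1-year map, capped at 1.

What the generator does **not** emulate: patient size (effective diameter),
scanner protocol detail, within-patient correlation of categories across
repeat exams, secular utilization trends, and any real-registry correlation
between dose and comorbidity. Passing tests therefore demonstrate that the
pipeline's logic is correct under the assumed structure, not that the shipped
totals estimate the real national burden.

## Stratification and national scaling

Exams with exclusion reasons are dropped; strata with fewer than 12 exams are
dropped (dose estimates would be imprecise) and proportions renormalized.
Scaling allocates `pediatric_share × total` exams to pediatric strata
proportionally to the pediatric mix, the remainder to adult strata, using
largest-remainder rounding so block totals are exact (reported national
counts are rounded; conservation is the testable property). Patient totals
are derived, not simulated: patients(cell) = exams(cell) / mean exams per
patient(cell). End-of-life exclusion multiplies each stratum by
(1 − eol(sex, age-group)), with largest-remainder rounding of the excluded
counts against the rounded national exclusion total.

## Risk engine

* **Solid sites** (17 of 18): ERR and EAR of the form
  β·D·exp(γe*)·(a/60)^η with e* = (min(e,30)−30)/10. Default modifiers
  γ = −0.30/decade, η = −1.4 (ERR) and γ = −0.41, η = +2.8 (EAR); thyroid is
  ERR-only with γ = −0.83, η = 0; lung EAR uses η = 5.2; breast is EAR-only.
  Breast uses a single attained-age power (η = 2.0) rather than a piecewise
  power switching at age 50 — a deliberate simplification keeping one solid
  functional form; at CT dose levels the difference is a second-order shape
  effect within the breast row only.
* **Leukemia**: linear-quadratic β·D·(1+θD)·exp(γe* + δln(t/25) + φe*ln(t/25)),
  evaluated with each path's own θ (defaults are equal at 0.88/Gy). No DDREF.
* **Coefficients** ship as an editable table. Values for the 11 dedicated
  sites are this implementation's transcription of the BEIR VII preferred
  models; the 7 additional sites (oral cavity/pharynx, esophagus, rectum,
  pancreas, kidney, brain/CNS, remainder) carry implementer-chosen pooled
  defaults of plausible magnitude. No downstream logic depends on specific
  values.
* **Transfer weights**: w = 0.7 (ERR) by default; lung 0.3, breast 0.0,
  thyroid 1.0 — standard practice for these sites.
* **LAR sum**: annual, over integer attained ages a with e < a ≤ 100. The
  discrete annual grid matches life-table granularity; starting at the first
  whole age after exposure makes LAR(e = 100) exactly zero, keeps leukemia's
  t > 0 domain, and gives the clean closed form λ·D·(100−e) under flat
  survival/constant baseline used as a test oracle. S(e) at non-integer
  exposure ages (group midpoints such as 54.5 or 0.5) is linearly
  interpolated.
* **Exposure age within a stratum**: the group midpoint (e.g. 50–59 → 55.0;
  <1 → 0.5) — unbiased under a uniform within-group age distribution.
* **Latency**: logistic ramp in time since exposure, weight(μ) = 0.5, with
  steepness (end − start)/(2·ln 19) so the ramp traverses 5%→95% across the
  group's phase-in window (solid 4.0–11.0 y, thyroid 2.5–7.6 y, leukemia
  0.4–4.1 y) at the modal midpoint. μ is sampled per draw from the group's
  triangular distribution. The ramp shape is this package's choice; the
  windows and midpoint distributions are the constraint it satisfies.
* **DDREF**: divisor on solid-site risk, lognormal with median 1.5. The
  target 90% interval (1.1, 2.3) is not exactly log-symmetric about 1.5, so σ
  (= 0.2242) is the least-squares compromise on the log scale. The fitted
  interval is (1.04, 2.17): a log-symmetric lognormal cannot hit both printed
  endpoints, and the compromise leaves each about 6% below its target.
  Sampled medians match 1.5 exactly and the interval sits within the sampler
  test tolerances.
* **Uncertainty**: Latin hypercube over 40 dimensions — one lognormal
  multiplier (σ = 0.25, median 1) per site × sex applied to both β's, the
  DDREF, and the three latency midpoints. One draw set is shared across all
  strata in a run (risk-model parameters are systematic, not per-person), so
  national uncertainty limits reflect parameter uncertainty, not Monte Carlo
  sampling noise. Per-stratum dose uncertainty is not sampled by default;
  dose SDs are carried in summaries and available to a custom analysis.
* **90% uncertainty limits**: empirical 5th/95th percentiles of the per-draw
  totals of whatever group is being reported — coherent within a table,
  deliberately not additive across rows.

## Projection and sensitivity

Projected cancers per group and draw are Σ included exams × per-exam risk;
points use the central evaluation (multipliers 1, DDREF 1.5, modal μ).
Because solid risk is linear in dose and all risk is linear in exam counts,
projections are exactly homogeneous in volume, exactly proportional to dose
under a pure-solid configuration, and identical whether aggregated per exam
or per patient — all verified as exact tests. Rates per 1000 examinations
use the group's **total** exam count (before end-of-life exclusion) as the
denominator, a conservative convention.

The eight sensitivity scenarios are declarative modifications of the baseline
(lung-coefficient swap, volume ±10%, dose ±20%, pediatric share 9.0%,
alternate-year distribution profile, 2-year end-of-life exclusion), re-run
against the same parameter draws so deltas are paired. With leukemia θ > 0,
+20% dose raises the total strictly more than −20% lowers it; at CT doses
the asymmetry is small but strictly present.

## Numerical and degenerate-input choices

* Lognormal dose sampling with SD = 0 degenerates to a point mass at the
  mean; mean ≤ 0 or SD < 0 is a configuration error.
* Largest-remainder rounding is stable-sorted, so allocation is
  deterministic under ties.
* Strata whose configured probability is too small to reach 12 exams at the
  generated sample size are dropped by design; national scaling renormalizes
  over retained strata.
* All randomness flows from one root seed via `SeedSequence.spawn` (stage
  order: registry, uncertainty draws); derived seeds are kept below 2³¹.
* Default problem sizes (registry of ~10⁵ patients; 500 uncertainty draws in
  the acceptance run) keep every stage in seconds while leaving Monte Carlo
  error well inside the test tolerances; both are configuration.

## Known limitations

* Synthetic registry defaults, dose table and baseline rates are stand-ins;
  absolute projected totals are properties of those inputs.
* The additional-site coefficients and the per-coefficient uncertainty σ are
  plausible defaults, not fitted values.
* Transfer-weight and dose uncertainty are not part of the default LHS.
* No DICOM ingestion, radiation-transport dosimetry, patient-size modeling,
  or calendar-year utilization forecasting.
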