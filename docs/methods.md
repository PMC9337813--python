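# Methods

This note documents the statistical procedures, the synthetic-data model
behind the tests, the tunable parameters and their defaults, and the design
choices made where more than one reasonable convention exists.

## Input formats

- `intensities.csv` — features × samples, non-negative intensities, missing
  allowed; row index `feature_id`, columns are sample ids.
- `samples.csv` — one row per injection: `sample_id`, `subject_id` (empty
  for QC injections), `sample_type` ∈ {`study`, `pooled_qc`, `dilution_qc`},
  `run_order` (unique, increasing), `batch`, `dilution_fraction` (dilution
  injections only), `platform`.
- `subjects.csv` — one row per participant: `subject_id`, `cohort` (A/B),
  `age`, `sex`, `diabetes`, `hypertension`, `hypercholesterolaemia`;
  longitudinal outcomes as `<outcome>_y<year>` columns (e.g. `mdnph_y0`,
  `wmh_percent_y5`); `microbleed_count`, `lacune_count`, `fazekas_grade`;
  `dementia_event`, `dementia_time` (years).

## Drift correction

Pooled-QC injections — a mixture of equal parts of every study sample —
estimate the instrument response over the run. Per feature and batch a
locally linear LOESS curve is fitted to pooled-QC intensity vs run order
(statsmodels `lowess`). Every sample in the batch is divided by the curve
value at its run order, linearly interpolated between QC injections and
held at the nearest fitted value beyond the first/last QC (no extrapolated
trend, which avoids blow-up at run edges). Multiplying by the feature's
median pooled-QC intensity across the whole run restores the original scale
and removes between-batch offsets at the same time.

Numerical choices:

- **Span** defaults to 0.5 of the batch's QC series, with the smoothing
  window floored at five QC points. Without the floor, sparse QC series
  (3–7 points) are nearly interpolated, which deletes the technical
  variance the pooled-QC RSD criterion is supposed to measure.
- **Anchoring.** After division the corrected pooled-QC median is only
  approximately the reference level (the median of the QC/curve ratio is 1
  in expectation, not identically); an explicit per-feature rescaling makes
  corrected-QC-median = raw-QC-median exactly.
- **Degenerate fits** (non-positive curve values, fewer than two usable QC
  points in a batch, non-positive reference) leave the feature uncorrected
  and flagged in the diagnostics rather than failing the run.
- **Platform switch.** Correction can be disabled per platform (hydrophilic
  interaction chromatography data often needs none); the matrix then passes
  through unchanged but still advances to the `corrected` state.
- Fewer than `min_qc_per_batch` (default 3) pooled-QC injections in any
  batch is an error naming the batch.

A known property of any QC-curve method: because the curve is fitted to the
QC points themselves, the post-correction pooled-QC RSD is attenuated
relative to the true technical RSD (the fit absorbs part of each QC
residual, roughly 2/window of the variance). With dense QC series the
attenuation is small; with sparse ones, features whose study variance is
almost purely technical can slip past the variance-ratio criterion.

## Feature quality criteria

On the corrected matrix, per feature:

- `rsd_qc` — 100 · sd/mean over pooled-QC samples (sample sd, n−1);
- `rsd_study` — the same over study samples;
- `dilution_r` — Pearson correlation between intensity and dilution
  fraction over the dilution-series injections (all levels used).

Retention requires `rsd_qc < 30`, `dilution_r > 0.7` and
`rsd_study > 1.1 · rsd_qc`. All inequalities are strict: a feature at
exactly 30 % QC RSD fails. Undefined metrics (fewer than two values,
non-positive mean, zero variance, fewer than three distinct dilution
levels) fail their criterion with the reason recorded. Datasets without a
dilution series (e.g. NMR) skip the linearity criterion vacuously. Features
with more than 50 % missing study values (configurable) fail regardless.
The RSD denominator (n−1) and the missingness rule are conventions chosen
here; both are recorded in the QC report along with the thresholds used.

## Transforms

The generalized log `glog(x) = ln((x + √(x² + λ))/2)` is monotone, defined
at zero, and converges to ln x for large x. λ defaults to `auto`: the
squared median pooled-QC standard deviation of features in the lowest
quartile of median QC intensity — an estimate of the additive noise floor
the transform should damp. A fixed λ ≥ 0 can be supplied instead.

Autoscaling computes each feature's mean and sample sd over **study samples
only** (QC injections are not participants), applies them to all columns,
and drops zero-variance features with reason `zero variance`. The (mean,
sd) pairs are returned so the same scaling can be reused.

## Outcome panel

Endpoints are oriented so that a higher value always means worse disease:
mean diffusivity normalized peak height (MDNPH), total brain volume
(analysed as atrophy), the three cognition scores and the Barthel index are
sign-flipped; WMH volume (% of brain volume) enters as its natural log;
peak width of skeletonized mean diffusivity (PSMD) is already
worse-when-higher. Oriented endpoints are z-scored across participants.
The sign map is recorded and overridable. "Inverse of total brain volume"
is implemented as sign negation of the z-score (orientation), not the
reciprocal (transformation); a reciprocal would distort effect sizes
without changing ranks.

Lesion counts are analysed both as z-scored continuous endpoints and as
presence/absence binaries (count > 0). The simple MRI severity score
defaults to one point each for any microbleed, `lacune_count ≥ 1` and
`fazekas_grade ≥ 2` (cut-offs configurable; no canonical point system is
established, so the default is the simplest additive one).

Annualized change is `(latest non-missing visit − baseline) / elapsed
years`, computed on the oriented scale, ignoring intermediate visits;
subjects with only a baseline are excluded. Changes are then z-scored like
the baseline endpoints.

## Association models

All effects are per 1-SD metabolite (the metabolite matrix is autoscaled).
Two adjustment sets: demographic (cohort + age + sex) and extended
(+ diabetes, hypertension, hypercholesterolaemia). Continuous endpoints use
OLS; binaries use maximum-likelihood logistic regression; dementia uses Cox
partial likelihood with Efron tie handling (lifelines), time origin at the
baseline serum draw, no time-varying covariates. Wald two-sided p-values
and 95 % CIs are reported with the complete-case n per fit. Change models
use the demographic adjustment; adjusting additionally for the baseline
outcome value is available but off by default.

Non-estimable fits — metabolite collinear with the adjustment covariates,
separated or non-converged logistic fits, Cox fits with fewer than 10
events (configurable) — are flagged with a reason and excluded from their
FDR family rather than reported with meaningless numbers.

For the linear family the suite uses an exact Frisch–Waugh–Lovell sweep:
outcome and metabolites are residualized on the shared covariate block, and
the per-metabolite coefficient, standard error and t-test are identical to
the full-model OLS fit (asserted against statsmodels in the tests). This is
what makes 500-replicate null experiments with 369 features feasible.

Benjamini–Hochberg q-values are computed within each (outcome, family,
adjustment, stratum) family across metabolites — the per-outcome-measure
reading of FDR control — and `significant` flags q < 0.05. Sensitivity
strata (per cohort, age < 65 / ≥ 65 with ties to the older group, Fazekas
≥ 2) refit the baseline models on the subgroup; covariates that are
constant within a stratum (cohort, within a cohort stratum) are dropped
automatically, and strata below 25 subjects (configurable) are skipped with
the reason logged. A stratum containing everyone reproduces the
unstratified results exactly.

## Synthetic-data model

The generator emulates the structure the analysis assumes, not any specific
instrument:

- **Run sequence.** Study samples are shuffled and split contiguously into
  batches. Each batch opens and closes with a full dilution-series block
  (default 10×100 %, 5×80 %, 3×60 %, 3×40 %, 5×20 %, 10×1 % — 36
  injections per block, two blocks per batch); a pooled-QC injection opens
  the study block, recurs every `qc_interval` study samples (default 10;
  real QC spacing varies by lab and is configurable) and closes the batch.
- **Intensities.** Feature base abundances are log-uniform over 10⁴–10⁶.
  Study intensity = base × mean-one lognormal biological variation driven
  by the subject's true standardized metabolite level (the same level the
  outcomes use), so the intensity pipeline and the clinical simulation are
  consistent. Pooled-QC intensity is the feature-wise mean of the clean
  study intensities; dilution intensity is that level times the fraction.
  Everything is multiplied by a smooth per-batch cubic drift curve (equal
  to 1 at the batch start, peak deviation = `drift_amplitude`), a
  per-(feature, batch) lognormal offset, and mean-one lognormal technical
  noise, so `raw = clean × drift × offset × noise` holds exactly and the
  lognormal noise CV equals the configured `tech_cv`. Fractions of features
  can be planted to violate each quality criterion: inflated technical CV
  (default 0.6), a dilution response flat in the fraction, or biological
  variance shrunk to ~0.
- **Subjects.** Two cohorts (defaults 121 and 503) with distinct age
  distributions (≈70 ± 8.5 vs ≈65.5 ± 8.8 years, the second clipped to
  50–85), 58 % male, cohort-specific vascular risk-factor prevalences, and
  visit schedules of years {0,1,2,3} and {0,5,9,14}. Each continuous
  endpoint lives on a unit-variance latent severity scale: planted
  standardized effects, modest covariate effects (age 0.25, sex 0.12,
  cohort 0.20) and Gaussian noise whose variance is set so the marginal
  variance is one — which is what makes a planted β directly recoverable
  from the z-scored endpoint. Latents map affinely to natural units (e.g.
  MDNPH 0.35 − 0.03·L; WMH % = exp(0.9·L); brain volume 1150 − 60·L ml);
  follow-up adds a subject-specific annual slope (0.05 ± 0.05/yr on the
  latent scale) plus visit noise (sd 0.2). Lesion presence is Bernoulli
  through a logistic link (planted per-1-SD log-odds; baseline prevalences
  30 %/40 %), counts are presence × (1 + Poisson); the Fazekas grade
  discretizes the WMH latent. Dementia conversion times are exponential
  with log-hazard linear in the planted predictors and age, right-censored
  at `censor_years` (default 14).
- **Determinism.** All randomness derives from `(seed, stream)` seed
  sequences; a fixed config reproduces every table byte-for-byte.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: chromatographic peak shape, retention-time or m/z
artefacts, correlated metabolite panels (features are independent given the
subject), informative missingness, batch × feature interaction drift,
measurement error in covariates, competing risks of death before dementia,
and real annotation structure. Results on real matrices depend on upstream
peak processing quality, which is out of scope here.

## Validation experiments and problem sizes

`metabosvd.validation` (used by both the test suite and
`scripts/acceptance.py`) runs, per invocation:

- QC-filter agreement: 500 features, 600 subjects, two batches, 10 %
  planted violations of each criterion; pipeline pass/fail vs a scalar
  recomputation of all three rules — exact agreement expected.
- Drift recovery: 300 features, 400 subjects, drift amplitude 0.15, batch
  offsets 0.10, tech CV 0.05, biological CV 1.0 (untargeted serum features
  vary far more between subjects than technically). On the log scale the
  corrected-vs-truth correlation is ≈ σ_bio/√(σ_bio² + σ_tech²), so the
  r ≥ 0.99 recovery level is only attainable when biological variance
  dominates; the chosen CVs reflect that regime.
- Null FDR: 500 replicates of 369 null metabolites at n = 600, linear
  family + BH; the mean false-discovery proportion at q < 0.05 sits near
  the 0.05 guarantee.
- Recovery: 200 replicates each — linear β = 0.3 at n = 2000, logistic
  log-odds = 0.5 at n = 2000, Cox log HR = 0.4 at n = 1500 with base
  hazard 0.022/yr and censoring at 14 yr (≈30 % events); bias and 95 % CI
  coverage are reported.

## Limitations

- Counts are modelled by OLS on the z-scored count (matching the
  "as continuous" convention); no negative-binomial alternative is
  implemented.
- The annualized-change summary uses two time points; subjects with
  non-monotone trajectories are summarized coarsely, and no mixed-effects
  trajectory models are provided by design.
- FDR families are defined per outcome × model specification; other family
  definitions (e.g. pooling outcomes) would change which associations are
  declared and are configurable only by post-processing the p-values.
- The pooled-QC RSD attenuation described above means the variance-ratio
  criterion is conservative on sparsely QC'd batches.
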