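# Methods

## Problem setting and data model

The unit of analysis is a participant history: baseline covariates (sex,
education years, marital status, APOE-ε4 allele count) plus a strictly
time-ordered list of visits.  Time is real-valued months since the
participant's first visit.  A visit may carry any subset of the recurring
features: MMSE (0–30), CDR global (5-level grid 0/0.5/1/2/3), clinical
diagnosis (CN < MCI < DEM), and six volumetric features (hippocampus,
fusiform, middle temporal, ventricle, whole brain, ICV in mm³).  The five
non-ICV volumes are analyzed as fractions of ICV to remove head-size
effects; normalization happens at table load and a non-positive ICV is an
error.  Eligibility requires recurring features at two or more visits; the
features need not co-occur (MRI-only at one visit plus cognition-only at
another qualifies).

Raw tables may code missingness with sentinel integers (−1, −4, 999).
Sentinel cleaning applies only to the configured raw phenotype columns and
must precede feature engineering, because 999 later reappears as a
legitimate engineered constant (the no-milder-diagnosis recency sentinel).
When cognitive and MRI assessments are dated separately, an MRI row merges
into the nearest phenotype row within 6 months, keeping the phenotype row's
date; an equidistant tie goes to the earlier row — a repository decision,
made for determinism, since no convention forces either side.

## L2C transformation

Each continuous modality contributes seven temporal summaries and the
diagnosis trajectory eight (64 engineered features), plus six covariate
augmentations (70 total).  Design choices that were genuinely open:

- **Reference point of `time_since_*`.**  All recencies are measured from
  the forecast time t_f, not from the last input visit.  The same quantity
  (time since the target's most recent measurement) drives window selection
  in the windowed forecaster, so one definition serves both.
- **Change rate.**  `mr_change` uses only the two most recent observations
  of the modality, matching the "most recent" reading; no regression over
  the full series.
- **Extreme-value ties** resolve to the most recent occurrence — the more
  recent extreme is the more clinically relevant, and the rule is
  deterministic.
- **"Milder" diagnosis** means strictly milder than the *most recent*
  diagnosis (not the worst).  The feature then pairs with `mr_dx` to flag
  past improvement; reading it against the worst diagnosis would make it
  redundant with `best_dx < worst_dx`.
- An empty modality series yields all-NaN features; a single observation
  leaves only the change rate missing.  Age at t_f is extrapolated
  linearly from the last observed age (age advances deterministically).

Training samples: every prefix of length p ∈ 1..m−1 predicts every later
visit, m(m−1)/2 candidates; candidates whose target visit observes none of
the three targets are dropped.

## Preprocessing for the network

Tree learners consume the raw 70-column frame (NaN passes through).  The
network path drops `time_since_milder` (dominated by the 999 sentinel and
diagnosis missingness), imputes numeric features with training medians,
applies Gauss-Rank normalization — averaged ranks mapped through
Φ⁻¹((r−0.5)/n), linear interpolation between knots, clipping outside the
training range — and one-hot encodes discrete features over the training
vocabulary plus an explicit unknown class that absorbs missing and unseen
values.  Regression targets get their own Gauss-Rank maps fit on training
targets; losses are computed on the Gaussian scale and predictions
inverse-mapped before metrics.  Every statistic is fit on training rows
only and frozen into a JSON-serializable state.

The encoded design width follows from this package's vocabularies
(diagnosis categories CN/MCI/DEM + unknown; sex, marital, APOE, milder
analogously) rather than any externally fixed number: 62 numeric + 25
indicator columns = 87.  The width is asserted fixed per fit, not matched
to an outside constant.

## Forecasters

**Windowed gradient boosting (`xgb_w`).**  One XGBoost estimator per
(target, forecast-gap window): MMSE windows 0–9, 9–15, 15–27, 27–39, >54
months; diagnosis 0–8, 8–15, 15–27, 27–39, 39–60, >60; ventricle 0–9,
9–15, 15–30, >30 — fifteen models.  Intervals are closed on the left, open
on the right.  The MMSE specification leaves (39, 54) uncovered; gaps in
the hole route to the adjacent 27–39 model (nearest lower boundary), a
deterministic repository decision.  The gap is the time since the most
recent observed measurement of the target variable, identically at
training-sample assignment and at prediction; when the target was never
observed the gap is undefined, no model is selectable, and the prediction
is reported unavailable rather than guessed (evaluation skips it and
reports coverage).  Searchable hyperparameters: max depth 3–8, subsample
0.4–1, learning rate 0.01–0.2; defaults sit mid-range (4 / 0.8 / 0.1, 100
trees).

**Single gradient boosting (`xgb_nw`).**  One estimator per target over
all gaps; the recency features already encode the temporal information the
windows hard-code.

**Multi-task network (`fnn`).**  Hidden layers (2–5 layers, 128–512 units)
with LeakyReLU (slope 0.01–0.1) and dropout (0–0.5); a five-unit head:
three softmax diagnosis probabilities, MMSE and ventricle on the
Gauss-Rank scale.  Per-sample loss = cross-entropy + MAE + MAE, each term
masked by target availability and summed with equal weights (the
Gauss-Rank scale makes the magnitudes comparable).  Optimizer: SGD with
momentum (0–0.9), learning rate 1e-5–1e-1 decaying by γ ∈ 0.1–0.9 per
epoch; fixed 100-epoch budget, batch 512, no early stopping, so a seed
fully determines the fit.  The network is implemented directly in numpy,
which keeps training bit-reproducible and the dependency surface small.
Hyperparameter search, where used, is plain random search over these
ranges scored on the validation split (validation mAUC plus negative
normalized MAEs, equal weights).

**Carry-forward baseline.**  Probability one on the last observed
diagnosis (uniform if never observed); last observed MMSE and
ventricle/ICV, training medians if never observed.

**CDR conversion.**  A continuous CDR prediction maps to (CN, MCI, DEM)
probabilities piecewise-linearly between anchors 0 → CN, 0.5 → MCI,
≥1 → DEM; e.g. 0.1 → (0.8, 0.2, 0) and 0.6 → (0, 0.8, 0.2).  Negative
scores clip to zero.  The conversion is continuous on [0, 1] and always
sums to one.

Predictions are post-processed: MMSE clipped to [0, 30], ventricle/ICV to
non-negative, probabilities renormalized within 1e−6.

## Evaluation protocol

Validation/test participants are split first-half → second-half at the
visit level; odd visit counts give the extra visit to the input side
(⌈m/2⌉), maximizing observed history — the even case is the only one the
protocol pins down.  Folds are cyclic: partition i tests, partition i+1
validates, the rest train; test sets are disjoint and exhaustive.
Forecasts are evaluated only at actual second-half visit months (truth
exists only there): each target visit pairs with the nearest monthly grid
row, ties to the earlier month, visits beyond the horizon excluded and
counted.

Metrics: pooled mAUC (one-vs-rest AUCs by rank statistic with tie
correction, averaged over classes computable in the pooled truth; an
absent class is skipped with a log message — small synthetic strata can
lack a class, which the original protocol never faces); per-participant
MAE and RMSE, averaged within participant first.

Statistical machinery: corrected resampled t-test with
ρ = test/train fraction = 1/19 for the 20-partition design (the validation
partition counts on the training side since it influences model
selection); ρ = 0 recovers the classical one-sample t.  The permutation
scheme for pooled mAUC swaps the two models' probability rows per time
point with probability ½ (the add-one-smoothed p is bounded below by
1/(1+n_perm)); the exact published scheme is not specified in accessible
form, so this choice is documented rather than attributed.  Yearly horizon
bins close on the right at 12-month multiples (a 10-month gap is year 1),
capped at 6.  The varying-input analysis truncates test inputs to 1–4
visits and keeps only participants whose input half has ≥4 visits so the
same participants appear in all conditions.  The ablation analysis
restricts to participants whose input half observes every recurring
feature at least once, blanks one modality across all input visits, and
compares against the full feature set; deltas are oriented so positive
means degradation.

## Synthetic cohort generator

The generator exists so that every pipeline stage is testable without
restricted data; it emulates structure, not any particular dataset.  Each
participant draws a baseline age (N(73, 7.2²) years), an APOE-ε4 count
(P = 0.5/0.4/0.1 for 0/1/2 alleles) and a latent onset age
(N(75, 6²) minus 2.5 years per allele, so baseline covariates carry
signal).  Disease time s = age − onset drives logistic trajectories:
MMSE declines (30 → 0, slope 0.20/yr, inflection at s = 13 yr), grey-matter
volumes shrink, ventricles expand (25 → 75 mL, inflection s = 6 yr).  CDR
is a staircase over s jittered by N(0, 1 yr) with thresholds 0/4/8/12/16 yr
for 0/0.5/1/2/3; diagnosis maps CDR 0 → CN, 0.5 → MCI, ≥1 → DEM with 5%
independent label-flip noise.  Visits: count uniform in 2–12, intervals
uniform in 6–12 months.  Missingness is MCAR per modality-visit
(cognitive 30%, MRI 39%, diagnosis 30% under the ADNI-like preset), with
the first two visits exempted whenever a draw would break eligibility.

Site presets (`adni_like`, `macc_like`) shift onset, visit schedules and
missingness to create the cross-site contrast (the memory-clinic-like
preset is more impaired with near-complete cognitive ascertainment but
heavier MRI missingness); preset values live in YAML files, and each
preset documents its own empirical baseline-MMSE target used by sanity
checks.  Under these settings the default cohort has roughly 20% dementia
at baseline; the observed baseline MMSE mean (~25.5) is lower than a real
mildly-impaired research cohort's because the generator has no enrolment
truncation of severe cases — a documented mismatch, acceptable because the
cohort's role is exercising the pipeline, not mimicking any dataset's
marginals.  What passing tests on this cohort show is that the pipeline
extracts real longitudinal signal under realistic missingness; they cannot
show robustness to MNAR missingness, site effects in measurement, or
non-logistic trajectories, none of which the generator produces (a
severity-dependent missingness hook exists for stress tests).

## Problem sizes and numerical choices

The test suite's end-to-end benchmark uses the default simulated cohort
(n = 500, seed 0), a single cyclic train/test split (k = 5 partitions, one
fold) for the three-variant versus baseline comparison, and a k = 3 harness
run for the stratified analyses — sizes chosen to keep the default test
run in the minutes range while leaving the learned-versus-baseline margin
wide (pooled mAUC ≈ 0.94 versus ≈ 0.79).  Gauss-Rank round-trips are exact
at knots and tested to 1e−6; mAUC is verified against an O(n²) pairwise
oracle to 1e−12; probability simplex checks use 1e−6.  Degenerate inputs
are defined rather than left to chance: constant columns degrade to a zero
map with a warning, all-missing training columns are a configuration
error, zero-variance zero-mean fold differences give t = 0 and p = 1, and
single-class windowed cells fall back to a constant-outcome predictor.

## Known limitations

- The MCAR missingness model understates the informative missingness of
  clinic data.
- The network's input width is derived from this package's vocabularies,
  not matched to any external dimensionality.
- The permutation scheme for pooled mAUC and the corrected-t ρ are
  reasoned defaults, not reconstructions of any particular study's
  unpublished choices.
- The windowed variant leaves MMSE gaps in (39, 54) routed by a
  nearest-lower-boundary rule that the window specification itself does
  not determine.
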