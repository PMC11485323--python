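# Methods

This note records the models, conventions and design choices behind
`neovital`, in the order data flows through the package.

## Grid, windows, day validity

All analysis runs on a uniform 2-second grid. Irregular monitor streams
(1-s or 1024-ms displays) are sub-sampled, not interpolated: grid slot `g`
takes the latest raw sample in `(g − 2 s, g]` and is otherwise missing.
Windows are 300 samples (10 min), tiled consecutively from each infant's
first grid time (not clock-aligned; the tiling origin is arbitrary and this
is the simplest deterministic choice). A window enters feature extraction
only if ≥ 75 % of its samples are present in each signal; the threshold is
a package default (`min_completeness`), configurable, since no canonical
window-validity rule exists for this kind of data. A calendar day of life
(birth day = day 1) is *valid* when both HR and SpO₂ have at least 12 h of
non-missing samples (≥ 21 600 samples each); exactly 12 h counts.

## Window features

33 features per window: 16 on HR, 15 on SpO₂, plus the maximum and minimum
HR×SpO₂ cross-correlation over integer lags in ±15 samples (±30 s).
Conventions shared by all of them:

* Moment statistics use the non-missing samples; `std` is the n−1 sample
  standard deviation, skewness/kurtosis are standardized central moments
  (kurtosis of a normal is 3), the trimmed mean discards 10 % per tail.
* Sequence statistics (symbol words, pairs, transitions, autocorrelation
  pairs, the walker) are computed within contiguous non-missing runs and
  pooled, so nothing ever spans a monitoring gap.
* A feature whose preconditions fail (zero variance, too few symbols)
  is NaN — recorded, never dropped.

Symbolic features use two 3-symbol codings: successive differences
(increase / exactly-equal / decrease — the equality band is δ = 0 because
monitor HR is integer-valued, so ties are real), and per-window empirical
tertiles with ties assigned to the lower bin. Motif entropies are Shannon
entropies, in nats, of the distribution of overlapping length-4 words
(3⁴ = 81 possible patterns, so the range is [0, ln 81 ≈ 4.394]); a
bits-based variant is exposed as an option. `hr_probincreases` recodes
differences as up vs not-up and reports the frequency of `uu` among
adjacent symbol pairs.

The walker statistic simulates a particle with inertia: w₁ = x₁, w₂ = x₂,
then wᵢ = w_inert + (xᵢ − w_inert)/m with w_inert = 2wᵢ₋₁ − wᵢ₋₂ and mass
m = 5 (configurable); the feature is σ(w)/σ(x). The update is a resonant
AR(2) filter with poles at radius √0.8 and a gain peak near a 27-s period:
slow persistent patterns (long desaturations) give ratios near 1,
mid-frequency variability is amplified to ratios well above 1, and white
noise is attenuated to ≈ 0.64. With m = 1 the walker *is* the signal and
the implementation returns exactly 1.0 (the naive IEEE evaluation of
`a + (b − a)` does not reproduce `b` exactly).

Auxiliary-feature parameterizations are conventional defaults, exposed in
a serializable registry so they can be overridden without code changes,
and should be treated as provisional: clipped means clip HR to [50, 250]
and SpO₂ to [50, 100]; `corrmean` is the mean of the 3-point moving
average; `surprise` is the mean −log probability of observed first-order
tertile-symbol transitions; the wavelet features are the fraction of
detail energy at level 3 of a 4-tap Daubechies (db2) decomposition,
computed with periodized boundaries on the longest run truncated to a
multiple of 8 samples (this makes the transform exactly defined and
independently checkable); `derivative` is the sample std of the second
difference; `symeigen` is the population std of the eigenvalue moduli of
the 3×3 tertile transition matrix (unobserved rows set uniform);
`symbin` is the longest streak of not-above-mean samples over the count
of non-missing samples (a constant window scores 1); `symiqr` is the
switch rate of the inside/outside-interquartile-range coding.

`compute_feature_vector` evaluates all 33 through a shared per-signal
context (runs, moments and symbol sequences computed once); the test suite
verifies on randomized windows that this fast path, the public one-feature
functions, and independent straight-line transcriptions of each definition
agree to 1e-10.

## Events

IH80 (SpO₂ < 80 %), IH90 (SpO₂ < 90 %) and Brady80 (HR < 80 bpm) events
are maximal runs of consecutive non-missing samples strictly below
threshold. Durations are below-threshold sample counts × 2 s. The IH
duration filter 10–300 s is inclusive on both ends, and an over-length
desaturation yields *no* event (filtered, not truncated) — a choice worth
a sensitivity analysis in any reanalysis. Brady80 requires ≥ 5 s with no
upper bound. Missing data terminates an event rather than bridging it, so
dropout never fabricates hypoxemia; optional `bridge_gap_s` (credit no
duration to the gap) and `join_gap_s` (merge nearby events, gap counted in
the joined episode) parameters exist but default to off. Events belong to
the day containing their start.

Daily statistics per kind: `count` (events/day), `dur` (minutes/day), and
`dpe` = 60·dur/count (seconds/event), undefined when count = 0. A
zero-count day stores `dpe` as missing, not 0 — zero would conflate "no
events" with "instantaneous events". Models using `dpe` impute missing
cells at the column's minimum observed value (an event-free day behaves
like a day of minimal-duration events); this imputation is this package's
choice, configurable at the model-matrix level.

## Daily table

Each valid infant-day carries the median of each feature over that day's
valid windows (median of the defined values only; even counts take the
midpoint) plus the 9 event statistics: 42 candidate metrics in a stable,
versioned column order, joined to the outcome table on infant id. Infants
with vitals but no outcome record are dropped with a logged warning.

## Outcomes and evaluation

The 5-level respiratory outcome (Death > Severe > Moderate > Mild >
Favorable) maps to 4 nested flags: `unfavorable` (≠ Favorable),
`mod_sev_death`, `sev_death`, `death`.

**AUC.** Rank-based concordance with mid-rank ties, pairwise deletion of
missing values, oriented to ≥ 0.5 with the sign recorded. Univariable
metric ranking uses this raw concordance, unadjusted.

**Clustered CV.** Pregnancy clusters (siblings) are shuffled by seed,
sorted largest-first, and greedily assigned to the lightest of 10 folds, so
a twin never helps predict its sibling and fold sizes stay balanced; the
no-straddling invariant is asserted on every run. Per fold, an unpenalized
logistic model is fit on standardized training features; held-out linear
predictors are centered per fold and pooled into one AUC. Centering
matters: fold intercepts track the training split's prevalence, which
anti-correlates with the held-out fold, and pooling raw probabilities
biases a label-shuffled null AUC to ≈ 0.44; centered scores are
rank-equivalent within folds and restore the null to 0.5. Default seed
20240603.

**Risk curves.** Signature-of-risk curves fit a logistic model on a
restricted cubic spline of the metric with 3 knots at the 10th/50th/90th
percentiles (k − 1 = 2 design columns, linear tails), evaluated on a
100-point grid spanning the central 99 % of the metric, with pointwise
95 % Wald intervals on the linear predictor mapped through the inverse
logit. Grid points whose interval excludes the cohort event rate are
flagged, and the central-95 % limits of the metric distribution are
reported.

**Fixed model and importance.** The fixed 3-feature model uses `sp_walk`,
`sp_mean` and `hr_entropy_diff` with linear terms (splines are reserved
for single-metric curves). Variable importance is the drop in CV-AUC when
one variable is removed, same folds. Feature selection is a greedy
forward-backward search: add while the best candidate gains ≥ 0.005
CV-AUC, then drop any feature whose removal costs ≤ 0.005; ties break
alphabetically. On pure noise this policy returns at most one (spuriously
best) metric.

**Trajectories.** Per-day AUC for days 1–56; the smoothed value at day d
averages the defined AUCs in [d − 2, d + 2], skipping gaps.

## Synthetic cohort

The generator exists so every stage above is testable without data access,
and doubles as a ground-truth instrument: a latent severity s ~ N(0, 1)
(correlated 0.7 within twin pregnancies, twins in 12 % of pregnancies)
drives every risk link, and outcomes come from an ordered logit on s with
thresholds set to the nested prevalence profile 45.4 / 20.7 / 13.7 / 6.8 %.

Per infant (integer-rounded, as monitors display):

* **SpO₂** = baseline (96.5, minus 0.3·expit(s)) + a quasi-periodic
  oscillation with a ~25-s period (resonant AR(2), pole 0.95) whose
  amplitude *shrinks* with severity — the periodic-breathing-like
  variability of stable preterm infants — + a slow wander (AR(1), pole
  0.995, ≈ 7-min correlation time) whose amplitude *grows* with severity
  (unstable oxygenation control) + white noise (sd 0.5), with trapezoidal
  desaturation dips (20 % fall, 60 % dwell, 20 % recovery) at a
  severity-increasing rate (2.5/h at s = 0, log-slope 0.4, capped 20/h)
  with severity-increasing lognormal durations (median 20 s, log-slope
  1.0, log-sd 0.35) and depths (8 + 5·expit(s) %).
* **HR** = per-infant baseline (155 ± 5) + AR(1) (φ = 0.97) whose
  innovation scale shrinks with severity (1.2 bpm × (1 − 0.35·expit(s))),
  plus occasional bradycardia dips at a severity-linked rate. The
  suppression is calibrated so that high-severity records fall into the
  dominant-unchanged-HR regime (successive differences mostly rounding to
  zero), which is what makes the difference-symbol entropy drop with
  severity; weaker suppression leaves the "same"-symbol probability near
  1/3 on both sides and the entropy–severity relation non-monotone.
* **Gaps**: missing-data gaps (mean 2 min, geometric) at a rate giving 8 %
  missingness per signal, independent of severity.
* **Heterogeneity**: per-infant lognormal frailties on HR variability
  (log-sd 0.3) and desaturation rate (log-sd 0.4) decouple those channels
  partially from severity, as in real cohorts.

These structural choices were calibrated so the generator meets its own
design goals — the walker/autocorrelation features and the IH90
duration-per-event metrics top the metric ranking, and sp_walk correlates
strongly negatively with ih90_dpe (≈ −0.9 across infant-days) — i.e. the
generator reproduces the qualitative risk structure of real NICU cohorts.
What it does **not** emulate: oximeter averaging-time effects, motion
artifact, day-of-life maturation trends, apnea/periodic-breathing
mechanics coupling HR and SpO₂, site or device differences, informative
missingness, and clinical interventions reacting to the vitals. Passing
tests on this cohort demonstrate that the pipeline recovers planted
structure; they say nothing about effect sizes in real infants.

A separate binormal construction (`designed_auc_cohort`) draws a single
marker from N(0, 1) for controls and N(δ, 1) for cases with
δ = √2·Φ⁻¹(AUC*), giving a cohort whose population AUC is exactly the
target; it anchors the evaluation-recovery tests.

Everything is deterministic under the master seed; each infant's signals
re-generate lazily from a per-infant child seed, so cohorts of any size
stream through the pipeline without being held in memory.

## Problem sizes and numerical notes

The test suite runs the full pipeline on 200 infants × 5 simulated days
(≈ 144 000 windows, a few minutes on one CPU) for ranking recovery, 5 000
infants for designed-AUC recovery, and 100 randomized windows for oracle
equivalence at 1e-10. Because a single label-shuffled null CV-AUC has a
standard deviation of ≈ 0.013 at n = 5 000, null checks average several
shuffles rather than widening tolerances. Feature evaluation avoids
catastrophic cancellation by centering before forming correlation sums;
percentile-based bin edges follow the linear-interpolation convention.

## Known limitations

* The exact parameterizations of several auxiliary features (clip ranges,
  wavelet family/level, transition-matrix conventions, walker output
  statistic) follow conventional choices; alternative published
  parameterizations exist and the registry makes swapping them cheap.
* Day-of-life numbering uses calendar days from the birth date; records
  starting mid-day have a short day 1.
* The evaluation module assumes one row per infant-day; repeated-measures
  correlation across days is handled only through clustering at the
  pregnancy level, not modeled longitudinally.
* Real-cohort effect sizes (published AUC tables) are not reproducible
  from synthetic data and are out of scope here.
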