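# Methods

This note documents the models, estimators, parameter choices and known
limitations of the `awakeosa` package. Empirical statements below are
restricted to what the test suite and `scripts/acceptance.py` actually
compute.

## Problem setting

The package screens for obstructive sleep apnea (OSA) at the clinical
severity threshold AHI = 15 events/hour, using tracheal breathing sounds
recorded during wakefulness (nose and mouth maneuvers, five deep breath
cycles each, followed by a breath-hold silent period) together with
anthropometrics: age, sex, BMI, neck circumference (NC), Mallampati score
(MpS). The central modelling assumption is that OSA-associated upper-airway
remodelling changes the spectral balance of breathing sounds during
wakefulness, but that anthropometric confounders modulate those changes —
hence features are selected and classifiers trained *within* anthropometric
subgroups, and the subgroup decisions fused by a reliability-weighted vote.

## Signal processing

**Segmentation.** Breath phases are detected with a short-time energy
envelope (50 ms frames, 10 ms hop). The threshold is bootstrapped from the
envelope's 10th/90th percentiles and refined once to the midpoint between
the median burst and median quiet energies; sub-50 ms gaps are bridged and
bursts shorter than 0.25 s discarded. Phases alternate starting with
inspiration (the recording protocol marks the first inspiration). The
silent period is the longest sub-threshold stretch. A manifest-supplied
boundary table overrides automatic segmentation. On generator output the
automatic boundaries match ground truth within ±50 ms (tested).

**Quality screening.** A phase is rejected when its broadband SNR against
the silent period falls below 10 dB (package default; only a qualitative
"low SNR" criterion exists upstream) or when more than 1% of samples sit at
full scale. A subject needs at least two clean cycles per maneuver/phase;
combinations failing that contribute missing features instead of excluding
the subject outright.

**Welch PSD.** Hann window, 1024-sample segments, 50% overlap, one-sided
density scaling; at the 10 240 Hz default sampling rate this gives a 10 Hz
grid covering the 2100–2400 Hz band with margin. The sampling rate is
configurable (the source protocol does not state one; 10 240 Hz was chosen
so all analysis bands fit below Nyquist with margin). Per-subject spectra
are linear-power averages over clean cycles. Parseval consistency (integral
of the PSD ≈ signal variance within 5%) is enforced by test.

**Indirect bispectrum.** The third-order cumulant c3(m, n) is estimated to
max lag 255 with unbiased normalization, computed for m ≥ 0 via FFT
cross-correlations of lagged products and completed with the cumulant
symmetries; it is tapered with the product Parzen window w(m)w(n)w(m−n) and
transformed with a 512-point 2-D FFT (20 Hz grid). Magnitudes are read
along four bifrequency lines: the main diagonal (f, f), the anti-diagonal
of the band square, and the (f, f/2) and (f, 2f) lines. "Weight center" is
the magnitude-weighted mean frequency Σf·|B| / Σ|B|; first/second-order
moments are the unnormalized averages Σf^k·|B| / N — the two are kept
numerically distinct because they are listed as distinct features. Against
an independent direct FFT-product oracle on 1024-sample
quadratically-phase-coupled signals, the coupled-peak location agrees to
one grid bin and the band-mean magnitude to well under 10% (tested).

**Fractal features.** Katz FD (path length vs diameter; exactly 1 for
straight lines), Higuchi FD (k_max = 16), and the Hurst exponent by
rescaled-range analysis over dyadic windows (≥ 16 samples) with the
Anis–Lloyd–Peters small-sample correction: H = 0.5 + slope of the excess
log R/S. Breathing phases are treated as stationary series (R/S applied to
their cumulative sum); integrated inputs can be differenced via
`kind="levels"`. Calibration (tested): white noise gives H = 0.50 ± 0.05
and Higuchi FD = 2.0 ± 0.1; synthesized fractional Gaussian noise with
H = 0.8 is recovered within ±0.1.

## Feature bank

The catalog holds 254 features: the 26 published subset-specific features
(with features 9 and 10 marked as alternatives, never co-occurring in one
combination) plus an exploratory grid — for each maneuver × phase and each
fixed band (100–300, 350–600, 1000–1700, 2100–2400 Hz): band mean,
geometric mean, mean slope, centroid, centroid bandwidth ("bandwidth of the
spectral centroid" is implemented as the spectral spread), mean
maximum-peak frequency, and seven bispectral line statistics; plus
first-peak frequency (cutoff 550 Hz), a low-minus-high band-mean
difference, and the three fractal descriptors. Mean/slope/difference
operators act on the dB scale, centroid-type and geometric operators on the
linear scale (configurable per definition). Peak operators use a 3 dB
prominence floor and return missing values when no peak qualifies.

Scaling is min-max to [0, 1], fit on training rows only (leakage-safe;
whether the original fit used all data is unstated), with test values
clipped to [0, 1] and constant features dropped.

## Feature reduction

Stages, in order, each operating only on survivors of the previous one:

1. **Significance**: Welch's unpaired t-test (the unequal-variance form is
   the safer default where only "unpaired t-test" is specified; pooled
   variance available by flag); keep p ≤ 0.05.
2. **Robustness**: 20 rounds; per round each severity group is shuffled and
   chunked into covering 15-member subgroups (a short remainder group is
   topped up by resampling already-assigned members, so everyone is
   selected at least once per round); every non-OSA × OSA subgroup pairing
   awards a feature one point when the t-test is significant *and* both
   subgroups pass the Lilliefors normality check at α = 0.05. Keep features
   scoring > 0.6 × the best observed score. The Lilliefors statistic is
   computed vectorized over features; critical values come from
   statsmodels' table and the per-column decision is verified against
   `statsmodels.stats.diagnostic.lilliefors` by test. When a severity group
   is smaller than 15 the subgroup size shrinks to the group size (with a
   warning); below 5 the stage is skipped.
3. **Redundancy**: features correlated at |r| ≥ 0.9 are clustered by
   transitive closure; each cluster keeps the feature with the best
   single-feature linear-SVM training accuracy (sensitivity + specificity,
   then feature id, as tie-breaks).
4. **Effect size**: Glass's delta (group mean difference / non-OSA SD) is
   reported for every kept feature; the default filter keeps |Δ| > 0.8.

No multiple-testing correction is applied; the robustness stage is the
procedure's surrogate for it. Simulation behavior (tested): on null
features the significance stage retains 5% ± 2%; a null feature clears the
0.6 × max robustness threshold in well under 5% of runs; designed 6-SD
features are never rejected by the significance or robustness stages.

## Subset training

Subsets: BMI < 35, age > 50, age ≤ 50, male, NC > 40, MpS ≤ 2 (membership
may overlap; sizes below 30 non-OSA / 20 OSA raise a warning, matching the
design minimum). The severity threshold for labels is AHI ≥ 15, but feature
reduction uses only the clearer cases (AHI ≤ 10 or ≥ 20); subjects in
between still join classifier training. Neck circumference enters the
candidate pool of every subset except its own.

**Outlier fences.** Per feature and severity group, the boxplot adjacent
values (extreme observations within Q1 − 1.5·IQR … Q3 + 1.5·IQR,
linear-interpolation quartiles); the merged fence is the lowest lower and
highest upper adjacent value. Values outside the fence become missing;
fencing is idempotent. Fences are computed on the scaled table — min-max
scaling is a monotone affine map, so quartiles and adjacent values commute
with it exactly.

**Combination search.** All 3-/4-feature combinations of the candidate
pool. Each is trained 3 times (seeds s, s+1, s+2) as a random forest with
2/3-in-bag bootstrap, Gini splitting, per-split random predictor
subsetting, and misclassification costs inversely proportional to class
prevalence; OOB votes give accuracy, sensitivity (OSA recall) and
specificity (non-OSA recall). Combinations with any of the nine values
below 0.7 are dropped; among survivors, those whose mean accuracy lies
within max(largest observed accuracy spread, 2%) of the best mean are
shortlisted. The ambiguous "maximum difference or 2%" window is resolved as
lower bound = best − max(max_difference, 0.02), which guarantees a
non-degenerate window. The shortlist is re-scored with 5 repetitions and
the winner chosen by mean OOB accuracy (ties: sensitivity + specificity,
then lexicographic ids). Selection uses validation (OOB) accuracy only —
consulting blind-test accuracy, as the original protocol also did, leaks
test information; the leakage-safe variant is the default. The "interaction
curvature" predictor-selection heuristic of the original MATLAB forests has
no scikit-learn equivalent; standard Gini splitting with random predictor
subsetting is used instead.

## Voting

Every subset model votes on every subject (subset membership does not gate
voting; a membership-only mode is a documented alternative). A model
abstains when any of its combination features is missing after fencing;
abstentions are skipped from the vote mean by default (a zero-vote policy
is available). d = 0 exactly is called non-OSA with a tie flag. |d| > 0.7
is reported as a high-confidence flag without any attached probability
claim. Leave-one-subset-out ablation and correlations of the selected
combinations with AHI and log(AHI) (least-squares fit, Pearson r between
fitted and observed) are provided as diagnostics.

## Synthetic cohort generator

The generator reproduces the *statistical* structure the pipeline feeds
on — it is not an acoustic model of the trachea:

- **AHI**: truncated normals per group — non-OSA 3.59 ± 3.95 on [0, 15),
  OSA 42.85 ± 32.72 on [15, ∞) (group moments from the study population;
  the truncated-normal family is the package's choice).
- **Anthropometrics**: a 4-variate Gaussian copula links AHI with BMI, NC
  and MpS. The latent within-group correlations (0.45, 0.18, 0.12) were
  calibrated once, by simulation against the generator's own targets, so
  the pooled correlations land near r = 0.44 (BMI), 0.43 (NC), 0.26 (MpS);
  group means/SDs for age, BMI, NC, the MpS category frequencies and the
  sex ratios follow the reported cohort tables.
- **Audio**: five cycles of (inspiration 1.0 s, expiration 0.9 s, 0.3 s
  gaps) plus a 2.5 s silent tail at 10 240 Hz. Bursts are white noise
  shaped by a per-subject spectral envelope: a first resonance at 300 Hz
  (non-OSA) vs 350 Hz (OSA), a second at 1280 vs 1380 Hz, a spectral slope
  over 250–350 Hz of −0.030 dB/Hz (non-OSA) vs +0.030 dB/Hz (OSA) whose
  offset persists above the band, and a +4 dB OSA shelf above 2100 Hz — so
  every fixed analysis band carries some group information. A
  quadratically phase-coupled tone triple (pair at 170/260 Hz non-OSA vs
  210/320 Hz OSA) gives the bispectral features genuine structure.
  Per-subject jitter (slope SD 0.012 dB/Hz, resonance SD 18 Hz, gain SD
  1.2 dB, level SD 1 dB) sets the designed effect sizes; the contrast-band
  slope separates groups with Glass's delta ≈ 4 and the correct signs in
  ≥ 95% of seeds (tested).

What passing tests on this generator do **not** show: robustness to real
recording conditions (sensor placement, ambient noise, flow-rate
variability, comorbidities), to inter-site hardware differences, or to the
much weaker and messier group contrasts of clinical audio. The generator's
contrasts are deliberately clean so that pipeline defects are not masked by
noise.

## Problem sizes and runtime profile

Defaults follow the full protocol (1200 trees, uncapped candidate pools,
double precision, all cycles). For single-CPU runs the
`PipelineConfig.desk()` profile is used by the test suite: 300 trees,
candidate pool capped at the 4 most robust features per subset (plus NC),
the combination shortlist capped at the 6 best mean accuracies, and
bispectra in single precision from the first 0.6 s of the first two clean
cycles per maneuver/phase with max lag 127. These are estimator
problem-size choices, documented here as such; the protocol structure
(stages, thresholds, repetition counts) is identical in both profiles. The
study-scale run uses the generator defaults: 199 subjects (109/90) split
113 train / 86 blind-test.

## Degenerate inputs and numerical conventions

- Zero-variance signals: PSD raises; Katz FD returns 1 by convention;
  Higuchi FD and Hurst return missing.
- Bands are closed intervals; a grid point belongs to a band iff
  f1 ≤ f ≤ f2. PSD band statistics need ≥ 3 grid points.
- Bifrequency line samples round the partner coordinate to the nearest
  grid bin and drop points leaving the grid.
- d = 0 votes, all-abstain subjects, constant features, sub-minimum
  severity groups: all handled explicitly (tie flag, unclassifiable flag,
  drop-with-warning, shrink-with-warning respectively).
- All stochastic steps derive child seeds from one master seed via
  `numpy.random.SeedSequence`; repetition r of a repeated training uses
  seed + r. Fixed seeds reproduce byte-identical cohorts and identical
  OOB metrics.
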