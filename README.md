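# awakeosa

Screening for obstructive sleep apnea (OSA) during **wakefulness**, from a
few minutes of tracheal breathing sounds plus basic anthropometrics.

Overnight polysomnography (PSG) — the diagnostic gold standard — is slow and
expensive, and questionnaire-style screeners have poor specificity. The idea
implemented here is that OSA-related upper-airway changes (narrowing, tissue
stiffening, loss of muscle tone) color breathing sounds even while the
subject is awake, and that these acoustic signatures are confounded by
anthropometric factors (age, sex, BMI, neck circumference, Mallampati
score). The screener therefore works **per anthropometric subgroup** and
fuses the subgroup decisions with a reliability-weighted vote.

## The procedure

For each subject, nose and mouth breathing recordings (5 deep breath cycles
plus a breath-hold "silent period") are segmented into inspiratory and
expiratory phases, quality-screened against the silent period, and
summarized per maneuver/phase by:

- the Welch power spectrum `P(f)` — band means, geometric means, mean
  spectral slopes, centroids and spreads, peak frequencies over four
  analysis bands (100–300, 350–600, 1000–1700, 2100–2400 Hz);
- the indirect-class bispectrum `B(f1, f2)` (third-order-cumulant estimate,
  Parzen lag window) — means, weight centers and moments of `|B|` along the
  main/negative diagonals and the `(f, f/2)` / `(f, 2f)` lines;
- time-domain fractal descriptors — Katz and Higuchi fractal dimensions and
  the rescaled-range Hurst exponent.

The ~250 features are min-max scaled to `[0, 1]` (parameters fit on training
rows). Within each anthropometric subset (BMI < 35, age > 50, age ≤ 50,
male, NC > 40, MpS ≤ 2) the pool is reduced by: unpaired t-test (keep
p ≤ 0.05) → robustness scoring over random 15-member subgroups gated by the
Lilliefors normality test (keep score > 0.6 × max) → correlation-redundancy
removal at |r| ≥ 0.9 (keep the best single-feature SVM performer per
cluster) → Glass's delta effect-size check (|Δ| > 0.8).

Surviving features (plus neck circumference outside its own subset) form
all 3-/4-feature combinations; each is scored by repeated random-forest
out-of-bag (OOB) validation (2/3 in-bag bootstrap, Gini splitting,
prevalence-balanced misclassification costs), with outliers fenced at
boxplot adjacent values. The best combination per subset becomes that
subset's classifier.

**Voting.** Each subset votes on every subject: an OSA vote contributes
`+1 × OOB sensitivity`, a non-OSA vote `−1 × OOB specificity`; the final
decision is the mean

```
d = mean_k ( label_k × weight_k ),   d ∈ [−1, 1]
```

with `d > 0` → OSA (AHI ≥ 15), `d < 0` → non-OSA, and `|d| > 0.7` flagged as
high-confidence. With six subsets at 100% sensitivity and specificity, a
unanimous OSA vote gives exactly `d = +1` and a unanimous non-OSA vote
`d = −1`.

Because no recordings are publicly deposited, the package ships a
synthetic-cohort generator (`awakeosa.synthetic`) reproducing the
statistical structure the method assumes: group AHI distributions,
anthropometric–AHI correlations (r ≈ 0.44 BMI, 0.43 NC, 0.26 MpS), and
breathing-sound spectra whose slope above 250 Hz rises for OSA subjects and
falls for non-OSA subjects.

## Worked example

```bash
python examples/05_voting_arithmetic.py
```

prints

```
six unanimous OSA votes, perfect weights:     d = +1.000
six unanimous non-OSA votes, perfect weights: d = -1.000
votes (+0.84, -0.875, +0.80):                 d = +0.255 -> osa
```

The first two lines are the voting identities (perfect subsets in perfect
agreement saturate the decision scale); the third is a weak OSA call — two
subsets vote OSA with sensitivities 0.84 and 0.80, one votes non-OSA with
specificity 0.875, and the mean lands at +0.255, well below the 0.7
high-confidence threshold.

`examples/01_simulate_cohort.py` … `04_train_and_screen.py` walk through
cohort simulation, band discovery, feature reduction, and a miniature
train/blind-test cycle. For a shell workflow there is also a thin CLI:

```bash
awakeosa simulate --n-non-osa 109 --n-osa 90 --seed 7 --out cohort/
awakeosa train --manifest cohort/manifest.csv --out model/
awakeosa screen --model model/ --manifest cohort/manifest.csv --out decisions.csv
```

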