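# Methods

## Problem and scope

`emofuse` classifies positive vs negative emotional valence from multi-channel
EEG across subjects — the hard setting where the classifier is trained on some
people and tested on entirely different people. The package implements the
complete classical workflow: preprocessing of DEAP-shaped recordings (per
subject: trials × 32 channels × 128 Hz signal with continuous self-report
ratings), a 249-dimension feature battery, two-stage feature selection, and a
stacking-style multi-classifier fusion stage, evaluated with subject-disjoint
hold-out and leave-one-subject-out (LOSO) protocols.

## Preprocessing

* **Trimming.** Only the final 40 s of each trial are analysed; early samples
  are discarded because subjects need time to enter the target emotional
  state. Trimming always counts back from the end of the trial, which handles
  both 60 s trials and baseline-padded 63 s trials uniformly.
* **Windowing.** Trials are sliced into contiguous, non-overlapping 10 s
  windows (1280 samples at 128 Hz), so a 40-trial subject yields 160 windows
  and a 32-subject study 5120. The trial length must divide evenly; nothing is
  silently truncated.
* **Labels.** The valence rating is binarized at 5: rating ≤ 5 → 0 (negative),
  rating > 5 → 1 (positive). The threshold is a parameter.
* **Channels.** The default montage keeps 15 electrodes — AF3, AF4, F3, F4,
  F7, F8, FP1, FP2 (frontal), P7, P8 (parietal), T7, T8 (temporal), O1, O2
  (occipital), CZ (central) — matching case-insensitively against mixed-case
  labels such as DEAP's Geneva ordering.
* **Standardization.** z = (x − μ)/σ per feature, with σ in *population* form
  (divide by N). Constant columns map to 0. Parameters are fit on training
  subjects only and applied to test subjects; fitting on the whole dataset is
  possible but is never done inside the evaluation protocols.

## Feature battery (249 per window)

| family | definition | count |
|---|---|---|
| time domain | mean; population std; mean abs first difference (÷ T−1); mean abs lag-2 difference (÷ T−2) | 4 × 15 = 60 |
| band energy | Σ of squared samples after zero-phase order-4 Butterworth band-pass; alpha 8–14, beta 14–30, gamma 30–47 Hz | 3 × 15 = 45 |
| beta/alpha ratio | band-energy ratio on F3, F4, AF3, AF4 | 4 |
| RASM | left/right band-power ratio for (F3, F4) and (AF3, AF4) in alpha and beta | 4 |
| power sum | Σ over the 7 non-frontal channels (P7, T7, O1, P8, T8, O2, CZ) of mean squared broadband signal | 1 |
| nonlinear | SampEn, ApEn, DE, WE, λ_max, Higuchi FD, Hurst H, Hjorth mobility and complexity, all on the broadband window | 9 × 15 = 135 |

Notes on the individual estimators and their defaults:

* **SampEn/ApEn**: m = 2, r = 0.2 × window std, Chebyshev distance. SampEn
  excludes self-matches, ApEn includes them. Zero template matches are capped
  at ln(10⁶). The O(n²) loops are numba-compiled; the test suite checks them
  against an independent pure-Python counter on short series.
* **Differential entropy**: Gaussian closed form ½ ln(2πeσ²) in nats with the
  window's sample variance.
* **Wavelet entropy**: Daubechies-4, 5-level DWT; Shannon entropy of the six
  relative sub-band energies, so WE ∈ [0, ln 6].
* **Largest Lyapunov exponent**: Rosenstein small-data method — delay
  embedding (dimension 10, delay 2), nearest neighbors outside a Theiler
  window equal to the delay, least-squares slope of the mean log-divergence
  curve over the first 30 steps. The map-derivative definition of λ only
  applies to known 1-D maps; it serves as the test oracle (fully chaotic
  logistic map, λ = ln 2). On noiseless periodic signals the estimator carries
  a small positive bias (~0.01 nats/sample) from the step-0 nearest-neighbor
  minimum, so "non-chaotic" is asserted as near-zero, not strictly ≤ 0.
* **Higuchi FD**: k_max = 10, slope of ln L(k) vs ln(1/k), clipped to [1, 2].
* **Hurst (R/S)**: dyadic ladder of subseries lengths {16, 32, …, N/2};
  per-length mean rescaled range; regression slope clipped to [0, 1]. A
  constant series returns 0.5 (no evidence either way).
* **Hjorth**: mobility = √(var(Δx)/var(x)); complexity = mobility(Δx)/mobility(x).
* The time-domain family follows the difference-*mean* formulas; a recipe
  switch (`time_domain_variant="table"`) replaces the lag-2 mean with the
  first-difference standard deviation, keeping the 249 count either way.
* All denominators are floored at 1e-12; any residual non-finite value is
  zeroed after extraction, so feature tables never carry NaN/Inf.

Column order is fixed by the recipe and stable across runs; identical windows
produce bit-identical rows.

## Feature selection

1. **Mutual-information filter.** Each feature is coded into 10 quantile bins
   (features with fewer unique values keep their values as codes — this makes
   a binary feature identical to the label score exactly H(Y) = ln 2 on
   balanced labels) and the plug-in MI with the label is computed in nats.
   Quantile binning makes scores invariant under strictly monotone transforms.
   The top floor(fraction × p) features are retained: fraction 0.5 on 249
   features keeps 124. Ties break toward the lower column index.
2. **SFFS.** Classic floating search over the retained features: add the
   feature that maximizes the evaluator, then repeatedly remove any feature
   whose removal strictly improves the best-known score at the smaller size;
   stop when the best subset of the target size survives a full cycle
   unchanged. The evaluator is stratified 5-fold CV accuracy of a KNN
   classifier with k = 5 and a frozen fold seed — a deliberately small,
   fast selector model, distinct from the k = 41 final classifier. The
   reference configuration selects 65 features from the 124.
3. **Alternatives** (comparison baselines only): forward-only SFS,
   backward-only SBS, a correlation filter (feature-to-label by default,
   with a pairwise-redundancy switch; threshold 0.93), and PCA.

## Multi-classifier fusion

Base classifiers — any of KNN (k = 41), RBF-SVM (C = 0.7, γ = 0.015,
probability mode), polynomial SVM, random forest (100 trees, fixed seed) —
are trained on the selected subset. Their per-class probability outputs are
summed elementwise across bases into two *weight features* (rows sum to the
number of fused bases), which are concatenated with the full original
249-feature matrix; the final classifier is fit on the re-standardized
concatenation. The supported variants are KNN+RF, KNN+SVM, RF+SVM and
KNN+RF+SVM, each with any of the three families as the final classifier.

Training-set probabilities are **cross-fitted** (5-fold out-of-fold
predictions, standard stacking practice): in-sample probabilities — a random
forest's in particular — are near-degenerate and would let the final
classifier overfit the bases' memorization. A `naive_insample` switch
restores the literal in-sample reading. Test-time weight features come from
bases refit on all training rows. Whether weight features should be z-scored
before the final fit is underdetermined; the implementation re-fits
standardization on the concatenated training matrix, which treats them like
any other column.

KNN clamps k to the training-set size: the reference k = 41 presumes
thousands of training windows, and an unclamped k would crash (or silently
majority-vote) on small per-fold training sets.

## Evaluation protocols

* **Hold-out**: a seed-controlled random subject split, 27 training / 5 test
  subjects by default (4320/800 windows at full scale). Which subjects the
  reference configuration used is unknown, so the split is randomized by seed.
* **LOSO**: one fold per subject; within each fold standardization,
  selection and fusion are re-fit on the training subjects only. An exclusion
  list (empty by default) supports dropping problematic subjects. A fast mode
  selects the feature subset once on the whole table; it is clearly logged as
  not subject-disjoint at the selection stage and is used only where both
  compared arms share the same subset.
* **Metrics**: accuracy, precision, recall, F1 with class 1 positive;
  zero-denominator cases return 0 with a warning; macro averages are plain
  fold means.

## Synthetic data

The generator emulates the DEAP shape, not its physiology. Each trial is a
sum of band-limited Gaussian oscillations (filtered white noise; amplitudes
alpha 6, beta 3, gamma 1.5 µV RMS) over a 1/f background (8 µV RMS), with
log-normal per-trial band-power jitter (SD 0.3 in log-amplitude), a
multiplicative per-subject random effect (SD 0.2), and microvolt-scale
output. Positive-valence trials get frontal beta power multiplied by
(1 + β_eff) and a left/right alpha-power ratio shift — exactly the band-power
premises the ratio/RASM features target. Ratings sit margin 2.0 from the
threshold on the correct side plus Gaussian noise (SD 0.5), so binarization
recovers the truth exactly at zero noise. Trial labels are a shuffled
balanced list per subject, mirroring curated stimulus sets; iid labels at a
dozen trials per subject would produce class-imbalance artifacts that mask
the null-data chance check. Oscillations are stochastic processes rather than
pure tones so the entropy/FD features are non-degenerate.

What passing tests on this generator do **not** show: robustness to
artifacts, electrode drift, ERPs, non-stationarity, or any real
neurophysiological valence correlate. The generator validates the machinery
(shapes, leakage-freedom, direction of fusion effects), not clinical claims.

## Packaged benchmark

The fusion benchmark (`emofuse.benchmark`, seed 0) uses 8 subjects × 12
trials at β_eff = 0.6 — a deliberately desk-scale study (384 windows) so the
full battery, selection and a 5-arm LOSO comparison complete in minutes on
one core. Selection is MI 0.5 + SFFS to 12 features, done once in fast mode:
the benchmark's question is whether adding weight features helps relative to
the no-fusion baseline, and both arms share the subset. The companion null
benchmark (both effects zero, MI-only selection) must land at chance; it is
the leakage detector for the whole pipeline.

## Known limitations

* The plug-in MI estimator is biased upward for small samples; it is used
  only for ranking, where the bias is shared across features.
* SFFS cost grows as O(p × D) evaluator calls; at the reference scale
  (124 → 65) a per-fold LOSO re-selection is hours of compute, which is why
  the fast mode exists.
* Probability outputs of the SVM rely on internal Platt-style calibration,
  which adds its own CV layer and seed sensitivity.
* The R/S Hurst estimator has the well-known small-sample upward bias for
  iid data (~0.55 at n = 1280); tests use bands that account for it.
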