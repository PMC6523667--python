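# Methods

This note documents the scientific and numerical choices behind eegad: the
generative model of the synthetic cohorts, the preprocessing and feature
conventions, the cross-validation protocol, and what the synthetic
experiments can and cannot show about clinical data.

## Synthetic cohort model

Clinical EEG of the kind this pipeline targets (19 scalp channels, 10–20
montage, 500 Hz, eyes-closed resting state; ~20 min per control and
~11–17 min per patient; groups of 10 controls / 8 mild AD / 6 moderate AD)
is not publicly available, so the package ships a generator that reproduces
the *statistical structure the features measure*, not EEG morphology.

Each channel is a sum of five band-limited Gaussian noise components — white
noise shaped by the same equiripple band filters the feature bank uses —
with component variances set by a band-power profile that depends on group
(CN / mild / moderate) and region (anterior, central, temporal left/right,
posterior), plus a 1/f^a pink background (default fraction 0.1 of total
variance, exponent a = 1). Channels of one region share a common component
(default 30% of variance) so cluster-level analyses see spatially coherent
signal; there is no volume-conduction model. Signals are synthesized with a
one-filter-length margin and trimmed, so zero-phase edge transients never
leak broadband power into the delivered recording.

Three mechanisms carry the group contrasts:

- **Band-power profiles.** The default profiles give controls a posterior
  alpha dominance and shift weight diffusely toward delta/theta with
  severity. Two stylized alternatives are provided for targeted
  experiments: `strong_slowing_profile()` (spatially uniform, delta+theta
  weight 0.7 in moderate AD vs 0.3 in controls) and
  `posterior_effect_profile()` (group differences confined to
  posterior/central regions).
- **Complexity factor** c ∈ (0, 1] per group (defaults 1.0 / 0.85 / 0.7):
  each band component is smoothed by an AR(1) filter with pole
  φ = 0.95·(1 − c) and renormalized to its target variance. This narrows
  the component's effective bandwidth, lowering sample/permutation entropy
  at constant band power — the "reduced complexity" marker.
- **Effect size** e ∈ [0, 1] interpolates every group's profile, complexity
  factor and pink exponent between the control values (e = 0: all groups
  share one generating distribution exactly) and the specified values
  (e = 1). Exact effect sizes in patients are unknown; e is a free
  simulation parameter, not an estimate of any clinical cohort.

Metadata are drawn uniformly: ages from the groups' interquartile ranges
(CN 62.25–72, mild 68.5–77.25, moderate 61.25–68.25 years), MMSE from the
integer ranges 30 / 19–23 / 10–18, durations from 20–23 min (controls) and
11–17 min (patients). Artifacts are Poisson-count 1 s intervals (default
0.5/min) recorded as a mask; they exist to exercise epoch exclusion, not to
model EMG/EOG waveforms.

Determinism: one `SeedSequence` per cohort spawns per-subject generators,
so equal specs give bit-identical cohorts, including after CSV
serialization.

## Preprocessing

Re-reference to the common average, then band-limit, then epoch. Filters:

- high-pass: equiripple FIR, passband edge 0.5 Hz, stopband edge 0.25 Hz,
  40 dB stopband / 0.1 dB passband ripple (single pass);
- low-pass: equiripple FIR, 60 Hz passband edge, 65 Hz stopband edge;
- notch: 2nd-order Butterworth band-stop, 49–51 Hz;
- band filters: each rhythm's band-pass is the convolution of a
  single-transition equiripple high-pass and low-pass (transition widths
  0.5 Hz below 13 Hz, 2 Hz above; the delta lower edge reuses the global
  0.25→0.5 Hz high-pass design). A single three-band remez design with
  these very unequal transitions fails to converge at the required lengths;
  the cascade keeps each design well-conditioned at the cost of doubled
  passband ripple (still within ±0.5 dB after zero-phase application).

All filters are applied zero-phase (forward–backward), implemented as two
FFT convolutions with odd-reflection padding — equivalent to `filtfilt` for
linear-phase FIRs but O(n log n). Equiripple designs are validated against
their ripple targets at design time over a small grid of lengths and
remez grid densities, because long narrow-transition designs converge
erratically.

Epoching starts at t = 0, uses no overlap and no padding, discards the tail
remainder, and drops any epoch that overlaps an artifact interval.
Referencing precedes filtering; the order follows the usual clinical
processing narrative, and the two commute in what the features see except
for edge effects.

## Feature conventions

Per-band features are computed on band-filtered time series, not spectral
coefficients. Deliberate conventions, all configurable via
`EstimatorParams`:

- ApEn/SampEn: m = 2, r = 0.2 × SD of the analyzed (band-limited) segment —
  the field-standard choice; Chebyshev distance; SampEn uses N−m templates
  with self-matches excluded. SampEn with zero match counts is a `nan`
  sentinel; sentinel-bearing epochs are dropped from the feature table and
  counted in the log.
- Permutation entropy: order 3, delay 1, natural log, ties broken by order
  of occurrence (stable sort).
- Tsallis entropy: q = 2 on a 100-bin equal-width amplitude histogram
  spanning the segment's min–max (same histogram for Shannon entropy).
- MSE: Costa coarse-graining at scales 1–5, r fixed at 0.2 × SD of the
  original series, summarized as the mean over scales with a finite
  estimate (the single-number summary is this package's choice); scales 1–5
  keep the coarse-grained series ≥ 160 samples at the shortest window used
  here.
- Variance/SD are population (1/n); skewness is the population third
  standardized moment and kurtosis the non-excess fourth (Gaussian → 3),
  both defined as 0 for constant segments; IQR uses linear-interpolation
  quantiles.
- Column order: per channel, the 8 full-band statistics, then per band
  (δ→γ) energy, RBP, ApEn, PermEn, Tsallis, SampEn —
  `{channel}_{feature}[_{band}]`, 38 × 19 = 722 columns plus the label.

The ApEn/SampEn kernel sorts templates by first coordinate and scans only
pairs within r there — an exact pruning (Chebyshev matches must match every
coordinate) that removes most of the O(n²) work at r = 0.2·SD. The kernels
are tested to machine precision against naive enumeration.

## Classification protocol

Random Forest with 100 trees, √p features per split, unlimited depth,
bootstrap on; stratified 10-fold cross-validation with a fixed seed;
metrics computed from the confusion matrix pooled over test folds.
Multiclass precision/F1 are support-weighted. Kappa uses the marginal
chance-agreement formula; a single-cell confusion matrix (p_e = 1) returns
kappa 0 with a warning.

Folds are stratified at the **epoch level**: epochs of one subject can
appear in both training and test folds. This mirrors common practice in
the clinical-EEG classification literature, and the classify module's
docstring flags it as the main reproducibility caveat: it optimistically
biases accuracy whenever subjects have
idiosyncratic signatures; `run_cv(..., groups=subject_ids)` provides the
honest subject-grouped alternative, and results from the two modes should
never be mixed. Alternate classifiers (MLP, KNN, SVM, NB, DT) are available
behind the same contract for comparison runs; SVM/MLP are wrapped with
standardization.

## Demographic statistics

Kruskal–Wallis uses midranks and the tie correction
1 − Σ(t³−t)/(N³−N) — necessary here because control MMSE is entirely tied
at 30 — and reports per-group mean ranks (a 10/8/6 cohort with the
canonical non-overlapping MMSE ranges gives 19.5/10.5/3.5 exactly). Welch's
ANOVA reports the Welch–Satterthwaite fractional denominator df as defined,
rather than the classic N−k integer df sometimes printed alongside Welch
results in the clinical literature.

## Problem sizes in tests and the acceptance script

The entropy features cost O(n²)-ish per channel-band, so the end-to-end
statistical checks run at desk scale, chosen once: synthetic acceptance
cohorts are sampled at 160–200 Hz (all five rhythms remain below Nyquist;
filter transition widths are fixed in Hz so designs are unchanged in
frequency terms) with recordings of 1–8 min. The null-calibration check
uses a balanced 12-subject effect-free cohort yielding ≥ 1000 five-second
epochs; the effect-recovery check uses 10 subjects at the 12 s window; the
regional check uses 10 seeded 7-subject replicates. Full-scale defaults
(500 Hz, 24 subjects, 11–23 min) remain the generator's defaults and run
fine, just longer.

## What passing tests do and do not show

The synthetic cohorts share the features' own generative vocabulary
(band-limited Gaussian noise), so recovery results demonstrate that the
pipeline is *correctly wired and statistically calibrated* — chance-level
performance without an effect, high accuracy and the expected
problem/region orderings with one. They do not demonstrate clinical
accuracy: real EEG has nonstationarity, artifacts with structure,
volume conduction, medication effects and between-subject variability that
the generator deliberately omits. Known limitations: no automated artifact
detection (masks must be provided), no wavelet/parametric spectral
alternatives, no feature selection or hyperparameter search, and EDF
export is not provided (recordings serialize to CSV; EDF reading is
supported when `mne` is installed).
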