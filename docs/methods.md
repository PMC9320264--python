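# Methods

This note documents the models, conventions and design choices behind
`gadpipe`, and what the synthetic validation does and does not establish.

## Preprocessing

Recordings are resampled to a 100 Hz working rate with polyphase
anti-aliased resampling (output length `floor(T · fs_target)`), then
band-passed 4–30 Hz. "4th-order Butterworth" is interpreted as the order
parameter of the band-pass designer (`scipy.signal.butter(4, [lo, hi])`,
an 8-pole band-pass transfer function), applied **zero-phase**
(forward–backward, `sosfiltfilt`). Zero-phase filtering is chosen because
the downstream fuzzy-entropy and phase-lag-index features are
phase-sensitive: a causal filter would add band-dependent group delays that
corrupt inter-channel phase differences. The effective magnitude response
is therefore the design response squared.

Filtering — both the broadband pass and the four rhythm extractions — is
applied to the *continuous* signal, and 4-s windows are cut from every
filtered stream at the same offsets (windows start every 2 s; a trailing
partial window is dropped). A 4-s window is comparable to the theta filter
transient, so per-epoch filtering would distort band estimates.

Band edges (4/8/10/13/30 Hz) are given to analog-prototype filter designs,
so content exactly at a shared edge falls in the transition region of both
neighbouring filters; this is unavoidable and intended.

An artifact-removal hook sits between filtering and segmentation; the
default is the identity (synthetic cohorts carry no ocular/muscle
artifacts). An ICA-based cleaner can be substituted for real recordings.

## Feature families

**Relative power.** One boxcar periodogram per (epoch, channel) on the
broadband window, one-sided with the standard doubling so summed power
equals the mean squared signal (checked to 1e-10). Band integrals are
discrete sums over FFT bins in **half-open** intervals `[lo, hi)`, which
makes theta/alpha1/alpha2/beta an exact partition of `[4, 30)` — raw band
fractions sum to 1 and shared edges are never counted twice. The value is
the band fraction multiplied by `(30 − 4)/(hi − lo)`, so a flat spectrum
scores exactly 1 in every band. The periodogram is computed on the
broadband window (not the rhythm-filtered versions) because the quantity is
a ratio over a single spectrum. At 100 Hz and 400-sample windows the bin
width is 0.25 Hz and every band edge lies on a bin.

**Fuzzy entropy.** `FE(m, r, N) = ln O^m(r) − ln O^{m+1}(r)` with embedding
dimension m = 2 and tolerance `r = k·σ`, k = 0.2 (σ the window's standard
deviation, population convention). For each dimension p ∈ {m, m+1}, the
N − m embedded vectors are the sliding windows of length p with their own
mean removed; distances are Chebyshev; similarity is the Gaussian-family
kernel `exp(−ln 2 · (d/r)²)` (equal to 1/2 at d = r); `O^p` averages
similarity over all ordered pairs i ≠ j. Because r scales with σ, FE is
invariant to positive rescaling of the window. A constant window returns 0
by convention (all distances vanish). N is whatever the working-rate window
holds — 400 samples by default — and is recorded in provenance; internal
consistency with the 100 Hz pipeline is preferred over any fixed nominal N.
The implementation evaluates only the condensed distance triangle
(`scipy.spatial.distance.pdist`); the test suite proves equivalence with a
literal brute-force double loop to ≥10 significant digits.

**Phase lag index.** Instantaneous phases come from the analytic signal
(Hilbert transform) of each rhythm-filtered window; the phase difference is
wrapped to (−π, π] *before* taking the sign — without wrapping, the sign
would not encode lead vs. lag — and `PLI = |mean(sign(Δφ))|` with
sign(0) = 0. Identical phases give exactly 0; any constant nonzero lag
gives exactly 1. The first and last 5 % of each window's phase samples are
discarded (configurable) because the analytic signal is distorted at window
boundaries.

**Table layout.** Columns are ordered family-major (PSD, FE, PLI), then
band (theta, alpha1, alpha2, beta), then channel in montage order or
channel pair in upper-triangle order: 64 + 64 + 480 = 608 columns.

## Feature screening

Per-column one-way ANOVA between the two groups; with two groups F = t² and
the p-value equals the pooled-variance two-sided t-test p-value (asserted
to 1e-10). Columns with zero variance get p = 1 and are never retained. No
multiple-testing correction is applied by default, matching mass-univariate
screening practice at p < 0.05 over 608 tests; a Benjamini–Hochberg mode is
available.

Two sampling conventions are first-class:

* **epoch-level** (default): every 4-s epoch is a sample. This replicates
  the common practice, but 50 %-overlap epochs from one subject are
  strongly dependent, so the screen is *anti-conservative*: on a null
  cohort the measured retained fraction is ≈ 0.12 at α = 0.05 — more than
  double nominal. The test suite asserts this inflation as a property.
* **per-subject** (`per_subject=True`): epochs are averaged within subject
  first and the independent subject means are tested. This is the level at
  which the binomial null model actually applies, and it is the mode used
  for the type-I calibration check (measured retained fraction ≈ 0.05 on
  the null cohort).

The frontal-edge ratio is the fraction of retained PLI features whose pair
touches {Fp1, Fp2, F3, F4, F7, F8}; the direction summary reports
sign(mean_patient − mean_control) per retained feature.

## Classifiers and evaluation

* SVM: RBF kernel, C = 1, `gamma="scale"` (1/(n_features·var)); the cost
  and width are conventional defaults, exposed in `ModelSpec`.
* Random forest: 500 trees, raw (unstandardised) features.
* BP bagging: 100 MLPs with 6 hidden layers of 100 rectified-linear units,
  adam optimiser, ≤200 passes; each base learner sees a random 80 % of the
  feature columns and 80 % of the training epochs (drawn without
  replacement, redrawn per learner); prediction is a majority vote with
  ties broken toward the control label. Validation-based early stopping
  (10 % slice, patience 25) engages only when a base learner trains on
  ≥1000 samples: at smaller sizes the validation slice is too small and the
  patience window shorter than the optimiser's escape time from
  initialisation, so early stopping would freeze untrained networks.

Evaluation: 10 repeats of a stratified 80/20 hold-out at epoch level;
z-score standardisation (for SVM and the networks) is fitted inside each
training fold only. Metrics are accuracy `(TP+TN)/(TP+TN+FP+FN)`,
sensitivity `TP/(TP+FN)`, specificity `TN/(FP+TN)` and F1
`2TP/(2TP+FP+FN)` with the patient group as positive; means ± standard
deviations over repeats. Per-band reports restrict the model to each band's
retained columns. Epoch-level splitting is optimistic (overlapping epochs
of one subject on both sides of the split); a subject-wise split mode
(`subject_split=True`) is provided and recommended for honest
generalisation estimates.

## Synthetic cohort generator

Each channel is a sum over bands of `amplitude × (band-limited unit-variance
oscillation)` plus 1/f^slope background noise. Oscillations are white noise
filtered into the band — not sinusoids — so instantaneous phase is
non-degenerate (the PLI of two equal-frequency pure tones is trivially 0
or 1). Defaults: amplitude 1 per band per group, noise σ = 1 with slope 1
(resting EEG spectra are approximately power-law; after the 4–30 Hz
band-pass the background contributes only a small in-band share), sampling
rate 250 Hz. A per-subject, per-band uniform ±10 % amplitude jitter makes
epochs from different subjects non-exchangeable, enabling subject-wise
split experiments.

A coupling specifies (channel a, channel b, band, lag, per-group mixing
weight w). Both channels' band components share one latent band-limited
source; channel b receives it rotated by the lag (a phase rotation of the
analytic signal). The coupled band component is the *normalised* mixture
`[(1−w)·intrinsic + w·source] / sqrt((1−w)² + w²)`, which keeps band power
independent of w: coupling strength moves phase synchronisation only, and
band amplitudes move power only, so the two implanted effect types do not
contaminate each other. w = 1 gives near-perfect phase locking (PLI > 0.9
downstream); PLI is monotone in w; a zero lag is legal but invisible to PLI
by construction.

Determinism: per-subject generators are seeded with
`SeedSequence(cohort seed, group index, subject index)`, so cohorts are
bit-identical given a spec, and any subject can be regenerated alone.

Presets: the **null** preset has equal amplitudes and no couplings (type-I
calibration); the **group-effect** preset scales patient beta amplitude
×1.3 and alpha1 ×0.75 and drops the mixing weight of eight frontal-to-other
couplings (two per band, lag π/4) from 0.8 in controls to 0.3 in patients.
Validation runs use 10+10 subjects with 60-s recordings (290 epochs per
group), sized so that the full suite completes quickly while every implanted
effect is recovered with high margin.

What the generator does *not* emulate: ocular/muscle/line artifacts,
volume conduction and shared references (beyond what zero-lag mixing would
contribute — which PLI is designed to ignore), non-stationarity within a
recording, realistic scalp topographies, or source-space structure. Passing
parameter-recovery tests therefore shows the *analysis chain* is correct
and sensitive at realistic effect sizes; it does not certify performance on
real clinical EEG, where artifact handling and inter-subject variability
dominate.

## Numerical conventions and degenerate inputs

* Resampling length: `floor(n · target_fs / fs)`; upsampling refused.
* All-zero windows: spectra are all-zero; relative power is undefined
  (error); Hilbert phase is undefined (error); fuzzy entropy of a constant
  window is 0.
* Confusion-matrix metrics with an empty denominator are NaN and excluded
  from means (flagged, not silently zeroed).
* A degenerate grouped split (a class missing from a side) is resampled
  from a seeded generator.
* The master seed fans out to named substreams (synthesis, splits, learner
  initialisation) via `SeedSequence`, so stage CLIs reproduce orchestrated
  outputs exactly.

## Known limitations

* EDF export writes the classic 16-bit format with 1-s records and
  symmetric physical range; quantisation error is `max|x|/32767` per
  sample. EDF+ annotations are not written.
* The epoch-level evaluation figures on the synthetic preset saturate near
  1.0; they demonstrate recovery, not a realistic clinical effect size.
* Fuzzy entropy is O(N²) per window; at the default 400-sample windows this
  is the pipeline's dominant cost (~50 s for a 580-epoch cohort on one
  CPU).
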