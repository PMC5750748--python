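# Methods

This note records the model, the numerical conventions, and the design
choices behind `tfmra`, at the level a maintainer or reviewer needs to
re-derive or challenge them.

## Signal model and preprocessing

Input is a multichannel EEG recording in microvolts. Facial and ocular
artifacts dominate at frontal midline sites, so the analysis is
single-channel (Fpz by convention); multi-channel fusion is out of scope.
Slow trends are removed by a 4th-order Butterworth high-pass at 0.5 Hz
applied forward–backward (`sosfiltfilt`). The zero-phase application
preserves transient morphology (a blink's biphasic shape is not skewed);
the cost is that the effective magnitude response is the square of the
design response, so the −3 dB point of the *design* sits at 0.5 Hz while
the applied attenuation there is 6 dB. Idempotence holds only for content
above the transition band (≈3 Hz at 1e−6 relative) and away from edge
transients, whose decay constant at a 0.5 Hz cutoff is of the order of a
second.

Segmentation uses non-overlapping rectangular windows of L seconds
(L·F_s samples, default L = 1); trailing remainder samples are discarded
(floor rule) so segment boundaries are deterministic.

## Time–frequency distributions

The analytic signal is computed by the FFT rule (negative bins zeroed,
positive doubled, DC and Nyquist kept), which makes the negative-spectrum
invariant exact to round-off. Instantaneous frequency is the unwrapped
phase derivative (central differences; one-sided at the ends) scaled by
F_s/2π; instantaneous amplitude is |z(n)|.

All lag-kernel TFDs start from the instantaneous autocorrelation
K(n, l) = z(n+l) z*(n−l) on an N×N (time × lag) grid, lags in FFT order
and zeroed where n±l leaves the segment. K is Hermitian in l by
construction — including at the truncated edges, since n+l and n−l leave
the support together — so the DFT over lag is real to machine precision;
`compute_tfd` asserts a relative imaginary residue below 1e−8 before
discarding it. Kernels:

- **WVD**: K unchanged.
- **SWVD**: time smoothing of K with a sum-normalized symmetric Hanning
  window, length ⌊F_s/4⌋ rounded down to odd (63 samples at 256 Hz).
  Time smoothing attenuates cross-terms between components separated in
  frequency because those terms oscillate along time at the beat
  frequency; on a 20 + 60 Hz pair the 35–45 Hz band's energy share drops
  by more than two orders of magnitude relative to the WVD.
- **Spectrogram**: computed directly as |STFT|² with the same window, FFT
  length 2N so bins land on the common axis f_k = k·F_s/(2N); exactly
  nonnegative.
- **Gaussian product kernel** (Choi–Williams type): applied in the
  Doppler domain as exp(−(θ·l)²/σ) with θ = 2π·fftfreq(N) rad/sample and
  σ = 0.8; smoothing is circular in time. The kernel is even in θ and l,
  preserving realness. The zero lag column is untouched, preserving the
  time marginal.
- **Modified B**: lag-independent time smoothing with
  cosh(n)^(−2β)/Σcosh(m)^(−2β), β = 0.02.
- **Separable kernel**: Hamming time smoothing × symmetric Hanning lag
  window (an even lag window keeps K Hermitian).

Values are scaled to an energy density per Hz, so a WVD column times the
bin width Δf = F_s/(2N) sums to |z(n)|² exactly; total energy then equals
Σ|z|². The frequency grid has N one-sided bins over 0…F_s/2 and one
column per sample; no interpolation.

IF-rule checks (argmax tracking of a linear chirp) and the tone-argmax
check exclude a few edge columns: at n = 0 only the zero lag survives, so
the column is flat and its argmax carries no frequency information. The
interior RMSE is well under one bin for WVD and SWVD.

Peak/component extraction thresholds at a fraction of the global maximum,
keeps pixels that are local maxima along frequency (first/second
derivative test), groups them under 4- or 8-connectivity
(`scipy.ndimage.label`), and reports each group's per-time argmax as its
IF polyline.

## 2D multi-resolution analysis

TF images are bilinearly resized to a fixed square (default 256×256;
the end-to-end study uses 64×64, see below) so decomposition shapes do
not depend on segment length.

**2D Haar DWT** uses PyWavelets with periodization, so level-k sub-bands
halve exactly and 4 levels give 3·4 + 1 = 13 matrices; the orthonormal
filter bank makes Parseval exact and the approximation of a constant
image equal the constant × 2⁴.

**Curvelet via wrapping** is implemented in-package as a Parseval tight
frame of frequency wedges:

- Radial Meyer-type windows with C∞ transitions partition the centered
  FFT plane into dyadic bands (band edges a_j = 2^(j−5) of the box
  radius, measured in the L∞ norm); the squares of the windows
  telescope to one at every frequency. Coarsest and finest bands are
  isotropic.
- Middle scales carry 8, 16, 16 angular wedges (orientations double
  every other scale — the discrete form of parabolic scaling). Angular
  windows on the circle are built from the same C∞ step so adjacent
  squared windows sum to one; wedge 0 is centered due north and indices
  increase with angle.
- Wedges for the second half of each scale's orientations are
  constructed by point reflection of their θ+π partners, so for real
  input the partner coefficients are conjugate mirrors — exactly the
  redundancy that `select_subbands` removes (keep scale 1, the first
  half of scales 2–4, scale 5: 22 matrices).
- Each windowed wedge is wrapped onto a small rectangle by modular
  re-indexing. The rectangle starts at the support's bounding box and is
  greedily shrunk while the index map stays injective; injectivity makes
  the wrap losslessly invertible, so the adjoint is an *exact* inverse
  and total coefficient energy equals image energy to round-off (the
  observed round-trip error is ~1e−15, against a 1e−6 requirement).
  Unitary FFT norms are used throughout.
- The middle-scale supports vanish before the asymmetric −F_s/2 row/column
  of even-sized grids, so the conjugate pairing is exact; the finest
  isotropic band absorbs those bins.

Sparsity comparisons between curvelets and Haar count the nonredundant
coefficient set (conjugate pairs once, with doubled energy weight),
since the complex transform stores each real-image wedge twice. On a
smooth curved ridge — the TF-space analogue of an edge — the curvelet
frame reaches 95 % energy with fewer coefficients than 4-level Haar; on
a filled binary region the Haar approximation band wins trivially, which
is not the claim of interest.

## Features

Each coefficient matrix yields an 8-feature block. GLCM settings
(unspecified in the underlying design) follow standard Haralick practice:
G = 8 gray levels, min–max quantization (round-half-up; constant input →
all zeros), symmetric accumulation, offsets {(0,1),(1,0),(1,1),(1,−1)},
properties computed per offset and averaged. The four properties are the
literal double sums for contrast, correlation, energy (Σp², i.e. angular
second moment), and homogeneity with a 1+|k−l| denominator. Degenerate
conventions keep every feature finite: a single-level image has contrast
0, energy 1, homogeneity 1 and correlation defined as 1; zero-variance
moments report skewness 0 and kurtosis 0. Moments are population moments
of the flattened real parts; kurtosis is Pearson (normal → 3). For
complex curvelet coefficients, magnitudes feed the GLCM (texture energy)
and real parts the moments.

Vectors: 8×22 = 176 (curvelet), 8×13 = 104 (wavelet; approximation block
first, then details coarsest-to-finest in horizontal/vertical/diagonal
order), and an 18-dim 1D baseline: 5-level Daubechies-4 DWT
(periodization) with per-band average power, mean, and standard
deviation. Daubechies-4 is the conventional EEG choice where the mother
wavelet is otherwise unspecified.

## Classification and statistics

Stratified k-fold CV (default 10) with shuffling under a fixed seed;
features are standardized with statistics fit on the training folds only.
Models: `SVC` (RBF, C = 10, gamma = "scale", one-vs-one), a CART-style
tree with entropy (information-gain) splitting capped at 100 splits
(`max_leaf_nodes = 101`), and 1-NN (ties broken at the lowest training
index by the backend's stable ordering). Sensitivity, specificity, and
total accuracy come from the pooled confusion matrix; an empty class row
reports NaN sensitivity rather than a fabricated rate.

PCA centers and unit-scales columns (constant columns dropped with a
warning), keeps 10 components by default, and exposes loadings
(components scaled by √eigenvalue) plus squared-loading contribution
percentages for per-component reports.

The one-tailed Wilcoxon signed-rank test drops zero differences, ranks
|d| with average ranks for ties, and computes P(T⁺ ≥ t) by full
enumeration of the 2^n sign patterns for n ≤ 15 (a normal approximation
with continuity and tie corrections beyond); all-zero differences give
p = 1. Confidence is reported as (1−p)·100 %, positive meaning the first
method is better. The two-sample comparison is Welch's t-test, two-sided,
with rejection at α = 0.005 by default.

## Synthetic data

The generator emulates a supervised frontal-channel artifact study:
10 participants × 8 classes × 10 trials of 1 s at 256 Hz. The background
is 1/f Gaussian noise (10 µV RMS) plus a 10 Hz alpha burst; artifact
morphologies are standard EEG phenomenology (biphasic blink transient of
300–500 ms; vertical-EOG step with slow exponential return versus a
horizontal-EOG ramp-plateau with fast return — the time-course contrast
matters because quadratic TF images discard polarity; 3–4 Hz eyebrow and
1–2 Hz head oscillations; sustained versus double-burst 20–90 Hz EMG).
Event spans scale with the trial length for sub-second windows.
Per-participant amplitude/frequency/time-constant jitter (±15 %) comes
from hierarchical `SeedSequence` spawning, so datasets are
bit-reproducible per seed and participants differ reproducibly.

`snr_db` sets the artifact-to-background power ratio and is the single
difficulty knob. The default of 3 dB was chosen so that the eight-class
problem lands in the accuracy regime reported for single-channel
artifact classification (roughly 80–95 % under 10-fold CV) rather than
at ceiling: at high SNR every method saturates near 99 % and comparisons
between decompositions become uninformative, while at 3 dB the curvelet
pipeline's advantage over the 2D wavelet pipeline expresses consistently.
Accuracy falls monotonically with SNR (≈99 % at 20 dB to chance at
−12 dB).

What the generator does *not* model: volume conduction and electrode
topography, heart/line-noise interference, non-stationary baselines
across trials, class overlap from simultaneous artifacts, and realistic
inter-participant covariance. Passing end-to-end tests therefore shows
the pipeline separates classes whose TF morphology differs in the ways
modeled here — it is evidence of correct mechanics and sensible features,
not of clinical-grade performance on real recordings.

## Problem sizes and runtime choices

The end-to-end study runs at 64×64 TF-image resolution (the curvelet
system is cached per image shape), where one 800-trial dataset — SWVD,
both 2D decompositions, all features, and 10-fold SVM — takes well under
a minute on one CPU; the replicate comparison uses ten seeds. Unit and
property tests use 64×64/128×128 images and 256-sample segments. The
reduced sizes are analysis choices: every structural count and exactness
property is resolution-independent, and the classification regime is set
by SNR, not by image size.

## Known limitations

- The wrapping rectangles are chosen greedily per wedge; they are small
  but not provably minimal, so coefficient matrices can be slightly
  larger than a hand-optimized layout.
- Finest- and coarse-scale coefficient phases carry the FFT-shift
  convention (a checkerboard/linear phase in space); magnitudes and the
  moment features of real parts are consistent across calls but the
  phase convention differs from other curvelet implementations.
- The GKD time smoothing is circular (Doppler-domain product), so very
  strong smoothing can wrap energy across segment edges.
- 1-NN tie-breaking relies on the neighbor backend's stable ordering
  rather than an explicit rule.
- The spectrogram path does not satisfy exact marginals (inherent to the
  method, not an implementation gap).
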