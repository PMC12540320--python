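# Methods

`seedspec` implements a full-band hyperspectral classification pipeline for
seed-variety discrimination: reflectance calibration of ENVI-style cubes,
per-seed ROI spectrum extraction, spectral smoothing, and classification with
KNN/ELM baselines or a 1-D convolutional network carrying a
squeeze-and-excitation (SE) attention block. Because no public seed accession
ships with the package, every stage is exercised on synthetic spectra whose
generative model is described below; what the synthetic benchmark can and
cannot establish is discussed at the end.

## Reflectance calibration

Raw counts are converted to reflectance with the standard black/white
correction

    R = (I_raw − I_dark) / (I_white − I_dark),

applied elementwise per band, where `I_white` images a near-unit-reflectance
reference panel and `I_dark` is the closed-shutter dark current. References
may be full scans or single-line frames; a single-line reference broadcasts
across lines. Bands where `|I_white − I_dark|` falls below 1e−6 of the white
dynamic range are treated as dead: the output is set to 0 there and the pixel
count is recorded on the result, so dead bands cannot inject non-finite
values. The output is deliberately not clamped to [0, 1] — specular pixels
legitimately exceed 1 — but a clamp flag exists.

## ROI extraction

Each seed contributes exactly one spectrum: the arithmetic mean over all
pixels of a rectangular region of interest, per band. Coordinates are 0-based
and half-open everywhere, which removes any off-by-one ambiguity between the
truth tables the simulator writes and the rectangles the extractor reads.
Rectangles come either from an explicit TSV or from the regular 5×6 tray
layout; automatic seed segmentation is out of scope.

## Smoothing operators

Four smoothers and two derivatives operate along the band axis, all with
mirror padding (index −k maps to +k; the edge sample is not repeated) so the
band count is preserved:

| method | default | notes |
|---|---|---|
| Savitzky–Golay | window 11, order 3 | local least-squares polynomial fit; exact on polynomials of degree ≤ order at interior bands |
| Gaussian | σ = 2 bands, window 11 | truncated, renormalized kernel (weights sum to 1) |
| median | window 5 | nonlinear; run 1-D along bands since classification consumes 1-D spectra |
| moving average | window 5 | centered boxcar |
| derivative (1st/2nd) | window 11, order 3 | derivative of the local SG polynomial, scaled by band spacing; raw differencing of noisy reflectance is avoided |

Window defaults are conventional for 320-band VNIR spectra; nothing in the
pipeline depends on them structurally and all are exposed in the config and
CLI.

## KNN baseline

Per-band transforms (mean centering, min–max scaling, `log(x + 1e−6)`) learn
their statistics from training rows only. The log transform clips at zero
first, since additive noise can push low-reflectance bands slightly negative.
Three distances are supported: variance-standardized Euclidean (the
conventional reading of "standard Euclidean distance" in this literature),
correlation, and Mahalanobis. With 320 bands and at most ~2,000 training
rows the sample covariance is ill-conditioned, so the Mahalanobis covariance
is shrunk toward its own diagonal, `(1 − λ)S + λ diag(S)`, with λ chosen
analytically by the Ledoit–Wolf estimator when not given; full shrinkage
(λ = 1) recovers standardized Euclidean exactly, which is tested. Distances
are computed by Cholesky whitening followed by a plain Euclidean distance
matrix — mathematically identical to the quadratic form and far cheaper.
Votes are majority over the k nearest training rows; ties break by the
smaller summed neighbour distance, then the smaller label id. A grid-search
helper sweeps k = 1..20 × transforms × distances with cross-validated means.

## ELM baseline

The extreme learning machine draws input weights and biases uniformly in
[−1, 1] and solves only the output layer: β is the minimum-norm least-squares
solution of `sigmoid(XW + b) β = T` with one-hot {0, 1} targets, via
`numpy.linalg.lstsq`. Draws are organized one row per hidden unit so that,
for a shared seed, the first H units of a wider network coincide with a
narrower one; the training residual is then provably non-increasing in the
hidden-layer width, which the suite checks. Prediction is the argmax over
class scores, ties toward the smaller class id.

## CNN family

All convolutions are 1-D with (kernel, stride, padding) = (3, 1, 1), so the
320-band length is preserved until flattening; there is no pooling. The
variants are

* `cnn1c` — conv(1→16) + ReLU, flatten, FC(16·320 → C);
* `cnn2c` — conv(1→16), conv(16→32), flatten, FC(32·320 → 64) + ReLU,
  FC(64 → C);
* `cnn3c` — three convs (…→64) and three FC layers (64, 32);
* `cnn2c_se` — `cnn2c` with one SE block after the second convolution's
  ReLU.

Channel and FC widths are package choices (16/32 channels, 64 hidden) — the
smallest conventional sizes that reach the intended accuracy regime on
320-band input without handing the flattened 10,240-feature layer enough
free parameters to memorize small training sets — and are constructor
parameters. The SE block squeezes each
channel to its global average, passes the pooled vector through
FC(C → C/r) + ReLU + FC(C/r → C) + sigmoid, and multiplies each channel by
its gate in (0, 1); the reduction ratio r defaults to 16 with {4, 8, 16, 32}
exposed for the ablation harness.

Training minimizes multiclass cross-entropy with Adam (β₁ = 0.9,
β₂ = 0.999), initial learning rate 0.01, batch size 64 and 10,000 mini-batch
update steps by default ("iterations" are parameter updates, not epochs).
Adam's per-coordinate step is bounded by the learning rate, so at rate 0.01
the very first updates move every weight by roughly the scale of its
initialization; unchecked, that spikes the loss, kills most ReLU units and
leaves the network to recover by memorizing the training set. Three standard
safeguards prevent this: the output layer is zero-initialized (initial
logits exactly uniform), the learning rate ramps linearly to its initial
value over the first 200 steps, and it then follows a cosine decay to zero
over the run. All three are package choices exposed as parameters. Forward
and backward passes are hand-written NumPy (im2col convolutions, explicit SE
backward); the Adam update is a fused single-pass kernel because the
parameter count (~2.7 M, dominated by the first FC layer) makes the update
memory-bound. Gradients are verified against central finite differences in
float64 in the test suite. Optional extras, off by default: dropout
(p after FC1), L1 weight regularization, and early stopping on a validation
split with configurable patience. Inputs are per-band z-scored with
statistics from the training rows; learning rate 0.01 is unstable on raw
reflectance scales, and the flag can be disabled.

Numerical notes: softmax is computed with max-subtraction; the loss adds
1e−12 inside the log; a non-finite training loss raises instead of being
clipped silently; prediction batches are chunked (512 rows) to bound
activation memory; fits are bit-reproducible given `random_state` on a fixed
BLAS configuration.

## Evaluation

The 4:1 stratified split reproduces the study design exactly: 2,700 balanced
spectra → 2,160/540, i.e. 72/18 per class. The headline protocol is
stratified 10-fold cross-validation (folds of 270, 9 per class per fold);
tables report the fold mean of each metric with (max − mean) and
(mean − min) deviations plus mean per-sample inference time. Accuracy is
trace/N of the confusion matrix; Precision/Recall/F1 are one-vs-rest
per-class values, macro-averaged — with exactly balanced classes macro and
weighted averaging coincide. All preprocessing statistics are fitted inside
each training fold; the smoothers themselves are per-spectrum maps with no
cross-sample state, so they are leakage-free wherever applied. A
permutation-null check (shuffled labels must yield chance accuracy within
binomial error) guards the harness against leakage regressions.

## Synthetic data model

Each variety's mean reflectance curve is a monotone-ish rising baseline —
typical of dry seed coats over 380–1018 nm — built by PCHIP interpolation
through 8 knots, minus 2–4 Gaussian absorption dips (position 430–960 nm,
σ 12–55 nm), clipped to [0, 1]. Class identity lives in knot perturbations
(s.d. 0.030 × `class_scale`) and dip parameters; `class_scale` is the single
separability dial, monotone by construction.

Each simulated seed spectrum is

    (1 + e_scatter) · mean + shift + slope · t + ε(λ),

with `t` ramping −1..1 across the grid: multiplicative scatter
(`e_scatter ~ N(0, 0.0875²)`), a constant baseline shift (s.d. 0.030), a
linear tilt (s.d. 0.015 at the grid edges), and additive per-band noise
(s.d. 0.010) smoothed with a 3-band boxcar and rescaled, so sensor noise is
band-correlated and smoothing operators have something real to remove. The
default `class_scale` is 0.45. These defaults were chosen once so that the
benchmark sits in the intended regime — the attention CNN near but not at
ceiling, the shallow CNN below it, the closed-form baselines well below
that — giving the comparison harness headroom in both directions. No claim
is made that the scales estimate any particular instrument's noise floor.

The tray simulator embeds one spectrum per cell of a 5×6 grid (8×8 px
rectangles on a 0.05-reflectance background), multiplies by a smooth
halogen-like illumination spectrum, adds dark current, and emits matching
white (unit-reflectance panel) and dark reference cubes plus a truth table
of rectangle bounds. Calibrating and extracting recovers the generated
spectra exactly at zero noise — the round trip is part of the acceptance
suite.

What the synthetic benchmark does *not* emulate: seed morphology and
within-seed spatial texture, specular glints, push-broom motion artifacts,
wavelength-dependent instrument response beyond a smooth illumination curve,
and any real biochemical absorption structure. Passing tests therefore
demonstrate the correctness and relative behaviour of the pipeline's
machinery, not field performance on real seeds.

## Problem sizes in the standing benchmark

The model-comparison harness retrains all five models on fresh 4:1 splits
over replicate seeds at 2,000 Adam steps per CNN — enough for the loss to
plateau on this problem while keeping a full run on one CPU core in the tens
of minutes (the test suite uses 5 replicates, the standalone reproduction
script 3). The permutation-null check uses the shallow CNN at 150 steps per
fold. The ablation CLI defaults to the full 10,000 steps.

## Known limitations

* The CNN is plain NumPy on one core; it is intended for 10²–10⁴ spectra,
  not large-scale training.
* Mahalanobis KNN refits the shrunk covariance on every `fit`, which is the
  dominant cost of the KNN baseline at 320 bands.
* ENVI support covers the plain ASCII-header dialect with full-cube reads
  only (no memory-mapped partial reads, BSQ/BIL/BIP only, little-endian).
* The ELM solves dense least squares; thousands of hidden nodes with tens of
  thousands of samples will be slow and memory-hungry.
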