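# Methods

## Scope and data model

The package classifies single heartbeats. A beat is a fixed window of
`beat_len = 256` samples (~0.71 s at 360 Hz) centred on the annotated R
peak — wide enough to span the P-QRS-T complex while staying a power of two
for dyadic wavelet levels. Labels are the five AAMI EC57 superclasses;
MIT-BIH beat symbols map as {N,L,R,e,j}→N, {A,a,J,S}→S, {V,E}→V, {F}→F,
{/,f,Q}→Q, and non-beat annotations are skipped. Beats whose window crosses
a record edge are dropped (and counted in the log), never padded. When
running on MIT-BIH itself, the paced records 102/104/107/217 are
conventionally excluded (exposed as `swinbeat.io.PACED_RECORDS`; exclusion
is the caller's choice), the first channel (MLII) is the default, and the
annotation index is taken as the 0-based R-peak sample.

## Denoising

Signals are decomposed with the orthogonal db6 wavelet to level 3 using
symmetric half-point boundary extension (PyWavelets supplies the filter
bank; an independent convolve-decimate oracle pins the convention in the
tests). Each detail band d is soft-thresholded with a per-band threshold:

* noise scale σ = median(|d|)/0.6745 — the robust MAD estimator that is the
  standard companion of SURE thresholding;
* threshold T minimizing Stein's unbiased risk estimate over the candidate
  set {|d_i|}: for sorted squared normalized coefficients s(1) ≤ … ≤ s(N),
  risk(k) = [N − 2k + Σ_{i≤k} s(i) + (N−k)·s(k)]/N, T = σ·√s(k*), ties
  broken toward the smallest k. A σ = 0 band (already noise-free) is left
  untouched. The universal threshold σ√(2 ln N) is available as an
  alternative rule and is an upper bound on the SURE choice.

The approximation band is not thresholded — white measurement noise
concentrates in the details, and shrinking the approximation would distort
the low-frequency ECG waves. After reconstruction the signal mean is
removed as a minimal baseline correction; beat templates are zero-mean, so
on clean input the whole procedure is the identity to within thresholding
of genuinely tiny coefficients (< 5% relative error is asserted; in
practice ~1e-16). At a 5 dB input SNR the median gain over 50 trials is
about 7 dB: level-3 details cover 22.5–180 Hz where ~7/8 of white noise
power lives, so the attainable gain is bounded near 9 dB and the residual
is the approximation-band noise plus shrinkage distortion of the QRS.

Note the source text couples "adjusted to the baseline" with threshold
selection in a single sentence; mean removal is our minimal reading of
that baseline adjustment, and it is toggleable (`baseline_correct=False`).

## Time-frequency images

The complex Morlet wavelet is used with the *unit* normalization exponent
−1/2, i.e. ψ(t) = (πF_b)^(−1/2) e^(2iπF_c t) e^(−t²/F_b); the printed
positive exponent would grow with bandwidth and contradicts the established
definition, so the exponent is a parameter (`norm_exponent`) with −1/2 as
default. Defaults F_b = 1.5, F_c = 1.0 follow the common cmor
parameterization. The CWT prefactor is |α|^(−1/2) by default (L2
convention); the L1 convention 1/|α| is available via
`prefactor_exponent=-1.0`.

The scale sequence is α_i = c/i, i = 1..totalscal with c = 2·F_c·totalscal,
the one assignment that makes the mapped frequencies F_a = F_c·f_s/α an
exactly linear ("isotropic") series f_s·i/(2·totalscal) reaching the
Nyquist frequency; the listed endpoints of the quoted sequence are
reproduced. With f_s = 360 Hz and totalscal = 256 the bins are 0.703 Hz
apart up to 180 Hz.

The transform itself is the correlation of the signal with scaled,
translated, conjugated wavelets, evaluated per scale by zero-padded FFT
convolution ('same' length); kernels are truncated where the Gaussian
envelope falls below 1e-12. A direct O(N²) summation of the defining
integral is kept as the reference path and the two agree to better than
1e-6 (tested, and used as the acceptance oracle).

**Ridge extraction and aliasing.** `ridge_frequency` renormalizes each
scale row to the L1 convention before taking the time-averaged argmax:
under L2 normalization a pure tone's response acquires a √α factor whose
maximum is biased low by ≈ 1/(4π²F_bF_c²) in relative frequency, while
under L1 the maximum sits exactly at the matching scale. Independently,
scales below ~4 samples alias, because the kernel is sampled at integer
offsets only; the smallest scale is 2·F_c samples, so tone localization
near Nyquist needs F_c ≥ 2 (the test suite uses F_c = 3, which localizes
5–170 Hz tones within a third of a bin). The default F_c = 1 is fine for
the rendered images — rendering consumes all scales, not an argmax.

Rendering min-max normalizes the magnitude per image (each beat shows its
own relative energy distribution, matching how such maps are usually
displayed; a global range is an option), applies the fixed warm–cold "jet"
colormap, flips so frequency ascends upward, and resizes bilinearly to a
square 8-bit RGB image. Training consumes the same images as floats in
[0, 1]. A constant magnitude renders as a uniform image rather than an
error.

## Classifier

The network is the tiny member of the hierarchical shifted-window
attention family, built from first principles in NumPy (float32) with
hand-written backpropagation — linear, layer-norm, GELU, windowed
multi-head attention, patch merging — verified against finite differences
and against naive per-window attention oracles.

* Patch embedding: 4×4×3 patches flattened to 48-vectors, affine map to C,
  layer norm.
* Stages: depths with W-MSA and SW-MSA alternating (even depths), window
  side M, shift ⌊M/2⌋. When a stage's token grid is not larger than M the
  window is clamped to the grid and the shift disabled (a single window is
  already global attention). Padding is deliberately not supported: input
  sizes must tile, which keeps the implementation exactly equal to its
  per-window oracle.
* Shifted windows: the grid is cyclically rolled by (−s, −s); windows that
  straddle the wrap are masked (additive −1e9 on the logits) so that only
  tokens from the same contiguous pre-shift fragment attend to each other.
  The mask derives from a 3×3 slab labelling cut at −M and −s per axis,
  which the tests check against brute-force fragment labelling.
* Attention: softmax(QKᵀ/√d_k)V per head with a learnable relative-position
  bias over the (2M−1)² offsets. The bias is standard for this
  architecture but absent from the bare attention formula, so it is
  toggleable (`rel_pos_bias=False`).
* Head: final layer norm, mean pool over tokens, linear map to 5 logits.
* Initialization: truncated normal (std 0.02, |x| ≤ 2 std), zero biases,
  all draws from one seeded generator — fixed seed gives bit-identical
  models.

Default architecture: C = 96, depths (2,2,6,2), heads (3,6,12,24), M = 7,
224 px input — the original tiny recipe, which the source model adopts
without stating its hyperparameters. All CPU-scale work uses the
`ModelConfig.tiny_test()` configuration: 32 px input, C = 16, depths
(2,2,2,2), heads (2,2,2,2), M = 4, MLP ratio 2 (~0.4 M parameters).

The complexity accountants implement the quoted operation counts verbatim:
Ω(MSA) = 4mnZ² + 2(mn)²Z and Ω(WMSA) = 4mnZ² + 2H²mn²Z. The W-MSA term
2H²mn²Z differs from the usual window-attention count (linear in the number
of windows with an M² factor); the symbols m, n, Z, H are treated as
opaque inputs exactly as printed.

Training minimizes mean softmax cross-entropy (loss computed in float64)
with Adam, β = (0.9, 0.999), ε = 1e-8. Full-scale default lr 1e-4, batch
32; the tiny configuration trains with lr 1e-3, batch 32, and 15 epochs
for cross-validation runs (it memorizes a 32-image set well before the
200-epoch capacity check). A non-finite loss aborts with a diagnostic
rather than continuing. Class weighting (`class_weight="balanced"`) is
available but off by default.

## Evaluation

`make_folds` builds deterministic 10-fold plans: beat-level random
partition (intra-patient) or subject-level partition (inter-patient, fold
i validating on all beats of subject group i). Subject disjointness is a
hard invariant and is independent of beat order. Metrics per fold:
accuracy = trace/total of the 5×5 confusion matrix (true classes on rows);
one-vs-rest precision, sensitivity, specificity and F1 per class,
macro-averaged; macro one-vs-rest AUC by trapezoidal integration of the
ROC from softmax scores. A class absent from a fold's test set has
undefined one-vs-rest metrics: it is reported as NaN and excluded from the
macro mean. Fold means carry 95% normal-approximation confidence
intervals, mean ± 1.96·sd/√k (sample sd, ddof = 1), clipped to [0, 1] —
matching the lower/upper-bound presentation convention; the CI method for
the reference results is unstated, so the normal approximation is our
choice.

## Synthetic benchmark — what it does and does not show

The generator emulates: R-peak-centred beats at 360 Hz with
class-dependent morphology (sums of Gaussian bumps for P/Q/R/S/T with
class-specific positions, widths, amplitudes: widened high-amplitude QRS
with discordant T for V, absent P for S, an N/V hybrid for F, low
diffuse deflections for Q; templates are zero-mean), additive white
Gaussian noise calibrated to a target SNR against the noiseless template,
sinusoidal baseline wander (0.3 Hz, 0.05 mV default), and records with RR
intervals uniform in [0.7, 1.0] s — the physiological resting range, which
also keeps 256-sample windows from overlapping. Defaults: 15 dB SNR (a
moderately noisy but usable clinical signal), 10 beats/class.

It does **not** emulate rhythm context, heart-rate variability beyond the
RR jitter, within-class morphological variability across subjects,
electrode artifacts, or class imbalance. Consequently the five classes are
fully separable at 15 dB and cross-validated accuracies reach 100%; the
benchmark demonstrates that the pipeline is implemented correctly and can
be trained to convergence, not that it attains any particular accuracy on
real inter-patient MIT-BIH data. The inter-patient synthetic benchmark
assigns each generated record its own subject and differs from the intra
run only through fold structure, since synthetic "subjects" share
templates.

Problem sizes for desk-scale runs — 500 beats (100/class) for
cross-validation, 64 CWT scales rendered at 32 px, the tiny architecture,
15 epochs/fold — were chosen once as the smallest sizes at which every
stage (including 10 disjoint folds with ≥ 2 subjects per fold) is
exercised meaningfully.

## Known limitations

* The WFDB layer implements the subset of the format family that MIT-BIH
  uses (single-segment records, formats 16/212, MIT annotation files); it
  has been validated by round trip against itself, not against reference
  readers on real files.
* Denoising thresholds are per-level global; no translation-invariant
  (cycle-spinning) variant.
* The CWT ignores the cone of influence; edge coefficients are computed
  under zero padding and simply rendered.
* Training is plain full-precision NumPy on CPU: fine for the tiny
  configuration, impractical for the 224 px/C = 96 default at dataset
  scale.
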