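# Methods

## Problem setting

A pasture is imaged by a UAV in three bands — green (~560 nm), red
(~625 nm), near-infrared (~850 nm) — resampled to 0.5 m ground sampling
distance.  The target weed (*Silybum marianum*, milk thistle) grows in
sizeable contiguous patches of large individuals with rough canopy texture;
the surrounding graminaceous vegetation forms an even surface with very
smooth texture, and several species (notably *Avena sterilis*) are nearly
indistinguishable from the target in the visible bands while separating
partially in the NIR.  Classification is one-class: only target pixels are
used for training, and every pixel of a scene is then labelled 1 (target
weed), 2 (other vegetation) or 0 (nodata).

## Features and calibration protocol

Each pixel carries a 4-vector: green, red, NIR reflectance and a texture
band, the **population variance of NIR in a 7 × 7 moving window**.  Edge
windows are reflect-padded (edge value included); nodata (NaN) pixels are
excluded from window statistics and propagate only when the whole window is
nodata.  Population (1/n) rather than sample variance is used, matching the
common "local variance" raster operator.

From a labelled scene a balanced calibration sample of 1434 pixels per
class (2868 total) is drawn without replacement, then split 70/30
**stratified per class** (rounding half-up per class, remainder to test):
1004 + 1004 = 2008 training and 860 test pixels.  Features are z-scored by
the mean/sd of the **target-class training rows only**; the same affine map
(stored in every model file, with a digest checked at classification time)
is applied to all data a model ever sees.  Standardization is necessary
because the SVDD spread σ = 2.5 and all fraction thresholds are
scale-sensitive and the feature units differ by orders of magnitude
(reflectance ~10⁻¹, NIR local variance ~10⁻³).

## The shared threshold rule

Every detector converts a novelty score into a decision with the same
order-statistic rule: given training scores `s`, sort ascending, let
`k = round(fraction · N)` (half-up, 1-based), and set the threshold to
`(s(k) + s(k+1))/2`.  A point is novel when its score is **strictly
greater** than the threshold, so the boundary itself is a target and the
training rejection rate equals `1 − fraction` up to ties.  Defaults:
fraction 0.95 for SVDD, OC-SOM and the autoencoder (5% training outliers),
0.90 for OC-PCA (10%).

## Detectors

**SVDD (OC-SVM).**  Dual problem `min αᵀKα` over the capped simplex
`{Σα = 1, 0 ≤ α ≤ C}`, `C = 1/(Nν)`, RBF kernel `exp(−‖x−z‖²/σ²)`
(note: σ², not 2σ²).  The solver is Nesterov-accelerated projected
gradient with a bisection projection onto the capped simplex; step size
1/(2λ_max(K)) with λ_max by dense eigendecomposition for N ≤ 512 and power
iteration above.  Convergence is declared when the projected-gradient KKT
residual falls below tolerance (default 10⁻⁸ relative); non-convergence
raises an error carrying the residual.  Support vectors are the points with
α above 10⁻⁴·C.  The decision radius R² is **calibrated** by the shared
threshold rule on training kernel distances rather than read off boundary
support vectors — this makes the 5% training rejection exact and unifies
the thresholds across detectors; the boundary-SV radius is still computed
and stored in the model for comparison.  The decision rule is inclusive
(distance² ≤ R² ⇒ target).

**OC-SOM.**  8 × 8 rectangular grid (3 × 3 … 20 × 20 supported), online
Kohonen updates with a Gaussian neighbourhood; radius decays exponentially
max(rows, cols)/2 → 0.5 and learning rate 0.5 → 0.01 over 20 epochs
(conventional settings; the training schedule is a free choice and all of
it is exposed in `SomConfig`).  Codebooks initialise from a seeded random
sample of training points.  BMU ties break to the lowest unit index.

**Autoencoder.**  4 → 8 (sigmoid) → 4 (linear) network trained by
full-batch gradient descent on mean squared reconstruction error
(learning rate 0.1, 2000 epochs default; mini-batches optional).  The
linear read-out is deliberate: on standardized features a sigmoid output
could not reach values outside (0, 1), and the one-hidden-layer
autoencoder's optimum is principal-component-like, for which a linear
output is the natural parameterisation.  Weights initialise seeded uniform
[−0.5, 0.5]/√fan_in; gradients are verified against finite differences in
the test suite.

**OC-PCA.**  Eigendecomposition of the covariance of (centred) target
training data; the component count M is either explicit or the smallest
count reaching a cumulative eigenvalue share (default 0.95; a request for
the full variance on rank-deficient data warns and caps M at the rank).
Score: `‖(z−μ) − W Wᵀ (z−μ)‖²`, valid because W is orthonormal.  Centring
is applied even though standardized features are near-zero-mean already.
The free-parameter count d·M is recorded as metadata only.

## The scene simulator

Per pixel and band:

    reflectance = mean[class, band] + spread[class, band] · S_class
                  + amplitude[class] · mean[class, band] · H_band,   clipped to [0, 1]

* **Patch mask** — Gaussian-smoothed white noise (smoothing length
  `patch_scale`, default 12 px) thresholded at the empirical quantile of the
  requested coverage (default 0.30), giving exact coverage and contiguous
  blobs whose size grows with `patch_scale`.
* **S_class** — one smooth unit-variance Gaussian field per class
  (smoothing length 16 px, well above the 7-px texture window), shared
  across bands and scaled by the per-band spread (default 0.02).  Sharing
  one field across bands encodes the dominant brightness/vigour axis of
  real canopies: canopy density modulates all bands together, so each
  class's spectral cloud is correlated and effectively low-dimensional.
  This is what makes subspace-based novelty detection (OC-PCA, autoencoder)
  meaningful, as it is on real imagery.
* **H_band** — unsmoothed white noise per band, scaled multiplicatively by
  `amplitude[class] · mean[class, band]` (defaults 0.055 target, 0.010
  background), which concentrates texture in the high-reflectance NIR band
  where canopy texture is strongest.  The target's amplitude must strictly
  exceed the background's.
* **Spectra** — target (0.10, 0.09, 0.55), background (0.09, 0.10, 0.42):
  visible bands nearly identical, NIR partially separated.  These are
  synthetic values chosen to reproduce the qualitative spectral-overlap
  pattern of the field system, not field measurements.

Randomness is split into named substreams (mask / fields / noise) from one
seed, so changing one parameter does not reshuffle unrelated noise, and
identical configs give bit-identical scenes.

**What the simulator does not emulate:** radiative transfer, illumination
geometry and shadows, georeferencing, mixed boundary pixels beyond what the
7 × 7 texture window straddling a patch edge produces, species diversity
within "other vegetation", and sensor noise models.  Passing benchmarks on
these scenes therefore demonstrates the correctness and calibration of the
detectors under the assumed class structure (spectral overlap in the
visible, partial NIR separation, texture contrast), not field-level
accuracy.

## Evaluation

2 × 2 contingency tables, rows actual, columns predicted, order (target,
other).  Overall = 100·trace/N; producer's(c) = diagonal over the actual
row total (omission = 100 − producer's); user's(c) = diagonal over the
predicted column total.  Commission(c) uses the **actual-other row total**
as denominator — the share of the foreign class wrongly assigned to c —
which is the convention consistent with published per-class over-estimation
figures.  Metrics with zero denominators are reported as undefined (`None`),
never 0.  Values stay full-precision internally; display rounding is
half-up to 2 decimals.

## Problem sizes and numerical choices

Default test/benchmark scenes are 256 × 256 px (65 536 px, ≥ 1434 target
pixels guaranteed at 30% coverage); the mosaic-scale check uses 885 × 885 =
783 225 px, matching the magnitude of a full survey mosaic.  Scoring is
chunked (~4 × 10⁶ kernel/codebook evaluations per block) so whole-mosaic
classification stays within modest memory.  Tiny negative variances and
kernel distances arising from floating-point cancellation are clipped at
zero.  Model files are JSON with sorted keys, so identical configurations
reproduce byte-identical files.

## Known limitations

* The SVDD boundary-SV radius and the calibrated radius differ slightly by
  design; only the calibrated one is used for decisions.
* The autoencoder inherits the usual sensitivity of gradient-trained
  perceptrons to learning-rate choice; divergence raises an explicit
  training error rather than degrading silently.
* OC-PCA detects only off-subspace deviation: outliers lying inside the
  retained subspace are invisible to it, which is why it trails the other
  detectors on both real and simulated scenes.
* The simulator's two-class world has no mixed or unknown classes; nodata
  handling is exercised but real-mosaic artefacts (seams, vignetting) are
  out of scope.
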