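# Methods

This note documents the models, conventions and numerical choices
behind `calscreen`, and what the synthetic data do and do not show about
real recordings.

## Synthetic response archetypes

The generator emulates single-cell fluo-4 responses to ATP in a
high-content setting: 380 frames at 2 Hz (190 s), raw-fluorescence
units. Three archetypes correspond to the phenotype classes:

| archetype | model | defaults |
|---|---|---|
| Oscillation & Peak | baseline + sinusoidal burst + logistic rise | burst 0.25 Hz, 80 a.u., 10–80 s; rise 400 a.u. |
| Peak | baseline + logistic rise | onset 90 s, 10–90% rise time 40 s |
| Other | baseline (+ one decaying transient) | transient 40 a.u., τ = 10 s |

Choices and why:

* **Baseline 420 a.u.** — matches the control resting-intensity regime
  of the assay (~420 ± 40 RFU), so frame-0 well summaries land on a
  realistic scale.
* **Logistic (sigmoid) rise** — a sustained rise to a plateau with two
  interpretable parameters (onset, 10–90% rise time). The default rise
  time of 40 s keeps the order-8 polynomial fit faithful: much sharper
  steps produce Gibbs ripple in the fit that distorts the
  valley-to-peak amplitude descriptor (dFP) by 10–20%; at 40 s the
  error is ≈ 4%.
* **Oscillation burst = sinusoid × Tukey window (α = 0.25)** — the
  tapered-cosine envelope keeps interior cycles at full amplitude. A
  fully tapered (Hann) envelope would attenuate most cycles below the
  small-peak detection threshold.
* **Oscillation frequency 0.25 Hz** — intermediate Ca²⁺ oscillations
  with a 4 s period. At 2 Hz sampling this puts the sinusoid apex
  exactly on the sample grid when the burst starts on a half-second
  boundary; the width-3 prominence detector then sees a neighbor drop of
  (1 − cos π/4) ≈ 0.29 of the local amplitude. Slower sinusoids
  straddle two nearly equal samples at the apex and their windowed
  prominence collapses toward zero regardless of amplitude — a
  genuine property of narrow-window peak detection on smooth signals,
  worth knowing when tuning the detector for real data.
* **Noise** — i.i.d. Gaussian per frame, default 5% of each archetype's
  dynamic range (noise-free max − min). Cell-to-cell variability is
  emulated by relative jitter (default 10%) on amplitudes and absolute
  jitter on event onsets. Shot noise, photobleaching, motion and
  cell–cell coupling are deliberately not modeled.
* **Mixtures** — a plate config maps ATP dose to a class-probability
  triple. The default map decreases the Other probability from 0.90 at
  0 µM to 0.21 at 1,000 µM, anchoring the top dose at the control
  condition's observed fractions (0.27/0.52/0.21 after renormalizing
  the printed 0.27/0.52/0.19, which sums to 0.98 due to rounding).
* **Determinism** — one master seed derives independent per-well and
  per-cell streams via `numpy.random.SeedSequence`; identical configs
  are bit-identical.

Because the archetypes are smooth parametric curves plus Gaussian
noise, classifier accuracies measured on them are an upper bound on
real-data performance: they demonstrate that the descriptor set
separates the three response shapes at realistic noise, not that a tree
trained on synthetic data transfers to a microscope.

Image stacks render each cell as a uniform-intensity ellipse carrying
its trace value (background only outside cells), with optional Gaussian
read noise, 16-bit, 696 × 520 px by default. Placement is rejection
sampling with a center-distance guard, so masks never overlap.

## Image pipeline

* Averaged image = pixel-wise mean over all frames; segmentation runs
  once on it and the masks are frozen for all frames (no per-frame
  re-segmentation or motion correction).
* Segmentation: global threshold at a configurable intensity quantile,
  4-connected components, then per-component local re-thresholding in
  fixed intensity steps for components above `max_area` (up to
  `max_iterations` rounds); undersized fragments are dropped. The
  initial quantile must sit above the background fraction of the image
  — a quantile inside the background's noise distribution turns the
  background into speckle components. With the synthetic scenes'
  bimodal histograms any quantile between the background fraction and
  ~1 works; real images may need the iterative refinement to do more of
  the work.
* Traces: mean of pixel values under the fixed mask per frame. Resting
  intensity: the same mean on frame 0 only; the well value is the
  unweighted mean over cells and is reported as missing (not 0) for an
  empty well.
* **Elongation factor**: max intercept over mean perpendicular
  intercept. Max intercept = the longest chord through the mask
  centroid over orientations discretized at 1° (ray marching at 0.25 px
  steps). The mean perpendicular chord is computed as mask area divided
  by the occupied extent along the max-intercept axis — mathematically
  the mean of the perpendicular chord profile, and far less sensitive
  to rasterization than summing per-column extents. Because the mean
  chord of a circle is π/4 of its diameter, the raw ratio would score a
  perfect disk at 4/π ≈ 1.27; the mean perpendicular intercept is
  therefore calibrated by that circle factor so a round cell scores
  exactly 1, which is the interpretive convention of the assay
  (1 = round/compromised, high = elongated/healthy). Accuracy on
  rasterized ellipses: ≈ 2% scale stability from ~300 px up, < 5%
  rotation sensitivity at 1° chords. Masks under 2 px wide are computed
  but flagged (warning + `degenerate` attribute).

## Trace descriptors

* **Polynomial fits** in the Chebyshev basis on time rescaled to
  [−1, 1]; a raw monomial Vandermonde at order 25 over 380 samples is
  numerically singular. Exported coefficients are power-series
  coefficients in rescaled time; only the order-8 fit's 9 coefficients
  and MSE are exported (expFitCoeff_0..8, expFitErr). The order-25 fit
  exists solely to supply the oscillation residual.
* **Peak detection contract**: sample *i* is a peak iff it is the
  strict maximum of its centered window of `width` samples (earliest
  index on ties) and its prominence — height above the higher of the
  two flanking minima inside the window — is at least `threshold`.
  Width is odd-adjusted and floored at 3; samples within half a window
  of the signal boundary cannot be peaks (no centered window exists
  there, and edge ripple of the order-8 fit would otherwise register as
  a spurious peak at index 0).
* **Large peaks (50/50) and the sustained-rise rule**: large peaks are
  detected on the order-8 fitted curve. A monotone rise to a plateau —
  precisely the macropore signature the descriptor exists for — has no
  prominence peak under any reading (the fitted curve's ripple carries
  prominence ≈ 10–35, under the 50 threshold). When no prominence peak
  exists but the fitted curve ends at least `threshold` above its
  start, the rise is counted as one large peak at the curve's maximum,
  with the preceding minimum as its valley for the dFP (amplitude) and
  dTP (time) descriptors.
* **Small peaks (3/3)** are counted on the order-25 residual within the
  first and last 90 s, taken as 180 frames at the nominal 2 Hz
  (exposure time is ignored for the time base).
* **Spectra**: one-sided periodogram |X_k|²/n² of the mean-subtracted
  trace with interior-bin doubling; the normalized spectrum divides by
  total power and sums to 1. All spectral moments (amp, peak location,
  mean, median, SD) exclude the DC bin, which is identically zero after
  mean subtraction. A constant trace has zero total power: its raw
  moments are reported as 0 (the vector is genuinely zero), while the
  peak location, the normalized spectrum and the Gaussian fits are
  undefined and flagged.
* **Gaussian spectral fit**: single Gaussian on the non-DC bins,
  initialized at the power maximum with the half-power half-width,
  bounded iterations. The fitted width is bounded below by **three
  frequency bins**: an unconstrained fit of a flat (noise) spectrum
  collapses onto its single highest bin (~97/100 noise realizations),
  while genuine burst lines span several bins and are unaffected.
  Non-convergence yields a missing-flagged result.
* **Missing values** are NaN throughout; the classifier consumes them
  directly (each split learns at training time which branch missing
  values take). Nothing is imputed.

Shift invariance holds by construction: adding a constant changes only
meanF, medF and the constant coefficient of expFitCoeff.

## Classifier

A binary entropy-gain decision tree (the C4.5/J48 family) with minimum
leaf size 2 and optional cost-complexity pruning, trained via
scikit-learn and exported to plain node arrays; prediction is the
package's own traversal of the JSON-serialized tree (asserted
equivalent to the learner, including NaN routing and alphabetical leaf
tie-breaking). Gain-ratio splitting and subtree raising of the original
C4.5 are not reproduced — the claim the package supports is the
achievable accuracy of a decision tree on these 27 descriptors, not a
specific topology.

Cross-validation is stratified (the 333/536/840 composition is
imbalanced) with seeded shuffling; every record is predicted exactly
once by a model that did not train on it, and the aggregated matrix
total always equals the training-set size. The confusion matrix follows
the benchmark table's orientation — columns = true class, rows =
predicted — so per-class accuracy is the column diagonal over the
column sum and the column sums reproduce the class counts. After CV the
deployed model is refit on the full training set.

On the full synthetic training set (1,709 traces, 5% noise, parameter
jitter) the 10-fold CV accuracy is ≥ 98.5% across seeds; the dominant
separating descriptors are the order-8 fit error (oscillation energy),
dF/lgePk (sustained rise) and the small-peak counts.

## Well analytics

Fractions are computed per well and averaged across replicate wells
unweighted (each independent experiment counts once); a cell-weighted
pooling is available through the aggregation-linearity identity but is
not the default. Sample SD uses the n−1 denominator and is reported as
0 (flagged) for single-well conditions. The dose–response report
classifies each class's mean-fraction profile as
increasing/decreasing/flat/non-monotone with an absolute per-step
tolerance (default 0.02 — the underlying claim is qualitative).

## Problem sizes

The test suite exercises the full 1,709-trace benchmark composition for
cross-validation, a complete image-based run at 400 cells in one
696 × 520 × 380 stack, 1,000-trace oracle equivalence for peak
detection, and 1,000–3,000-cell wells for binomial mixture checks;
smaller compositions (e.g. 200 traces) back the shared fixtures. These
sizes keep the whole suite around a minute on one CPU while leaving
every statistical tolerance at its stated value.

## Known limitations

* Archetypes are smooth parametric shapes; real responses show
  photobleaching trends, baseline drift, motion and compound kinetics
  none of which are modeled. Synthetic accuracy is an upper bound.
* The window-3 prominence detector is phase-sensitive for smooth
  oscillations near half the sampling rate's period (see above);
  spike-like real oscillations are less affected.
* The segmentation refinement only raises thresholds; cells dimmer than
  the initial global threshold are never recovered.
* The elongation chord measure assumes the centroid lies inside the
  mask; strongly concave cells would need a geodesic variant.
* Drug-effect tables are format-compatible with the assay's reporting
  (RFU, elongation, three fraction columns ± SD) but real drug
  pharmacology is outside what synthetic data can reproduce.
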