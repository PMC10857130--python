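# Methods

## Scan model and coordinates

A scan is an `n_rows·n_cols × m` intensity matrix over a square array
(defaults: 36 × 36 points, 15 mm edge, m = 308 channels).  Spectra are stored
in scan order: row-major from the top-left corner, matching the instrument's
scan direction.  Physical positions are pixel centers,
x = (col + ½)·pitch rightward and y = (row + ½)·pitch downward, with
pitch = 15/36 ≈ 0.417 mm.  All heatmaps render row 0 at the top so grid and
image orientation agree.

The wavenumber axis is configurable; the default is uniform, 602–1830 cm⁻¹
in 4 cm⁻¹ steps (308 channels).  No uniform 4 cm⁻¹ grid contains 1006, 1603
and 1614 cm⁻¹ simultaneously, so exact on-grid peak readings depend on the
anchor; the default anchor puts 1006 and 1614 on-grid.  Datasets whose
spectra have 307 channels are right-padded with their last value on load, so
the pipeline's authoritative feature length is always 308.

## Synthetic scans

The simulator generates the measurement this package analyzes:

- **Plume.**  Gas concentration over the array follows a 2D Gaussian,
  G(x, y) = strength · exp(−((x−x0)²/2σx² + (y−y0)²/2σy²)), sampled at pixel
  centers.  No airflow or time dynamics are modeled.
- **Signatures.**  Lorentzian lines by default (Gaussian selectable):
  S(ν) = Σ a/(1 + ((ν−c)/(fwhm/2))²).  BZD has peaks at 1006 (amplitude 1.0)
  and 1603 cm⁻¹ (0.8); EBZD a single peak at 1614 cm⁻¹; the sensor baseline
  has residual-chemistry peaks at 900, 1050 and 1400 cm⁻¹ (amplitudes
  1.0/0.7/0.5, FWHM 25 cm⁻¹).  Signature FWHM defaults to 20 cm⁻¹, a typical
  solid-state Raman linewidth at ~4 cm⁻¹ instrument resolution.
- **Composition.**  V[p] = Σ_g plume_g(p)·m_p·S_g + b·B + bg + ε_p with
  baseline strength b = 0.3, a flat broadband pedestal bg = 0.1 (the
  fluorescence background every real SERS spectrum rides on), per-pixel
  lognormal adsorption multipliers m_p (spread 5% — gas adsorption has a
  degree of randomness), and additive white noise ε with sd 1% of the maximum
  clean signal.  Gap pixels — one-pixel bands at the internal boundaries of
  the 3 × 3 sensor mosaic (rows/columns 12 and 24; 140 pixels in all) — carry
  zero-mean noise-only spectra.  Everything is clipped to ≥ 0; the clipped
  fraction over signal-bearing pixels is recorded in scan metadata and stays
  below 1% at default noise (gap pixels clip about half their channels by
  construction, which is intended: they are the unmixing's noise component).
- **Feature datasets.**  Class 1/2 spectra are BZD/EBZD signatures with peak
  centers jittered by U(−2, 2) cm⁻¹, lognormal amplitude jitter (10%), and
  2% white noise; class 0 (interference) alternates baseline-like spectra and
  low-amplitude pure-noise spectra.  Default compositions are the reference
  study's: 68/21/13 training and 28/14/14 test spectra.

Fixed seeds make scans and datasets bit-identical; noise-free scans equal the
generative formula exactly, so the simulator is its own oracle.

What the generator does **not** emulate: wavenumber miscalibration and
non-uniform axes, baseline drift across the array, sensor-to-sensor
sensitivity steps, adsorption saturation, plume asymmetry from airflow, and
cross-adsorption between gases.  Passing tests therefore demonstrate that the
algorithms recover what the stated measurement model produces, not that they
are robust to every artifact of physical scans.

## Unmixing

Frobenius-objective multiplicative updates,
H ← H ⊙ (WᵀV)/(WᵀWH + δ), W ← W ⊙ (VHᵀ)/(WHHᵀ + δ), δ = 1e-12, initialized
from seeded uniform (0, 1] entries scaled by √(mean(V)/r).  The update never
increases the objective, which the result object asserts via its stored
objective trace.  Convergence: relative objective decrease < 1e-6 or 2000
iterations (a 1296 × 308 scan at rank 3 converges in a few seconds on one
CPU).  Rank rule: r = n_gases + 2.

After factoring, each H row is rescaled to unit maximum with its W column
scaled inversely (the product is unchanged), and components are reordered by
descending total concentration so the dominant gas is component 1.
Signature matching assigns components to gases greedily by Pearson
correlation (threshold 0.8, injective over gases, ties toward the lower
component index).

NMF is unique only up to scaling/permutation under favorable conditions; a
strong flat pedestal shared by all pixels adds genuine rotational ambiguity
and lets a little baseline leak into the gas component's spectrum (observable
as correlation ~0.97 instead of >0.99 on pedestal-heavy noiseless scans).
This is a property of the factorization model, not of the solver; the
concentration column — what localization consumes — is barely affected.

## Heatmaps and overlays

Concentration columns are reshaped in scan order and min-max normalized per
component (each map independently spans [0, 1]); constant columns normalize
to all-zeros rather than NaN.  Overlays blend each map's value times its
named RGB color additively, clipped to [0, 1] — the rendering is qualitative,
so no perceptual colormap calibration is attempted.

## Localization and sizing

The plume model fitted to a heatmap is a sum of k ≤ 3 axis-aligned elliptical
Gaussians plus one shared constant offset (no rotation term).  The offset
absorbs baseline leakage into the concentration map.  Fitting is bounded
nonlinear least squares (scipy `least_squares`, trust-region reflective):
σ ∈ [pitch/2, array_size], centers allowed one pitch beyond the array edge,
amplitudes ≥ 0.  Up to three seeded restarts with ±20% perturbed starts run
if the first attempt fails; non-convergence raises an error carrying the best
attempt.

Initial centers come from peak seeding on a copy smoothed with a 1-pixel
Gaussian blur (reflective boundary); the fit itself always runs on the
unsmoothed map.  A candidate peak must (i) be an 8-neighborhood maximum
(ties allowed, so a plume centered between pixels still seeds), (ii) reach
25% of the map maximum, (iii) lie ≥ 6 px from an accepted taller peak, and
(iv) rise ≥ 10% of the map maximum above its highest saddle toward any
taller accepted peak.  The prominence criterion (iv) is what separates a
genuine second source (deep valley between plumes) from a noise wiggle on the
flank of a larger plume (tall in absolute height, negligible prominence).
σ starts are intensity-weighted second moments in a ~3 mm window.

The fitted diameter is (σx + σy)/2 in mm.  Because the gap bands cut
near-zero stripes through the plume, fitted diameters are systematically
smaller than the true plume width; the OLS size calibration
(fitted = slope·actual + intercept, with R²) is exactly the instrument
calibration that absorbs such a systematic, which is why a high R² — not a
unit slope — is the meaningful quality measure.

## Identification

Architecture (5 layers): 1D convolution (8 output channels, kernel 7,
stride 1, valid padding) → ReLU → fully-connected (64 units) → ReLU →
fully-connected (3 units) → softmax.  For the default 308-channel input this
is 154,947 parameters.  The network, its backward pass, and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) are implemented directly in numpy; training
is bit-reproducible under the config seed (weights and batch shuffling use
separate seeded generators).

Schedule: cross-entropy, batch size 8, 100 epochs, learning rate
η(t) = lr_min + (lr_init − lr_min)(1 + cos(π(t mod T)/T))/2 with
lr_init = 1e-4, lr_min = 1e-5, T = 10 (warm restarts; a non-restarting
variant can be had by setting the period to the epoch count).  Each spectrum
is divided by its own maximum before input, so classification rests on
spectral shape; a spectrum with no signal at all (max ≤ 0) is labeled
interference directly rather than through the network.  The stratified split
sends round(0.7·n) samples per label to training (68/21/13 → 48+15+9 = 72
train, 30 validation); labels with fewer than two samples stay in training
under a warning.  Unstated widths (8 channels, kernel 7, 64 hidden units,
batch 8, 100 epochs) are the smallest configuration that cleanly separates
the three classes, and all are exposed in `ClassifierConfig`.

## Pipeline

`run_pipeline` chains clip → NMF (rank = gases + 2) → normalize → identify
(signatures or trained classifier) → per-gas heatmap → Gaussian fits (k =
number of surviving plume peaks, ≤ 3) → overlay, fully seeded, and returns
all intermediates plus a provenance block sufficient to re-run identically.

## Problem sizes and determinism

Tests and the acceptance script run at the study's native sizes — 1296 × 308
scans, rank 3–4 factorizations, 102/56-spectrum datasets, 100-epoch training
— since the whole pipeline is desk-scale: a full simulate→unmix→fit pass
takes a few seconds and one training run ~4 s on one CPU.  All randomness
flows through explicit integer seeds (numpy `default_rng`); there is no
global-state seeding.

## Known limitations

- The axis is uniform by default although real spectrometer grids are not.
- Plumes are axis-aligned Gaussians; rotated or skewed plumes will fit with
  inflated σ and residuals.
- The classifier is trained and evaluated on simulated spectra only; transfer
  to physical instrument spectra is untested.
- Gap pixels are replaced, not interpolated, so maps legitimately show
  near-zero crosses; fits treat those pixels as data, which shrinks σ (the
  size calibration absorbs this, single-scan σ values read low).
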