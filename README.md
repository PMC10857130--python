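# sersmap

Analysis toolkit for **2D SERS gas-sensor-array imaging**: simulate
hyperspectral scans of a surface-enhanced-Raman sensor array exposed to odor
plumes, unmix them into gas / baseline / noise components, visualize the gas
spatial distribution as heatmaps, localize and size odor sources by 2D
Gaussian fitting, and identify component spectra with a small 1D
convolutional classifier.

## The problem

A square sensor array (15 mm × 15 mm, scanned as a 36 × 36 grid) is exposed
to gas evaporating from one or more odor sources — benzaldehyde (BZD,
characteristic Raman peaks at 1006 and 1603 cm⁻¹) and 4-ethylbenzaldehyde
(EBZD, peak at 1614 cm⁻¹).  Scanning yields 1296 spectra of 308 Raman-shift
channels, stacked as the detection matrix **V** ∈ ℝ₊^(1296×308).  Each
spectrum mixes the gas signature (scaled by the local gas concentration), the
sensor's own baseline, and noise — including noise-only spectra from the gaps
between the individual sensors of the 3 × 3 mosaic.

## The method

1. **Unmixing.**  V is factored by non-negative matrix factorization,
   V ≈ W·H, with multiplicative (Lee–Seung) updates under the Frobenius
   objective.  Rows of H are component spectra; columns of W are per-position
   component weights.  The rank is *r* = (number of gas types) + 2, the two
   extra components capturing baseline and gap noise.
2. **Visualization.**  A gas component's W column is min-max normalized and
   reshaped to the 36 × 36 grid (row-major, top-left origin — the scan
   order), giving a concentration heatmap.
3. **Localization and sizing.**  The heatmap is fitted with up to three
   elliptical Gaussians plus a constant offset,
   F(x, y) = offset + Σᵢ Aᵢ·exp(−((x−x0ᵢ)²/2σxᵢ² + (y−y0ᵢ)²/2σyᵢ²)),
   in mm.  The fitted source diameter is (σx + σy)/2, calibrated against the
   actual diameter by ordinary least squares.
4. **Identification.**  Component spectra are assigned to
   {interference, BZD, EBZD} either by Pearson correlation against reference
   signatures or by a 5-layer 1D CNN (conv → ReLU → FC → ReLU → FC, softmax
   output) trained with Adam, initial learning rate 1e-4, cosine annealing to
   1e-5 with 10-epoch warm restarts, and a stratified 7:3 train/validation
   split.

Because no public scans exist, the package ships a first-class simulator that
generates the same study conditions (grid, channel count, signatures,
Gaussian plumes, gap-noise bands) with known ground truth; every stage is
tested against it.

## Worked example

Simulate a single centered BZD source and run the full pipeline:

```sh
cat > scenario.yaml <<EOF
seed: 42
sources:
  - gas: BZD
    center: [7.5, 7.5]
    sigma: [2.0, 2.0]
EOF
sersmap simulate --config scenario.yaml --out scan.csv
sersmap run-all scan.csv --n-gases 1 --seed 42 --outdir out
```

prints

```
wrote scan.csv (1296 spectra × 308 channels) and scan.truth.json
BZD: source at (7.54, 7.56) mm, fitted diameter 1.67 mm
wrote out/report.json
```

The simulated source sits at (7.5, 7.5) mm — the array center — so the fitted
center is recovered to within a fraction of the 0.417 mm pixel pitch.  The
fitted diameter, (σx + σy)/2 of the fitted Gaussian, is smaller than the true
plume σ of 2.0 mm because the inter-sensor gap bands cut near-zero stripes
through the plume; the linear size calibration (`sersmap calibrate`) absorbs
exactly this kind of systematic shrinkage:

```sh
sersmap calibrate pairs.csv
fitted = 0.3109·actual + 0.3385  (R² = 0.9741)
```

Classifier training and evaluation on simulated feature datasets
(train 68/21/13, test 28/14/14 spectra for interference/BZD/EBZD):

```sh
sersmap train train.csv --seed 1
trained 100 epochs: final train loss 0.0073, valid loss 0.0098; wrote model.json
sersmap evaluate test.csv
accuracy 100.00%  (confusion → report.json)
```

The same stages are available as Python functions; see `sersmap.pipeline.run_pipeline`.

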