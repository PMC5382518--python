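# civstrain

Dense myocardial motion and strain from tagged cardiac MR, by correlation
image velocimetry (CIV).

Tagged MR imprints a grid of dark saturation lines on the myocardium that
deforms with the tissue, making cardiac motion visible on short-axis
slices. `civstrain` turns a sequence of tagged slices into quantitative
deformation measures in three stages:

1. **Tag-grid extraction** — harmonic-phase (HARP-style) isolation of the
   two tag harmonics in the Fourier domain; the wrap discontinuities of
   each harmonic phase localize the tag lines, and the product of the two
   edge images gives a sparse grid image interpolated to 512×512.
2. **Displacement estimation** — PIV-style pattern matching: one vector
   per correlation box (side C_B, 50% overlap) found by zero-mean
   normalized cross-correlation over a search box (side S_B), with
   sub-pixel Gaussian peak fitting, a deformation-compensating second
   pass, median-test outlier replacement and quadratic-surface smoothing.
3. **Strain mapping** — rotation of the dense field into the cylindrical
   LV frame (`u_r = u cos θ + v sin θ`, `u_θ = −u sin θ + v cos θ`),
   radial and circumferential strains `ε_rr = ∂u_r/∂r` and
   `ε_θθ = (1/r) ∂u_θ/∂θ + u_r/r`, divergence `E = ∂u/∂x + ∂v/∂y`,
   AHA-segment strain curves, and landmark tracking.

A synthetic-data module generates the validation imagery — a 512×512
black/white tag grid (23 px cells, 8 px lines) and an analytic
radial-dilation + torsion field `u_r = 0.02 r`, `u_θ = 0.035 r` — so the
whole pipeline is testable without any patient data.

## Worked example

Estimate the displacement field imposed on the synthetic grid and check
it against the exact field:

```python
import civstrain as cs

img1 = cs.generate_synthetic_grid(cs.GridSpec())       # 512x512 tag grid
img2 = cs.warp_image(img1, cs.AnalyticFlow())          # impose the flow
res = cs.CIVModel(img1, img2, cs.CivParams()).fit()    # (C_B, S_B) = (25, 55)
print(res.summary())
```

```
CIV displacement estimate
========================================
image size:            512 x 512 px
correlation box C_B:   25 px
search box S_B:        55 px
overlap:               50%
passes:                2
measurement grid:      41 x 41 (1681 vectors, step 12 px)
valid vectors:         1614 (96.0%)
filled vectors:        67
mean |d|:              7.531 px
mean correlation:      0.957
```

96% of the 1681 interrogation boxes correlate cleanly (the remainder —
frame-border boxes whose content leaves the field of view — are filled
from their neighbourhood); the mean displacement magnitude of ~7.5 px
reflects the imposed dilation+torsion field. The full error analysis:

```python
report = cs.run_synthetic_experiment()
print(report.summary())
```

```
Synthetic deformation error report
========================================
slope error e_s^u:     1.68 %  (fit 0.01966 vs true 0.02000)
slope error e_s^v:     1.16 %  (fit 0.03459 vs true 0.03500)
mean e^u (|d| >= 3 px): 2.16 % (std 3.28 %)
mean e^v (|d| >= 3 px): 1.93 % (std 2.87 %)
```

The slope errors compare the least-squares slope of each recovered
component along the horizontal line through the flow centre with the
exact slopes (0.02 and 0.035); the masked means summarize the pixelwise
relative error where the true displacement is at least 3 px — below
that, relative error is dominated by the zero lines of the field.
`report.plot_error_maps()` shows the error maps (colour scale saturated
at 0.2), and `cs.param_sweep(...)` maps both slope errors over a
(C_B, S_B) grid.

## Command line

The `civstrain` entry point chains the same stages on files:

```bash
civstrain synth --size 512 --cell 23 --line 8 --out grid.png
civstrain warp  --in grid.png --out warped.png
civstrain civ   --im1 grid.png --im2 warped.png --cb 25 --sb 55 --out field.tsv
civstrain extract --in slice.png --out taggrid.png --size 512
civstrain sweep --cb 15:85:10 --sb 25:95:10 --out sweep.csv
civstrain run   --config pipeline.yaml      # extract -> civ -> strain curves
```

Fields are TSV (`x y u v corr flag`), strain curves and landmark tracks
CSV, images 8/16-bit PNG or TIFF; every artifact gets a JSON sidecar
recording the parameters that produced it.

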