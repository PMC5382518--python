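# Methods

`civstrain` estimates dense in-plane myocardial motion from tagged cardiac
MR (tMR) short-axis slices by correlation image velocimetry (CIV) — the
cross-correlation pattern-matching core of particle image velocimetry —
applied to tag-grid images extracted with a harmonic-phase procedure, and
derives radial/circumferential strain in a cylindrical frame about the
left-ventricular axis. This note records the model, the numerical choices,
and what the synthetic validation does and does not demonstrate.

## Coordinate and sign conventions

Pixel coordinates are 0-based indices of pixel centres; `x` runs along
columns (rightward), `y` along rows (downward). The polar angle `theta` is
measured from +x toward +y; `+u_theta` points in the direction of
increasing `theta`. A displacement `d = (u, v)` at a point of image 1 maps
that point to its position in image 2. These conventions are applied
consistently across generation, estimation and strain mapping so that all
internal closure checks (polar transform of the analytic field, strain
trace vs divergence, landmark advection) hold exactly.

## Tag-grid extraction (harmonic phase)

A two-direction tag pattern contributes a pair of spectral harmonics. For
each direction the lowest harmonic peak is located as the
maximum-magnitude bin in the positive-frequency half-plane of that
direction's axis, excluding a DC-guard disk of 3 bins. A peak must exceed
both 3× the median spectral magnitude and 1e-3× the strongest spectral
component; the second floor is needed because noise-free synthetic images
have a near-zero median spectrum, which would otherwise let numerical
residue pass as a harmonic.

The spectrum is multiplied by a radial taper about the peak — full pass to
radius 5 bins, the monotone sinusoidal roll-off `(1 - sin(pi (r - 6) / 2)) / 2`
between 5 and 7 bins, zero beyond — i.e. the 1→0 branch of that
oscillatory expression, giving a proper band-pass window. The taper radii
are fixed in frequency bins regardless of tag spacing; this matches tag
spacings of roughly 5–10 px on ~100 px frames and is configurable.

The wrapped phase of the inverse transform is a quasi-linear ramp whose
2π wrap discontinuities sit on the tag lines. Edge strength is taken as
the absolute 3×3 Laplacian of the *wrapped* phase: the wrap jumps produce
strong ridges while the smooth ramp between tags produces nearly nothing.
(An alternative wrap-free formulation via Laplacians of cos/sin of the
phase was rejected: for a pure ramp it returns the constant squared
spatial frequency, i.e. no tag-line localization at all.) The two
directional edge images are multiplied, contrast-stretched with 1%
saturation at both tails, and bicubically interpolated to the working
resolution (512×512 by default). The product concentrates energy at tag
crossings, yielding a sparse bright pattern on a near-zero background —
well suited to zero-mean normalized correlation.

## Displacement estimation (CIV)

Interrogation windows ("correlation boxes", side `C_B`, default 25 px) are
tiled over image 1 with 50% overlap starting `C_B/2` from the border;
boxes overhanging the frame are dropped. For each box the zero-mean
normalized cross-correlation (skimage `match_template`) against the
`S_B`-sided search region of image 2 (default 55 px; the region is clipped
at the frame with the shift origin tracked) gives a correlation surface in
[-1, 1]; the largest detectable first-pass shift is `(S_B - C_B)/2`
(15 px at the defaults, matching the ≤ ~15 px motions of interest — and,
at the 512-px working resolution where the tag period is ~32 px, safely
below the half-period at which periodic-pattern matching becomes
ambiguous).

The integer peak (ties broken toward the smallest shift magnitude, then
row, then column offset) is refined per axis by a three-point Gaussian
(log-parabola) fit, falling back to a plain parabola when a sample is
non-positive; the refinement is clamped to ±0.5 px. A peak on the surface
border flags the vector instead (search too small there).

Pass 2 (default; more passes allowed) uses the validated, smoothed pass-1
field as a predictor: the search is re-centred on the interpolated
prediction, and the image-2 patch is sampled under the predictor's local
affine map (identity plus the interpolated Jacobian of the predictor),
which compensates the leading-order variation — strain and rotation — of
the displacement within a box. The residual search shrinks to `C_B + 8`
px. Counter-deformation is only applied where the sampling window is fully
inside the frame; overhanging boxes fall back to a plain clipped search
about the rounded prediction. (Filling out-of-frame samples with a
constant or with edge replication was tried and rejected: both bias the
sub-pixel peak at borders, visibly breaking the exact-zero result on an
identical image pair.)

Validation: vectors are replaced when flagged, when the correlation peak
is below 0.3, or when their deviation from the 8-neighbourhood median
exceeds 2 px; replacements take the neighbourhood median and the fill is
iterated so that clusters of unmeasurable vectors — frame corners whose
content genuinely leaves the field of view — are filled inward from the
trusted region. Smoothing fits a local quadratic surface per component
over a ±2-grid-step window (clipped at the field border), which
reproduces any affine field exactly everywhere; the analytic validation
field is affine, so smoothing there suppresses noise without bias.
Dense per-pixel fields are obtained by bilinear interpolation between
measurement points (edge value outside), which is exact at the points and
reproduces linear fields.

Known noise floor: with a three-point peak fit the correlation neighbours
are generally asymmetric even at a perfect integer peak, so even an
identical image pair yields vectors at the 0.01–0.05 px level on generic
imagery (exactly zero on the periodic grid). Strain computed across a
12 px grid step inherits a floor of a few 1e-3.

## Strain mapping

The dense field is rotated pointwise into the cylindrical frame
(`u_r = u cos t + v sin t`, `u_t = -u sin t + v cos t`). Radial strain
`eps_rr = d(u_r)/dr` and circumferential strain
`eps_tt = (1/r) d(u_t)/dt + u_r/r` are evaluated by resampling the polar
components on ±1 px radial/tangential stencils with bilinear
interpolation and centred differencing — no intermediate polar raster, so
no angular-resolution choice. Pixels with `r < 5` px (the 1/r terms) or
without stencil support are masked. The Cartesian divergence
`E = du/dx + dv/dy` (np.gradient: centred interior, one-sided borders)
satisfies `E = eps_rr + eps_tt` for smooth fields to ~1e-3 and serves as
an in-plane compressibility diagnostic.

Segment averaging uses a reduced AHA 17-segment model: 6/6/4 angular
sectors for basal/mid/apical slices; the apex cap (segment 17) has no
extent on a short-axis slice and is excluded. The anatomical reference
angle is not derivable from an image alone, so it is configuration
(default: first boundary straight up, sectors numbered with increasing
theta). Strain curves accumulate per-interval Eulerian segment means
(fixed segments, no material tracking) starting at zero at end diastole;
the pairing interval between correlated frames is configurable (default
consecutive) because small inter-frame motions (<3 px) are relatively
noisy — coarser pairing trades temporal resolution for accuracy.
Landmarks are advected by adding the bilinearly interpolated instantaneous
displacement per interval; tracks are clipped at the frame with a warning.

## Synthetic validation

The generator reproduces the study conditions: a 512×512 black/white grid
of 23×23 px cells bounded by 8 px white lines (autocorrelation period
31 px), an annular variant standing in for a pre-processed phantom, and
112×112 sinusoidal tag frames with 7 px spacing for the extraction chain.
The analytic deformation `u_r = 0.02 r`, `u_theta = 0.035 r` about
(256, 256) combines a 2% radial dilation with a ~2° rotation — a
simplified model of diastolic relaxation plus torsion; it is affine in
Cartesian coordinates, with corner displacements up to ~14.6 px. Images
are deformed by inverse mapping (fixed-point solve of the source location,
≤20 iterations, 1e-3 px tolerance; bicubic sampling; background fill), so
the deformed image satisfies `I_d(x + d_u, y + d_v) = I_o(x, y)`.

Error metrics: the relative slope error `e_s = |s_true - s_fit| / s_true`
from an OLS fit of the recovered component along the horizontal line
through the flow centre (where both components are exactly linear in `x`
with slopes 0.02 and 0.035); and pixelwise relative errors
`e = |(d_true - d_est)/d_true|`, undefined below 1e-6 px of truth, and
summarized (mean, std) over pixels with at least 3 px of true
displacement. Relative error necessarily blows up near the zero lines of
each component (for the vertical component, along `y = -x/1.75`), which is
why the ≥3 px mask is the meaningful accuracy summary — the package's
tests verify this localization explicitly. A `(C_B, S_B)` sweep re-runs
the full pipeline per combination (deterministic, order-independent).

What this does **not** show: the synthetic grid is noise-free, binary,
periodic and globally affinely deformed; real tMR slices have tag fading,
through-plane motion, anatomy-modulated contrast and non-affine motion.
Accuracy on the synthetic experiment is therefore an upper bound on
real-data accuracy, and the strain pipeline's physiological outputs are
validated here only through closure properties, not against clinical
reference values. No MR physics (k-space, SPAMM fading) is simulated.

## Problem sizes and determinism

The reference validation (512×512, ~1700 vectors, two passes) runs in a
few seconds; the 5×5 acceptance sweep re-runs it 25 times (~2 min). Unit
tests use 96–128 px frames with proportionally scaled boxes (15/31). The
entire pipeline is deterministic — the only randomness in the package is
the optional seeded noise generator, which defaults to off.
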