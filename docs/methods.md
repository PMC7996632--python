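# Methods

This note records the model behind `interiorct`, the numerical choices, the
design of the synthetic study, and what the package's tests do and do not
demonstrate about real data.

## Forward model

The object is a 2D map of linear attenuation µ (cm⁻¹) on a square grid of
square pixels, y up, centered on a stated laboratory position. A circular
fan-beam scan is described by the source–isocenter distance *a*, the
isocenter–detector distance *b* (*c = a + b*), a flat detector of
`n_detector` bins of pitch Δu, `n_views` equally spaced view angles over
360°, an initial angle, an optional lateral detector offset and the
laboratory position of the rotation center. At view angle β the source sits
at `rc + a(cos β, sin β)`; the detector line passes through
`rc − b(cos β, sin β)` with coordinate u increasing along `(−sin β, cos β)`.
The convention is arbitrary but used identically by the projector, the FBP
and the background reprojection, which is all that matters for consistency.

Line integrals are computed ray-driven with bilinear interpolation at a
uniform step of half the image pixel, and divided by 10 so that µ in cm⁻¹
and lengths in mm give dimensionless integrals. The projector is exactly
linear in the image — the compensation identities below rely on this — and
matches the closed-form fan-beam transform of a uniform disk to 0.05 %
(tested) away from the tangent rays.

Optional forward-model stages: Poisson photon noise
(`p → −ln(max(N, 0.5)/I₀)`, `N ~ Poisson(I₀ e^{−p})`), off by default since
the study is about geometry, not dose; and a rectangular focal-spot penumbra
of width `x·b/a` at the detector.

## Reconstruction

Flat-detector fan-beam FBP: rows are rescaled to a virtual detector through
the rotation center (s = u·a/c), pre-weighted by `a/√(a²+s²)`, convolved
with the band-limited ramp via an FFT zero-padded to ≥2× the row length, and
backprojected with the `a²/ℓ²` fan distance weight and linear detector
interpolation; the full 2π redundancy contributes the factor ½. The ramp is
apodized with a Hann window by default (a pure ram-lak is available and used
for the bar-pattern resolution measurement, where apodization would mask the
contrast being measured). Pixels outside the scanned field of view — the
disk around the rotation center that every view's detector covers — receive
structurally incomplete data and are set to zero; leaving them would
contaminate any later reprojection of the image (this is how the background
volume is used below).

On untruncated data the FBP recovers a uniform disk's center to 0.1 % and a
smooth phantom to <2 % RMS relative error; a 90° initial-angle relabeling
rotates the reconstruction exactly on the grid (both tested).

`direct_interior_fbp` demonstrates the truncation failure mode: rows are
extended with their edge value over one detector width before filtering,
which tames the edge blow-up but leaves the cupping and attenuation offset
characteristic of naive interior reconstruction.

## Background compensation

With the object split at the ROI circle, linearity gives
`P_ROI = P_local − trunc(P_background)` once the local window covers the
ROI. The pipeline estimates the background term as follows:

1. reconstruct the global scan (1.024 mm pitch) onto a 0.498 mm grid;
2. zero all pixels inside the ROI circle (radius 23 mm);
3. reproject this background volume along the *assumed* local geometry at a
   coarse sampling (the global pitch, 360 of the 1440 local views, with a
   4 mm detector margin so the next step never extrapolates);
4. interpolate onto the local sampling — cubic along the detector, linear
   along views, exact at coincident samples — and truncate to the local
   window;
5. subtract from the local scan and reconstruct the pure ROI sinogram with
   the same FBP.

The coarse-then-interpolate path is deliberate: the background estimate is
smooth, its residual high-frequency errors largely cancel during
backprojection, and reprojecting at full sampling instead changes the
in-ROI RMSRE by well under one percentage point (tested). With the
background computed exactly (from the phantom raster rather than the global
reconstruction) the compensated reconstruction equals the ROI-only
reconstruction to floating-point precision (tested) — all remaining error
is background *estimation* error.

## Misalignment model

Registration between the scans enters only through the assumed geometry of
step 3, so misalignment is injected exactly there and nowhere else:

* **isocenter offset** — the assumed rotation center shifts along the
  laboratory x-axis;
* **initial-angle offset** — added to the assumed starting angle;
* **magnification error m** — the assumed image-to-detector magnification is
  multiplied by (1+m). Realized by dividing the reprojection sampling pitch
  by (1+m) and labeling the result with the nominal pitch: a background
  feature whose rays truly map to detector coordinate u is subtracted at
  u·(1+m). The direction matters: this choice (and not its inverse) moves
  the background-deficit edge *inward* for m<0, so the accurately
  reconstructed region scales by (1+m) — at m = −20 % the measured accurate
  radius is 18.0 mm ≈ 0.78 × the 23 mm ROI, with a sharp error step at the
  edge (tested). The inverse convention produces only a global shift with no
  shrinkage.

A magnification error leaves a nearly uniform attenuation shift inside the
effective ROI. The **bias correction** removes it additively: the mean over
a known region is forced to its known value. The default reference is the
set of mastoid-like air pockets (2.5 mm radius, eroded by 0.8 mm against
edge blur) that the phantom places well inside the ROI, target 0 cm⁻¹; a
flat-region benchmark from the global reconstruction is the documented
alternative. The correction never changes pixel differences (tested).

## The synthetic head phantom

The phantom replaces a real head slice with analytic primitives in
Hounsfield units, converted by µ = µ_water·(1 + HU/1000), clamped at 0:
soft tissue 40 HU inside a 1500 HU cortical skull ring (outer semi-axes
80×95 mm), a 20 HU ventricle-like region, two air cavities, and a 700 HU
temporal-bone-like disk (radius 14 mm) centered 49 mm lateral of the head
center, containing a 100 HU cochlea-like inclusion, three fixed 2.5 mm air
pockets (the bias reference) and eight seed-jittered fine air cells. Two
resolution bar-pattern groups (horizontal and vertical; four bars, gap =
width) per bar width, 600 HU amplitude, sit on the bone near the ROI
center; defaults 50 and 75 µm. µ_water defaults to 0.2 cm⁻¹, the effective
monoenergetic water attenuation consistent with the metric scales the study
tables use. Tissue HU values are implementer-chosen within clinical ranges.
Rasterization is 2×2-supersampled at pixel centers (4×4 for the bars), so
material boundaries are anti-aliased; the generator is bitwise-deterministic
per seed.

What the phantom does *not* emulate: polychromatic spectra and beam
hardening, scatter, detector cross-talk, anatomical texture, 3D structure.
Passing tests therefore demonstrate the geometry and linear-algebraic
correctness of the compensation under realistic monoenergetic conditions,
not its spectral robustness; on real polychromatic data the linearity of
`P_ROI = P_global − P_background` is only approximate and residual errors
concentrate at the ROI periphery.

## Desk-scale study design

The reference experiment at full scale would need a ~10 000² raster of the
whole head at 0.025 mm. Instead the phantom is represented on two
complementary grids: a 2048² patch at 0.025 mm covering the local-scan disk
(split radius ≈ 24.6 mm around the ROI center) and a 512² full-head grid at
0.498 mm with that disk zeroed. Projection linearity makes every virtual
scan the sum of the two parts' projections, and *all* scans — global, local
and the ground-truth reference — derive from the same composition, so the
representation error cancels in comparisons.

Default scan conditions: both scans at magnification 2 (global:
a = b = 500 mm; local: a = b = 200 mm, rotated about the ROI center); global
detector 1.024 mm pitch, 720 views; local detector 0.11 mm pitch, 1440
views, window radius 35.05 mm; ROI radius 23 mm. The ground truth is the
FBP of an untruncated 0.11 mm-pitch scan about the ROI center, on the same
grid as the evaluated reconstruction (512² at 0.1 mm by default; the bar
patch at 0.025 mm). Metrics (masked SSIM with Gaussian 11×11/σ1.5 window,
PSNR with peak = in-mask reference maximum, MSE, RMSRE with air excluded
below 0.01 cm⁻¹) are evaluated at radius 21 mm, or 16.8 mm for the
magnification sweep where the effective-ROI intersection dictates the
smaller mask. Sweeps: isocenter 0–4.483 mm in 0.498 mm steps (10 runs),
angle −4.39°…4.39° in 1.098° steps (9), magnification −20 %…20 % in 5 %
steps (9). View counts and grid sizes are the package's desk-scale choices
and configurable; everything protocol-level above is fixed by the study
design.

When comparing an FBP reconstruction against the *rasterized* phantom
(rather than against a reference reconstruction), pixels within two pixels
of a material boundary are excluded: the discrepancy there is partial-volume
rasterization, not reconstruction error.

## Numerical choices and degenerate inputs

* Ramp filter from the spatial-domain band-limited kernel (h[0] = 1/(4Δs²),
  odd taps −1/(πnΔs)²) on a power-of-two FFT grid ≥ 2 rows, so the DC
  response is correct and interperiod wrap is negligible.
* Backprojection skips points within 10⁻⁹ cm of the source plane and bins
  outside the filtered row (their true contribution is unknown, not zero —
  hence the FOV mask).
* `trunc` keeps the bins whose centers lie within ±width/2 of the central
  ray (half-open tolerance 10⁻¹²) and rewrites the geometry so kept bins
  retain their physical coordinates.
* Up-sampling clamps detector coordinates to the coarse extent and flags
  extrapolated bins in a returned mask; the background chain sizes its
  margin so the flag never fires in normal runs.
* Zero-count Poisson bins clamp to half a count to keep the log finite.
* The effective-ROI radius estimator walks 0.5 mm rings outward from the
  ROI center and stops where the median absolute relative error (air
  excluded) exceeds 5 % — between the few-percent corrected in-region error
  and the ≥10 % shifts outside the effective region, so the estimate is
  insensitive to the exact threshold.
* Empty masks, non-square grids, short scans (<360°), non-positive
  distances/pitches/intensities and magnification errors ≤ −1 raise
  immediately.

## Known limitations

Monoenergetic, 2D, full-scan only; no scatter, motion or spectral effects;
the direct-interior baseline uses simple edge padding (not a detruncation
model), as it exists to demonstrate the failure mode; absolute metric
values depend on the synthetic phantom and the desk-scale grids and are not
comparable across phantoms — the trends (degradation with misalignment,
rescue by bias correction, effective-ROI scaling) are the reproducible
content.
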