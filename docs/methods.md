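# Methods

## The calibration model

The adaptive threshold TS (percent of the lesion's maximum intensity whose
isocontour recovers the true maximal cross-sectional area) is modelled as

    TS = B0 + B1·A + B2·(1 − 1/TBR) + B3·FWHM + E

with A the maximal cross-sectional area in mm², TBR the target-to-background
ratio measured on the reconstructed image, FWHM the transaxial
post-reconstruction Gaussian filter width in mm, and E a zero-mean error.
The contrast enters through 1 − 1/TBR rather than TBR itself: over the
protocol range TBR ∈ [2.5, 70] this term spans [0.6, 0.986] and linearizes
the strong hyperbolic dependence of TS on contrast. B2 is negative (higher
contrast needs a lower threshold), B3 positive (smoothing depresses the
maximum more than the boundary value, so the threshold must rise), and B1,
when present, is small.

Predictions are clipped to the physical range [1, 100]% and reported both
unrounded and as the nearest-integer percent that an operator would apply.

## The phantom simulator

`petbtv.phantom` emulates a NEMA-IEC-style body phantom in the image
domain. Nine spheres (internal diameters 6.5, 8.1, 10, 13, 17, 22, 28, 37,
57.4 mm) sit in a warm background of 3 kBq/mL: six on a 57.2 mm-radius
coplanar ring, the two micro-spheres and the 57.4 mm sphere on a lower
plane, approximating the physical phantom's supplemental inserts. The
default grid is 128×128 transaxial with 2.7 × 2.7 × 3.3 mm voxels and 55
slices (enough axial extent to house the bottom row); everything is
configurable.

A simulated acquisition is: voxel-center rasterization of the activity
(background b, spheres TBR·b) → isotropic 3D Gaussian blur of FWHM equal to
the scanner's intrinsic resolution (default 6.3 mm, a typical BGO-scanner
transverse resolution at 1 cm) → additive Gaussian noise with per-voxel SD
`noise_coeff · sqrt(activity / ESD)` → 2D transaxial Gaussian post-filter,
slice by slice, with replicate edges (slice totals conserved to ≲0.1% for
background-filled borders). The noise law mimics Poisson counting: variance
proportional to local activity and inversely proportional to the emission
scan duration (ESD, minutes), so ESD moves the *variance* of measured
thresholds but not their mean — which is exactly why the selection rule
should reject it as a predictor, and in our experiments does.

What the simulator does **not** model: scatter, attenuation, randoms,
time-of-flight or PSF reconstruction, sinogram-level noise correlations,
axial mean-filter kernels (carried only as inert covariate labels), lesion
motion, heterogeneous uptake. Passing tests therefore demonstrate the
correctness and internal consistency of the measurement and calibration
machinery under a clean image-formation model, not the clinical accuracy of
any specific scanner's calibration. The standard acquisition grid (9 TBR ×
4 ESD) with one reconstruction yields 324 candidate sphere-observations;
undetectable spheres (peak ≤ BG + 3·SD(BG)) are skipped and counted, which
is what separates theoretical from realized data-point counts.

Seeding: each (TBR, ESD, reconstruction) triple derives its own 31-bit seed
from the master seed through `numpy.random.SeedSequence`, so grids are
reproducible as a whole and per volume.

## Threshold measurement

The background value BG is the mean over six 17 mm-diameter circular ROIs
placed in the background between/around the spheres (default: a ring 30°
offset from the sphere positions at 100 mm radius; positions are
configurable because the physical layout never fixed them). Measured TBR is
the maximum pixel in an ROI encircling the sphere's central cross section
(diameter ID plus a 2-pixel margin) divided by BG.

For each detectable sphere, `find_optimal_ts` contours the central slice at
every threshold 1–100% of the window maximum (1% steps), keeps the
8-connected component containing the maximum, measures area as pixel count
× pixel area, and returns the threshold minimizing |area − true area|, ties
broken toward the larger threshold (on a step edge the area is flat over a
threshold range and any member satisfies the criterion; the largest is a
deterministic choice). The observation is flagged converged when the best
error is under 10 mm² — about 1.4 pixels at the default spacing.

**Numerical caveat (pixelization).** At the clinical 2.7 mm pitch a 4 mm
blur is under-sampled (σ ≈ 0.63 px), the area–threshold curve is a
staircase with plateaus wider than 10 mm², and the recovered TS can sit
several points from the continuum optimum. The oracle-agreement test
therefore rasterizes blurred disks at 0.5 mm, where the search matches an
independent boundary oracle — the blurred-disk profile in closed form (the
mass of an offset 2D Gaussian inside a disk is a noncentral-χ² probability,
itself cross-checked against direct high-resolution numerical convolution)
— within 2 percentage points over ID ∈ {13…37} mm × FWHM ∈ {4…11} mm. This
isolates the search logic from pixelization; in the full pipeline at
2.7 mm, the combination of PSF plus post-filter (total blur ≥ 7 mm) keeps
the staircase fine enough for stable trends.

## Model selection and its rules

Stepwise forward selection, no removal step: at each step the candidate
with the largest F-to-enter (the squared t of the added coefficient) is
admitted if F > 4 **and** it raises the multiple R² by at least 0.01. The
ΔR² rule is applied to the multiple R² (the adjusted R² is reported
separately as goodness of fit). With n in the hundreds-to-thousands the
ΔR² ≥ 0.01 requirement is by far the stronger guard: a pure-noise predictor
passes F > 4 about 5% of the time but essentially never adds 0.01 to R².
F-to-enter (not the final-model F) is used at each addition; ties in F
break by candidate column order; zero-variance or collinear candidates are
skipped. Per-predictor variance shares are recorded at entry: the first
predictor's R² is its "partial R²", later increments are "additional R²".
Standardized coefficients are β_i = B_i · SD(x_i)/SD(y).

Fits are restricted to cross sections larger than 133 mm² (a 13 mm sphere,
roughly twice the scanners' resolution) — below that partial-volume errors
dominate and threshold–area calibration is unreliable.

Reference calibrations for eight scanner models (Discovery ST/STE/600/690,
Biograph Hi-REZ/TRUEV, Gemini XL/TF) ship as package data with their R²,
standardized β, variance shares and cross-validation shrinkage, and can be
applied directly or used as generating truths for synthetic records
(`simulate_records`, which also draws the ESD and iteration-number decoys).

## Validation statistics

*Reliability*: records are split 50/50 at a seed (the proportion was an
open choice; equal halves maximize holdout power), the model is fitted on
the training half, and R²* is the squared Pearson correlation between
holdout predictions and observations. Shrinkage = R² − R²*; below 0.10
counts as reliable; negative values (holdout correlating better than the
training fit) are legitimate and reported as-is.

*Between-scanner comparison*: the coincident-regression-lines test pools
two record sets and compares the fit without any scanner term against one
augmented by a scanner dummy plus dummy×predictor interactions,
F = ΔSS_res / q / MS_res,full. The extra-parameter count q is explicit
(default 3: intercept shift plus two slope shifts for the two-predictor
form); when q exceeds the parameters actually added, the Δdf-consistent
statistic is reported alongside. A helper computes the same F directly from
tabulated SS/MS values.

## Segmentation front-end

`delineate_btv` measures BG from operator-placed ROIs, takes the lesion
window maximum over BG as the measured TBR (error below 1.2 — insufficient
contrast; warning above 70 — outside the calibrated range), predicts TS,
and keeps the 26-connected component above TS% of the window maximum.
The filter FWHM is always a user input — it is a known reconstruction
setting, never estimated from the image. For equations containing the area
term the area is the contour's own maximal cross section, so
`area_model_iteration` solves the fixed point: initialize with the area of
a 50% contour, alternate predict→contour until the area changes by < 1 mm²
(≤ 20 iterations; the best iterate is returned flagged non-converged
otherwise). On noiseless simulated spheres the iteration contracts in a few
steps and the recovered maximal cross sections of the large spheres land
within ~15% of truth — the accuracy floor set by pixel-count areas at
2.7 mm.

## Problem sizes used in the tests

The end-to-end pipeline test runs the full 9 TBR × 4 ESD × 3 FWHM grid
(108 volumes, 972 sphere-observations, ~10 s) at a fixed master seed;
synthetic-record studies use n = 1600 with 20 replicates; the null
behaviour of the coincidence test uses 100 replicates at n = 300 pooled.
These sizes give the selection and reliability statistics comfortable
stability while keeping the whole suite around half a minute.

## Known limitations

- Pixel-count areas (no sub-pixel contouring) bound the achievable area
  accuracy at coarse voxel pitches; the 10 mm² convergence criterion may be
  unattainable there even for a perfect image.
- The detectability rule (peak > BG + 3·SD) is an automated proxy for the
  visual assessment an operator would perform; its multiplier is a knob.
- The simulator's Gaussian image-domain model cannot reproduce
  scanner-specific contrast-recovery differences, so shipped reference
  equations are data, not something the simulator can re-derive.
- Thresholding assumes near-uniform uptake; heterogeneous lesions are out
  of scope.
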