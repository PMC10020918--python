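# Methods

This note records the models, conventions and numerical choices behind
`pseudodxa`, the open design decisions we had to settle, and what the
synthetic-data tests do and do not demonstrate about real data.

## Geometry and conventions

All volumes are isotropic 3D arrays indexed `(z, y, x)`: `z` is the
anterior–posterior (projection) axis once the neck is aligned, `y` runs
superior→inferior, `x` along the femoral-neck axis. Anisotropic inputs are
rejected rather than resampled, because the pipeline's currency is the voxel
count and resampling would silently change it. Indexing is 0-based and
half-open; mm→voxel conversions round half-to-even (so the standard 15 mm
slab at 0.027 mm voxels is 556 slices), and the rounding rule is recorded in
the output metadata.

Anteversion removal is a rotation in the axial `(z, x)` plane about the
vertical axis, default 15°, nearest-neighbour for label volumes (labels stay
in {0, 1, 2}) and trilinear for gray volumes. The VOI is a 15-mm slab
perpendicular to the neck axis whose anchor — the inflection point between
the superior neck contour and the greater trochanter — is a user-supplied
landmark; landmark placement is inherently manual, so the automated locator
in `voi.find_neck_anchor` is explicitly a heuristic for phantoms and smoke
tests, not a validated method. The ROI's superior–inferior extent
(`roi_height_mm`) is a free parameter: no numeric value for the scanner ROI
height is standardised.

## Hounsfield calibration

The two-point affine map anchored at the in-scan air (−1000 HU) and water
(0 HU) phantom means fully determines the conversion; the hydroxyapatite
mimicker is carried only as a QC readout, never as a third anchor. The map
is monotone and affine, so threshold-based segmentation commutes with it.

## Segmentation and the endosteal boundary

Bone/background segmentation is a global threshold (fixed HU or Otsu). This
is a deliberately deterministic substitute for learned segmentation; when a
label volume from a better segmenter exists, the pipeline consumes it
directly, and sparse voxel patch lists stand in for interactive correction.

The cortical/trabecular boundary is built per cross-sectional slice
(perpendicular to the neck axis):

1. periosteal envelope = hole-filled morphological closing of the bone mask;
2. marrow = periosteal ∖ bone;
3. subendosteal interior = hole-filled closing of the marrow, clipped to the
   periosteal envelope;
4. bone inside the subendosteal interior is trabecular, the rest cortical.

Closing the **marrow** rather than tracing bone connectivity is the load-
bearing choice: trabeculae that touch the cortex (most do) would otherwise
be claimed by the cortical compartment wholesale. The closing radius
(default 0.5 mm) sets the largest marrow gap the construction can bridge;
it must exceed roughly half the trabecular spacing and stay below the
thinnest cortex of interest. The partition is exhaustive and exclusive by
construction — `cortical + trabecular = bone`, exactly, always. On rod
phantoms with cortex-touching trabeculae the cortical Dice against ground
truth exceeds 0.95 with disagreement confined to within ~1 voxel of the
endosteal surface; on phantoms whose trabecular features are thick relative
to the closing radius, cortex-merged trabeculae are mislabelled cortical and
BV/TV biases low (quantified in `examples/03_morphometry.py`). The recorded
subendosteal region doubles as the BV/TV denominator.

## Pseudo-DXA projection

The projection is parallel voxel stacking along the ray axis — no divergent
beam, attenuation, scatter, marrow or soft tissue; those physics are out of
scope, and the voxel count is the measurand. Pixel size equals voxel size
(no rebinning), so all counts are integers and three identities hold exactly
and are asserted in tests: per-label count conservation, the
superior+inferior partition of BMC, and BMD = BMC/area.

Two interpretation choices:

* **Area** is the area of pixels containing ≥1 projected bone voxel, not the
  fixed ROI box — projected area must track neck width, which a constant box
  cannot do.
* **Midline** is the geometric midline of the image, `(H+1)//2`, with the
  superior half taking the extra row when the height is odd.

Column-wise widths (superior–inferior bone extent per column) give the
average and minimum femoral-neck width; bone-free columns are excluded with
a warning.

## Morphometry

BV/TV = trabecular voxels / subendosteal voxels. Tt.Ar and Ct.Ar are
per-slice voxel-count areas averaged along the slab (no subvoxel
contouring). Tb.Th and Ct.Th are means of the largest-inscribed-sphere local
thickness over the respective compartment.

The local-thickness map deserves its numerical note. Sphere centres
restricted to the voxel lattice systematically miss the medial plane of
even-width structures (a plate of 10 voxels admits no voxel-centred sphere
of diameter 10), which both biases the estimate and makes it oscillate with
resolution parity. We therefore supersample the mask ×2 so surfaces land on
sub-voxel boundaries, compute the Euclidean distance transform there, paint
spheres in decreasing radius order (radius binned to half fine-voxels;
painted radius carries the half-voxel surface offset, the recorded diameter
the matching lattice correction), and block-average back. The result is
exact on plates of any integer width, within ~¼ voxel on thin curved
shells, and changes by ≲0.1% under a further resolution doubling on the
test cylinder. Empty compartments yield NaN, never 0.

## Mechanics

Curves are trimmed at the 100 N seating preload (linear interpolation of
the crossing, displacement re-zeroed there). Fixture-compliance correction
subtracts a constant deflection scaled by load above the preload; it
defaults off because measured fixture deflection is ~1% of total
displacement.

Stiffness is the least-squares slope over a load-fraction window of the
rising limb. The window is not standardised anywhere we know of, so the
default is the 20–80% band of pre-maximum load, refined to the 0.4-wide
sub-window (0.05 steps) maximising R²; on a clean elastic limb every
sub-window agrees, and the chosen range is reported. The yield line has
slope 0.9 K. Where it is anchored is genuinely open; we default to the most
literal reading — it shares the stiffness regression's own intercept — with
`anchor="window_start"` available as the alternative. Yield is the first
crossing of that line with the measured curve beyond the fit range (linear
interpolation between samples); a curve that never softens gets yield pinned
at maximum load and a flag, never a fabricated crossing. Failure, the PYD
endpoint, is the first sample after the maximum where load drops below 50%
of maximum (configurable), else the last sample. Scaling invariants
(load × c, displacement × c) hold exactly and are property-tested.

## Statistics

* **Normality gate**: Shapiro–Wilk at α = 0.05; if it fails, try log then
  √, keep the first that passes, else the better of the two, recording the
  tag. Log body weight and √PYD are hard-wired defaults for those two
  variables — fidelity to the established analysis beats automation.
* **Narrow/wide split**: median split on pseudo-DXA area (no height
  adjustment), ties broken by specimen id, odd cohorts give the median
  specimen to narrow. Deterministic and row-order invariant.
* **Regression ladder**, outcome = maximum load: model 1 {age, log BW,
  BMD}; model 2 swaps BMD for {area, BMC}; model 3 swaps BMC for the
  superior/inferior totals; model 4 splits those into cortical/trabecular
  counts; model 5 adds √PYD. Standardized betas are b·sd(x)/sd(y); adjusted
  R² = 1 − (1 − R²)(n − 1)/(n − p − 1). Models are fitted on the full
  predictor set with the VIF table reported alongside (pruned refits are
  opt-in via `prune=True`), because collinearity diagnostics and the model
  of record are different questions. Rows missing a model's variables are
  dropped listwise per model, so a specimen lacking strength data
  participates everywhere else.
* **VIF pruning**: VIF_j = 1/(1 − R²_j) from auxiliary regressions;
  iteratively drop the max-VIF predictor while any VIF ≥ 10. Terminates in
  ≤ p − 1 steps; the retained set's VIFs are below the cap by construction.
* **ICC(3,1)** (two-way mixed, consistency, single rater):
  (MSR − MSE)/(MSR + (k − 1)MSE), CI via the F distribution, reliability
  category (poor/moderate/good/excellent at 0.5/0.75/0.9) assigned from the
  CI lower bound.
* **ANCOVA**: slope test = F on the group×x interaction; intercept test = F
  on group in the common-slope model, interpretable when slopes are
  homogeneous. Noise-free degenerate designs resolve to p = 1 (no effect)
  or p = 0 (exact effect) rather than NaN.
* **Sensitivity analysis**: after ranking by area, drop the m/2 largest
  narrow and m/2 smallest wide specimens (m ∈ {0, 4, 8, 12} by default) and
  refit the ladder, testing whether conclusions hinge on boundary
  assignments.
* Group comparisons are two-sided t-tests, equal-variance by default with
  Welch behind a flag; significance vocabulary (p < 0.05, borderline
  0.05–0.08) is interpretation, not computation, and is left to the caller.

## Synthetic data: what it emulates and what it does not

The phantom is a neck-like tube: an elliptic-annulus cortical shell whose
thickness varies linearly from the superior to the inferior pole, a
trabecular interior realised by thresholding a smoothed Gaussian random
field at the quantile that hits the target BV/TV (exact to one voxel), an
optional hourglass waist for the width measures, and an optional baked-in
anteversion. Truth records carry exact per-label and per-half counts,
analytic mean cortical thickness, widths, and the interior mask. The
trabecular field emulates scale and volume fraction, not the oriented
arcades of a real neck; the shell has no porosity; there is no marrow or
noise texture unless the grayscale rendition is used.

Load curves are bilinear with Gaussian load noise; the truth yield is the
closed-form intersection of the 0.9 K line with the second limb, and
failure before the slope break flags an elastic-brittle record with PYD 0.

Cohorts draw standardized predictor scores from a specified correlation
matrix (default: uniform 0.15 off-diagonal), map them to natural scales
chosen to be realistic for an elderly female donor cohort (age ~67 ± 17 y
clipped to 36–95, weight ~67 ± 24 kg, area ~4.63 ± 0.25 cm², BMC
~1.3×10⁸ voxels, regional shares of BMC centred on superior-cortical
20.1% / superior-trabecular 18.7% / inferior-cortical 36.3% /
inferior-trabecular 24.8%), and build strength as the stated standardized
effects plus residual noise sized so the outcome has unit generating
variance (so the requested betas *are* the true standardized betas;
`noise_fraction=0` gives a deterministic outcome). Clipping to plausible
ranges slightly attenuates tail observations; at n = 200 the measured
effect on beta recovery is within the tested ±0.1 and on CI coverage within
Monte-Carlo error. Passing tests on these cohorts demonstrates the
estimator machinery, not the biology: real cohorts have nonlinear
covariate relations, measurement error and missingness patterns the
generator does not emulate.

All generators are seed-deterministic and version-stamped.

## Problem sizes in the test and acceptance suites

Conservation checks use 100 random 20³–64³ label volumes; phantom-recovery
checks use 8–12 mm phantoms at 0.1–0.25 mm voxels (≈1–2 M voxels); ladder
recovery uses n = 200 cohorts, 25 replicates for recovery and 500 for CI
coverage. These sizes make every identity and tolerance measurable while a
full suite run completes in a few minutes on one core.

## Known limitations

* The morphological endosteal boundary under-assigns trabecular bone when
  trabecular features are thick relative to the closing radius; it is a
  declared substitute for learned or manual segmentation, not a replication
  of it.
* Ct.Th averages local thickness over all cortical voxels, which weights the
  thicker cortex by its larger volume; a surface-weighted mean would differ
  on strongly asymmetric shells.
* The projection ignores attenuation physics entirely; agreement with real
  DXA output is an empirical question outside what phantoms can establish.
* `find_neck_anchor` is a convenience heuristic; real analyses should supply
  landmarks.
* The statistics half assumes a complete cohort CSV; only per-variable
  missingness with listwise deletion is handled.
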