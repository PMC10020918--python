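# pseudodxa

Projection densitometry of the femoral neck: turn 3D labelled CT volumes of
the proximal femur into the 2D bone-mineral maps a clinical hip DXA scanner
would see, measure the underlying cortical/trabecular structure and
whole-bone mechanics, and ask how density, structure and strength relate —
separately for narrow and wide femoral necks.

## The problem

Hip fracture risk is screened with areal bone mineral density (BMD) from a
DXA scan of the femoral neck, yet BMD identifies only about half of the
people who go on to fracture. BMD is a heavy reduction of a 3D structure: a
projection onto a plane, then a ratio of two scalars,

    BMD = BMC / area,

where BMC (bone mineral content) measures the amount of bone and area the
projected bone outline. Very different arrangements of cortical shell and
trabecular lattice can produce the same BMD but very different strengths.
This package implements a research pipeline for studying that degeneracy
with high-resolution CT, where the projection can be done voxel by voxel and
every projected count can be traced back to labelled cortical or trabecular
bone:

1. **Volume I/O and calibration** (`volume_io`) — NIfTI / TIFF-stack /
   MHD readers for isotropic volumes; two-point Hounsfield calibration from
   in-scan air and water phantoms.
2. **VOI extraction** (`voi`) — derotation to remove femoral anteversion
   (default 15°) and extraction of the 15-mm neck slab anchored at the
   superior neck–trochanter inflection.
3. **Segmentation** (`segmentation`) — threshold bone/background
   segmentation (fixed HU or Otsu) and a deterministic morphological
   endosteal-boundary construction splitting bone into cortical and
   trabecular compartments; external label volumes bypass both.
4. **Pseudo-DXA projection** (`projection`) — parallel projection of bone
   voxels into per-pixel count maps; area, BMC (voxel count), BMD
   (voxels/cm²), femoral-neck widths, and superior/inferior ×
   cortical/trabecular regional counts. Conservation (Σ pixel counts =
   voxel counts, per label) holds exactly.
5. **Morphometry** (`morphometry`) — BV/TV, Tb.Th, Ct.Th (inscribed-sphere
   local thickness), Tt.Ar, Ct.Ar.
6. **Mechanics** (`mechanics`) — stiffness, yield point by the
   10%-stiffness-reduction rule (the yield line has slope 0.9 K and the
   elastic fit's intercept), maximum load, and post-yield displacement from
   sideways-fall load–displacement curves.
7. **Statistics** (`stats`) — Shapiro–Wilk-gated transforms (log body
   weight, √PYD), bivariate fits, ANCOVA, ICC(3,1), the narrow/wide median
   split by pseudo-DXA area, a five-model regression ladder predicting
   strength with standardized betas and iterative VIF (<10) pruning, and a
   middle-exclusion sensitivity analysis.
8. **Synthetic data** (`synthetic`) — seeded generators for neck phantoms
   (elliptic cortical shell, thicker inferiorly; thresholded Gaussian-field
   trabecular interior hitting a target BV/TV), bilinear load curves with
   analytic yield truth, and cohort tables with known standardized effects —
   so every stage is testable without cadaveric data.
9. **Pipeline + CLI** (`pipeline`, `cli`) — manifest-driven end-to-end runs
   with per-sample fault isolation and bit-reproducible CSV outputs;
   `pseudodxa run|project|morpho|mech|stats|synth`.

## Worked example

`examples/01_project_phantom.py` builds a 12-mm neck phantom (1 mm superior /
3 mm inferior cortex, 30% trabecular volume fraction, 0.25 mm voxels) and
projects it:

```
pseudo-DXA area : 1.800 cm^2
pseudo-DXA BMC  : 72960 bone voxels
pseudo-DXA BMD  : 40,533 voxels/cm^2
FN width        : avg 12.00 mm, min 12.00 mm
superior share  : 44.9% of BMC
cortical share  : 79.3% of BMC
```

Area is the bone-containing pixel area (hence it tracks neck width), BMC the
total projected voxel count, and BMD their ratio. The superior half holds
less bone than the inferior half because the inferior cortex is thicker —
the same asymmetry seen in real femoral necks. `examples/02_mechanics_curve.py`
recovers stiffness 2000.9 N/mm, yield 2027.4 N and PYD 2.879 mm from a noisy
bilinear curve whose analytic truth is 2000 N/mm / 2025 N / 2.875 mm, and
`examples/04_cohort_regression.py` runs the narrow/wide regression ladder on
a synthetic cohort. The other examples cover morphometry (including an
honest comparison of the morphological partition against ground-truth
labels) and the full manifest-driven pipeline.

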