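# Methods

## Pipeline overview

Input is a single-series stack of axial PET DICOM slices. Stages:

1. **Series reading** (`dicom_io`). Slices are ordered by physical
   location, rescale slope/intercept applied, and SUV calibration read
   from the patient-weight and radiopharmaceutical-dose tags. SUV follows
   the mass-based convention
   `SUV = concentration (mCi/kg) · weight (kg) / injected activity (mCi)`;
   whether a scanner reported Bq/mL converted at density 1 g/mL is
   scanner-specific, so the unit convention is a documented assumption
   rather than a conversion the package performs. Decay correction is
   assumed already applied by the scanner. Missing calibration tags
   degrade gracefully: raw activity stays readable, SUV-dependent stages
   refuse with a clear error.
2. **VOI detection**. The seed is the global SUV argmax; nodules with
   SUVmax < 2.5 are out of the method's scope and rejected. The VOI is the
   bounding box of the 26-connected component of {SUV ≥ 2.5} containing
   the seed, padded 5 mm in-plane. The padding is deliberately not applied
   axially: slices beyond the supra-threshold extent carry no nodule
   signal, and per-slice normalisation would amplify their noise into
   spurious contours. A manual per-nodule box (CSV) can override the
   automatic VOI, mirroring clinical workflows where the rectangle is
   drawn by hand.
3. **Contour transform** (`contours`). Each VOI slice is resampled to an
   isotropic 1 mm grid (bilinear; output side = physical extent rounded
   half-away-from-zero, so 192 px × 3.6458 mm → 700 px), then min–max
   normalised per slice. A constant slice maps to all zeros (a flat slice
   carries no contours). Two renderers exist: the *literal* one quantises
   to 8 bits, ORs with a matrix of ones and composites black ink over
   white (`gray = 255 − (round(255·v) | 1)`) — setting the least
   significant bit merges adjacent intensity pairs, which produces the
   banded topographic look; the *explicit* one additionally darkens the
   boundaries of the superlevel sets at the configured levels. Feature
   extraction never reads rendered pixels; it uses the superlevel-set
   tree directly, because the features are defined on contour structure,
   not on PNG bytes.
4. **Contour tree**. Components of {v ≥ k/L}, k = 1..L−1, restricted to
   the VOI, 8-connected. A component identical to its parent's pixel set
   is merged into it, so edges always mean strict containment and the
   tree counts *visible* contours rather than raw threshold crossings.
   L = 8 by default: enough to resolve high-degree nesting while robust
   to noise; configurable.
5. **Features** (`features`), measured across the per-slice trees:
   - *Nesting degree*: the longest root-to-leaf containment chain,
     maximum over slices.
   - *Shape change*: mean over consecutive slice pairs of 1 − Jaccard
     overlap of the outer contours (the root component containing each
     slice's maximum), after integer centroid alignment. Alignment makes
     the measure invariant to rigid in-plane displacement — respiratory
     motion moves the structure without distorting it, and the feature is
     designed not to see that.
   - *Maximum-uptake shift*: the largest consecutive-slice jump of the
     maximum-emission location, divided by the nodule equivalent radius
     √(max outer area/π). The location is the centroid of the most
     nested contour containing the hottest pixel — the "white dot"
     region — rather than the raw argmax pixel, which makes it stable
     under noise while agreeing with the argmax within about a pixel on
     clean unimodal slices.
   - *Enclosing-contour size*: the largest area (mm², 1 mm² per pixel) of
     the contour directly surrounding the maximum emission.
6. **Ordinal binning**. The features were originally scored visually;
   the quantitative proxies are binned onto the same scales so manual
   tables and automated extraction are interchangeable. Defaults, frozen
   in `BinningConfig`: nesting 0–1→1, 2→2, 3→3, ≥4→4; shape change
   <0.15→1, <0.35→2, else 3; shift <0.2→1, <0.5→2, else 3; size by
   cohort terciles (small/medium/large is inherently relative), with a
   fixed-threshold option for single-nodule runs. Aggregation across
   slices is max for nesting/shift/size ("highest degree", "largest
   size") and mean for shape change (robust to one noisy pair). A nodule
   with fewer than two usable slices gets score 1 on the two
   between-slice features, with a warning.
7. **Ranking** (`ordering`). Weights (0.6, 0.3, 0.05, 0.05) are fixed a
   priori, reflecting the informative richness of the variables. The
   pattern object takes the scale maximum on each stimulant variable; the
   neutral variable (size) has no preferred direction, so its pattern
   value defaults to the scale midpoint 2 while its weight is retained.
   GDM2 distances are computed in the context of the analysed cohort plus
   the pattern object (a switch excludes the pattern from the reference
   sums; both conventions are defensible and the default keeps it in).
   GDM2 is already bounded in [0, 1], so no rescaling is applied
   afterwards. The sorted synthetic variable is cut at its three largest
   consecutive gaps; boundary values are gap midpoints and exact ties
   resolve toward the smaller index, making the grouping deterministic.
   d ≤ 0.4 (boundary inclusive) flags expected malignancy. Reported
   percentages round half away from zero to one decimal.

## Numerical choices

- GDM2 is evaluated vectorised (sign tensor + einsum); identical profiles
  are forced to exactly 0 to avoid float residue. A degenerate context
  (all objects tied on every variable) yields 0 for identical profiles
  and a explicit error otherwise. The test suite holds an independent
  literal triple-loop implementation and checks agreement to 1e-12 on the
  exhaustive 108-profile grid and on 1,000 random cohorts.
- Whether GDM2 distances from the pattern decrease monotonically with
  dominance on all stimulant variables is context-dependent and not
  asserted; the ranking relies only on the computed distances.
- Resampling uses `skimage.transform.resize` order 1 with physical-extent
  rounding; mean intensity is preserved within 1% for smooth fields.
- Coordinates are 0-based (row, col) voxel indices with pixel centres on
  the mm grid after resampling.

## The phantom generator

A phantom is a uniform lung background (0.6 activity units) plus one
nodule of 1–5 Gaussian foci; voxel value = background + Σ foci + Gaussian
noise (σ = 0.03), clipped at 0. Each focus has an in-plane Gaussian
profile, a Gaussian axial envelope (default width radius/2, optionally
narrower and axially offset per focus so foci can peak on different
slices), and linear per-slice drifts of position and amplitude. Nodule
diameter is constrained to the 10–30 mm solitary-nodule definition;
validation rejects foci placed or drifting outside the nodule radius.
Injected activity is set so the hottest voxel maps to a target SUVmax.
DICOM output is one minimal single-frame PET file per slice with rescale
chosen to span the 16-bit range; write→read round-trips within one
rescale step.

The frozen cohort regimes (`regimes.py`) encode the dichotomy the method
exploits: malignant-like nodules carry 4–5 foci with at least three
stacked amplitude levels (successive decay 0.5–0.8), σ 2.5–3.5 mm,
position drift up to 3 mm/slice, amplitude drift 15–35 %/slice and short
axial envelopes at varied offsets — metabolically heterogeneous lesions
whose contour structure shifts from slice to slice. Benign-like nodules
have a single stable focus (σ 4–6 mm, negligible drift). SUVmax ranges
are 5–12 and 3.5–5 respectively; all nodules clear the 2.5 inclusion
threshold. A 14×64×64 grid at 3.0 mm in-plane spacing and 3.3 mm slice
thickness keeps full-cohort runs to seconds while matching clinical slice
geometry; the acceptance script and tests run 69-phantom cohorts at this
size.

What the phantoms do **not** emulate: attenuation/scatter, Poisson
counting statistics (noise is additive Gaussian by design), respiratory
motion, CT companion series, and — importantly — any structure hotter
than the nodule itself. In clinical slices the mediastinum or chest wall
often sets the slice maximum, so the nodule's normalised peak lands in an
intermediate level band and the nesting degree varies between nodules. In
the phantoms the nodule peak always normalises to 1, so nesting saturates
at its scale ceiling for every phantom and the synthetic-label recovery
is carried by the shape-change and shift features. Passing the end-to-end
tests therefore demonstrates that the transform, features and ranking
discriminate heterogeneous from homogeneous uptake structure — not that
the nesting feature alone separates clinical classes.

## Known limitations

- Per-slice min–max normalisation ties the contour structure to the
  hottest in-slice structure; a VOI- or cohort-level normalisation switch
  exists but is off by default.
- The feature thresholds binning continuous measurements onto the visual
  scales are declared defaults, not clinically validated cut-points.
- The 0.4 decision threshold and the group semantics come from a specific
  69-nodule cohort; on other cohorts the maximum-gradient boundaries
  adapt, but 0.4 is a fixed convention.
- GDM2 is context-dependent: adding or removing nodules changes every
  distance. Cross-cohort comparison of raw distances is not meaningful.
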