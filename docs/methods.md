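# Methods

## Coordinate and data conventions

Masks live on a `(z, y, x)` lattice — axis 0 cranial–caudal (CC), axis 1
anterior–posterior (AP), axis 2 left–right (LR) — with spacing given as
`(sx, sy, sz)` in mm/voxel. Physical positions are voxel centers,
0-indexed, converted to mm by index × spacing. NIfTI input is reoriented
to the closest RAS+ frame at load, so signed displacement metrics have one
unambiguous convention regardless of how a file was stored; any nonzero
stored value is binarized to 1. Anisotropic in-plane spacing is accepted
throughout: all in-plane moments are computed in mm, so the ellipse fit
stays geometry-correct even though typical acquisitions are isotropic
in-plane (≈1 mm, with 5 mm slices).

`.nii.gz` output is written with a zeroed gzip timestamp so that identical
masks produce byte-identical files; this is what makes the cohort
generator reproducible at the byte level.

## Equivalent-ellipse fit

Each axial slice's foreground is treated as N unit masses at pixel
centers. We use *central* second moments (coordinates relative to the
slice centroid): the inertia-ellipse construction is only
position-independent in that frame, and it makes a lesion's fit invariant
under translation within the image, which the tests pin exactly. The
half-axes are

    a, b = sqrt( 2[(A+B) ± sqrt((A−B)² + 4H²)] / N )

The normalizer is the pixel count N, with A, B, H in mm²·count, so a and b
come out in mm under any spacing; an ideal uniform ellipse returns its own
semi-axes exactly (its second moment about a principal axis is N·axis²/4),
which the recovery property tests guard.

Orientation is taken from the principal eigenvector of the scatter matrix
`[[A, H], [H, B]]` rather than from the explicit slope formulas
`k, l = [(A−B) ± sqrt((A−B)²+4H²)] / 2H`: the eigen route is algebraically
identical where the slopes are defined but has no H → 0 singularity, and it
degrades gracefully to the axis-aligned limit. The long-axis angle φ₁ is
reported in degrees in (−90°, 90°] measured from the +x (LR) axis; a
rotationally symmetric slice (a = b within 10⁻⁹ relative) reports φ₁ = 0
by convention. Slices with fewer than 3 pixels or collinear foreground are
flagged `degenerate` (a, b may be 0) but still participate in volume
integration. When a slice holds several connected components, all pixels
are pooled into one point system — that is what the moment formulation
prescribes — and a warning is logged, since a multi-focal slice's single
ellipse is a coarse summary.

## Volume integration

Between adjacent occupied slices the lesion is modeled as a truncated
elliptical cone; the frustum volume

    V = (π h / 6) (2(a₁b₁ + a₂b₂) + a₁b₂ + b₁a₂)

interpolates the cross-section area linearly in both semi-axes and reduces
exactly to the circular frustum, the elliptical cylinder and the cone in
the corresponding limits (unit tests assert all three). Design choices at
the edges of the model:

* **Single-slice lesions.** The frustum sum is empty for a one-slice
  lesion; it contributes π·a·b·h (a one-slice-thick elliptical cylinder),
  so tiny lesions have nonzero volume, consistent with the voxel baseline
  attributing h mm of tissue to a slice.
* **Axial gaps.** Masks whose foreground skips slices are split into
  contiguous runs, integrated independently and summed, with a warning; we
  do not interpolate across gaps.
* **No end-cap extrapolation.** Integration runs between the outermost
  occupied slice centers. On an n-slice cylinder ETECIM is therefore
  exactly (n−1)/n of the voxel sum; this is a property of the model, not a
  defect to be corrected, and it is documented and tested rather than
  patched.
* **Degenerate fits inside a run** stay in the frustum chain and
  contribute through the cone-limit terms, keeping the estimator
  deterministic and mechanical.

RECIST-style diameters are read off the fitted stack: longest = max 2a
over slices, shortest = min 2b, ties to the lowest slice index.

## Overlap metrics

Surfaces are the 6-neighborhood boundary voxels (foreground voxels with a
face-adjacent background neighbor; outside the lattice counts as
background) — deterministic, resolution-native, and standard for
segmentation evaluation; no sub-voxel meshing is attempted. Distances are
Euclidean between voxel centers in mm. HD is the full max-of-max Hausdorff
(not HD95); MSD is the symmetrized average of the two directed mean
distances. Overlap metrics are exact count arithmetic, and two identities
hold by construction and are asserted on every tested pair:
DSC = 2·CI/(1+CI) and 1/CI = 1/DI₁ + 1/DI₂ − 1. The center of mass is the
unweighted mean of foreground voxel centers; displacements are signed,
predicted minus ground truth, so one-sample t-tests against 0 detect
directional placement bias. Empty-input cases raise or flag (`None`)
rather than returning 0 — a silent 0 mm Hausdorff distance from an empty
pair would corrupt cohort summaries.

## Statistics

Pearson r (two-sided p from the t-distribution, n−2 df), paired t
(on y − x, n−1 df), one-sample t, and descriptive summaries (mean, sample
SD with n−1, median, quartiles by linear interpolation between order
statistics — one fixed convention; we do not chase any particular
software's quantile variant). Degenerate-variance inputs raise instead of
yielding NaN. The calibration line is OLS of predicted on ground truth,
matching the scatter-plot orientation of predicted-vs-manual GTV, and is
inverted algebraically to recover a ground-truth estimate from a
prediction. The cohort driver flags (rather than propagates) degenerate
tests, and excluded rows — unreadable files, geometry mismatches — are
counted and listed, never dropped silently.

## Phantoms: what they emulate, and what they do not

Phantoms are rasterized by center inclusion (a voxel is foreground iff its
center is inside the analytic solid), unbiased to first order in spacing.
Defaults mimic a PET/CT axial stack — (0.98, 0.98, 5) mm spacing, lesions
spanning 3–15 slices — and the cohort generator draws spindle-shaped
elliptical tubes (tapered ends, drifting orientation, jittered centers)
with perturbed copies standing in for automatic segmentations:
integer-voxel translation, one round of 6-neighborhood dilation or
erosion, and independent flips of boundary-band voxels (both the inner
surface and the adjacent outer shell, so the noise does not systematically
shrink or grow the lesion). Every phantom carries its analytic volume and
per-slice ellipse parameters; for tubes the reference volume is the
frustum chain through the analytic semi-axes, i.e. the quantity the
estimator targets, so discrepancies isolate rasterization error.

Passing on phantoms demonstrates geometric and statistical correctness of
the pipeline, not clinical performance: real lesions are not elliptical in
cross-section, real segmentation errors are spatially correlated rather
than independent boundary flips, and real cohorts carry acquisition
variability none of which is simulated. Cohort-level numbers on synthetic
data (DSC, R², calibration slopes) characterize the generator's error
profile, not any segmentation model.

## Numerical choices and problem sizes

* Isotropy tie-break at sqrt((A−B)²+4H²) ≤ 10⁻⁹(A+B); negative rounding
  residue under the b radical is clamped to 0.
* Frustum inputs must be ≥ 0 and h > 0; violations raise immediately.
* Statistical equivalence to textbook closed forms is asserted at 10⁻¹⁰
  absolute; geometric recovery tolerances (3 % axes, 3° angle, 8 %
  ellipsoid volume) reflect rasterization error at ~1 mm pixels, measured
  on the property tests' phantom ranges.
* The default synthetic cohort used by the test suite and the acceptance
  script is 164 patients on a (24, 96, 96) lattice — large enough for
  stable pooled statistics and 4-fold blocks of 41 while the whole
  pipeline stays in seconds.

## Known limitations

* DICOM / DICOM-RT structure sets are not parsed; masks are NIfTI-1 only.
* The equivalent ellipse pools multi-focal slices into one shape.
* ETECIM's no-end-cap convention biases volumes of blunt-ended lesions
  low by roughly half a slice at each end; conversely voxel summation
  biases high.
* HD95 and other robust surface-distance variants are deliberately out of
  scope; only the full Hausdorff is provided.
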