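# etecim

Gross tumor volume (GTV) estimation from 3-D binary segmentation masks by
the **equivalent truncated elliptical cone integral method (ETECIM)**,
together with the comparative-assessment suite used to validate automatic
tumor segmentations: overlap metrics (DSC, Hausdorff distance, mean
surface distance, conformity index, degree of inclusion, center-of-mass
motion vector) and cohort-level statistics (Pearson correlation, paired
and one-sample t-tests, quartile summaries, and a linear calibration that
maps predicted GTV back to a ground-truth estimate).

The intended users are medical-image-analysis researchers and radiotherapy
physicists who have paired predicted / manually-delineated tumor masks
(e.g. from a PET/CT segmentation model for esophageal carcinoma) and want
reproducible volumetry and agreement statistics without clinical data in
the loop: a synthetic phantom module generates lesions with exactly known
geometry for testing every step.

## The method

The common GTV baseline — foreground voxel count × voxel volume —
systematically overestimates, because every boundary voxel is counted
whole. ETECIM instead summarizes each axial slice's lesion by its
*equivalent (inertia) ellipse*: with the foreground treated as N unit
masses at pixel centers and central second moments
A = Σ(xᵢ−x̄)², B = Σ(yᵢ−ȳ)², H = Σ(xᵢ−x̄)(yᵢ−ȳ), the half-axes are

    a = sqrt( 2[(A+B) + sqrt((A−B)² + 4H²)] / N )
    b = sqrt( 2[(A+B) − sqrt((A−B)² + 4H²)] / N )

with orientation from the principal eigen-direction of [[A, H], [H, B]].
The tissue between adjacent slice centers (spacing h) is modeled as a
truncated elliptical cone:

    V = (π h / 6) · ( 2(aᵢbᵢ + aᵢ₊₁bᵢ₊₁) + aᵢbᵢ₊₁ + bᵢaᵢ₊₁ )

and the GTV is the sum of these frusta from the cranial to the caudal
slice. On an ideal ellipse the moment fit recovers the true semi-axes
exactly, and on a cylinder the frustum chain is exact, sitting a factor
(n−1)/n below the voxel sum — the overcount the baseline suffers.

## Worked example

```bash
python examples/estimate_volume.py
```

```
analytic ellipsoid volume :    18849.6 mm^3
ETECIM estimate           :    18634.4 mm^3 (-1.1%)
voxel-summation estimate  :    19120.0 mm^3 (+1.4%)
```

A rasterized ellipsoid with semi-axes (15, 10, 30) mm on a (1, 1, 5) mm
grid has analytic volume 4/3·π·15·10·30 ≈ 18 849.6 mm³. ETECIM lands 1.1 %
below it (it integrates between the outermost slice *centers*), while the
voxel sum overshoots. The other examples cover ellipse fitting and RECIST
diameters (`fit_ellipses.py`), the overlap report on a perturbed pair
(`compare_masks.py`), cohort statistics with calibration
(`cohort_analysis.py`), and phantom generation (`make_phantom.py`).

Everything is also reachable from a shell via the `etecim` command:

```bash
etecim phantom --shape ellipsoid --out lesion.nii.gz
etecim volume lesion.nii.gz --method etecim
etecim compare pred.nii.gz gt.nii.gz
etecim cohort manifest.csv --out report.json
```

Masks are NIfTI-1 (`.nii` / `.nii.gz`); cohort manifests are CSV with
columns `patient_id, predicted_mask_path, ground_truth_mask_path[, fold]`.

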