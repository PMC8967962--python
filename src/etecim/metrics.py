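"""Pairwise comparison metrics between predicted and ground-truth masks.

Overlap is measured on voxel counts (Dice, conformity index, degree of
inclusion) and surfaces (Hausdorff and mean surface distance between
6-neighborhood boundary voxel centers, in mm).  Positional agreement is
summarized by the signed center-of-mass displacement decomposed into
left-right (LR), anterior-posterior (AP) and cranial-caudal (CC)
components, plus its Euclidean norm, the motion vector (MV).

Sign convention: displacements are predicted COM minus ground-truth COM,
so the one-sample t-tests on LR/AP/CC detect systematic placement bias of
the predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyForegroundError, GeometryMismatchError, UndefinedMetricError
from .io import MaskVolume

__all__ = [
    "ConfusionCounts",
    "SurfacePointSet",
    "OverlapReport",
    "confusion_counts",
    "dice",
    "surface_points",
    "hausdorff",
    "mean_surface_distance",
    "conformity_index",
    "degree_of_inclusion",
    "center_of_mass_shift",
    "motion_vector",
    "compare_masks",
]

# 6-neighborhood (face connectivity) structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise TP / FP / FN of a predicted vs ground-truth mask pair."""

    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class SurfacePointSet:
    """mm coordinates (columns x, y, z) of a mask's surface voxel centers.

    A foreground voxel is a surface voxel iff at least one of its six
    face-neighbors is background; positions outside the lattice count as
    background, so voxels on the lattice border are surface.
    """

    points: np.ndarray  # (n, 3) float, mm

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class OverlapReport:
    """All pairwise metrics for one predicted / ground-truth mask pair.

    Distance and inclusion fields are ``None`` when undefined (empty
    predicted mask); they are never silently zeroed.
    """

    dsc: float
    ci: float
    hd: float | None
    msd: float | None
    di_pred_in_gt: float | None
    di_gt_in_pred: float | None
    lr: float | None  # mm, signed
    ap: float | None
    cc: float | None
    mv: float | None


def _check_same_geometry(pred: MaskVolume, gt: MaskVolume) -> None:
    if pred.shape != gt.shape:
        raise GeometryMismatchError(
            f"mask shapes differ: predicted {pred.shape} vs ground truth {gt.shape}"
        )
    if pred.spacing != gt.spacing:
        raise GeometryMismatchError(
            f"mask spacings differ: predicted {pred.spacing} vs ground truth {gt.spacing}"
        )


def confusion_counts(pred: MaskVolume, gt: MaskVolume) -> ConfusionCounts:
    """TP/FP/FN voxel counts (TN is never needed by the metrics here)."""
    _check_same_geometry(pred, gt)
    p = pred.voxels.astype(bool)
    g = gt.voxels.astype(bool)
    tp = int(np.count_nonzero(p & g))
    return ConfusionCounts(tp=tp, fp=int(np.count_nonzero(p) - tp), fn=int(np.count_nonzero(g) - tp))


def dice(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN)."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        raise UndefinedMetricError("Dice is undefined when both masks are empty")
    return 2.0 * counts.tp / denom


def _voxel_mm_coords(mask: MaskVolume, where: np.ndarray) -> np.ndarray:
    """(n, 3) mm coordinates (x, y, z) of the True voxels of `where`."""
    zz, yy, xx = np.nonzero(where)
    sx, sy, sz = mask.spacing
    return np.column_stack([xx * sx, yy * sy, zz * sz]).astype(float)


def surface_points(mask: MaskVolume) -> SurfacePointSet:
    """Extract the 6-neighborhood boundary voxels of a mask, in mm."""
    fg = mask.voxels.astype(bool)
    if not fg.any():
        raise EmptyForegroundError("cannot extract a surface from an empty mask")
    interior = ndimage.binary_erosion(fg, structure=_STRUCT6, border_value=0)
    return SurfacePointSet(points=_voxel_mm_coords(mask, fg & ~interior))


def _directed_nearest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each point of a, distance to its nearest neighbor in b."""
    dists, _ = cKDTree(b).query(a, k=1)
    return dists


def hausdorff(p: SurfacePointSet, g: SurfacePointSet) -> float:
    """Symmetric (full, not 95th-percentile) Hausdorff distance in mm."""
    if len(p) == 0 or len(g) == 0:
        raise EmptyForegroundError("Hausdorff distance needs two nonempty surfaces")
    return float(max(_directed_nearest(p.points, g.points).max(),
                     _directed_nearest(g.points, p.points).max()))


def mean_surface_distance(p: SurfacePointSet, g: SurfacePointSet) -> float:
    """Symmetrized mean surface distance: average of the two directed means."""
    if len(p) == 0 or len(g) == 0:
        raise EmptyForegroundError("mean surface distance needs two nonempty surfaces")
    return float(0.5 * (_directed_nearest(p.points, g.points).mean()
                        + _directed_nearest(g.points, p.points).mean()))


def conformity_index(pred: MaskVolume, gt: MaskVolume) -> float:
    """Conformity index |A intersect B| / |A union B| (Jaccard)."""
    _check_same_geometry(pred, gt)
    p = pred.voxels.astype(bool)
    g = gt.voxels.astype(bool)
    union = int(np.count_nonzero(p | g))
    if union == 0:
        raise UndefinedMetricError("conformity index is undefined when both masks are empty")
    return int(np.count_nonzero(p & g)) / union


def degree_of_inclusion(pred: MaskVolume, gt: MaskVolume) -> tuple[float, float]:
    """(|P∩G|/|P|, |P∩G|/|G|): how much of each mask lies inside the other.

    1 - first component is the fraction of the prediction that would be
    unnecessarily irradiated; 1 - second component the fraction of the true
    tumor that would miss irradiation.
    """
    _check_same_geometry(pred, gt)
    p = pred.voxels.astype(bool)
    g = gt.voxels.astype(bool)
    np_, ng = int(np.count_nonzero(p)), int(np.count_nonzero(g))
    if np_ == 0 or ng == 0:
        which = "predicted" if np_ == 0 else "ground-truth"
        raise UndefinedMetricError(f"degree of inclusion is undefined: {which} mask is empty")
    inter = int(np.count_nonzero(p & g))
    return inter / np_, inter / ng


def _center_of_mass_mm(mask: MaskVolume) -> np.ndarray:
    coords = _voxel_mm_coords(mask, mask.voxels.astype(bool))
    if coords.size == 0:
        raise EmptyForegroundError("center of mass of an empty mask is undefined")
    return coords.mean(axis=0)


def center_of_mass_shift(pred: MaskVolume, gt: MaskVolume) -> tuple[float, float, float]:
    """Signed COM displacement (LR, AP, CC) = COM(pred) - COM(gt), in mm."""
    _check_same_geometry(pred, gt)
    d = _center_of_mass_mm(pred) - _center_of_mass_mm(gt)
    return float(d[0]), float(d[1]), float(d[2])


def motion_vector(lr: float, ap: float, cc: float) -> float:
    """Euclidean norm of the COM displacement, in mm."""
    return math.sqrt(lr * lr + ap * ap + cc * cc)


def compare_masks(pred: MaskVolume, gt: MaskVolume) -> OverlapReport:
    """Compute the full overlap report for one mask pair.

    The ground truth must be nonempty.  An empty prediction yields dsc = 0
    and ci = 0 with every distance and inclusion field set to ``None``.
    """
    _check_same_geometry(pred, gt)
    if not gt.voxels.any():
        raise EmptyForegroundError("ground-truth mask is empty")
    counts = confusion_counts(pred, gt)
    dsc = dice(counts)
    ci = conformity_index(pred, gt)
    if not pred.voxels.any():
        return OverlapReport(dsc=dsc, ci=ci, hd=None, msd=None, di_pred_in_gt=None,
                             di_gt_in_pred=None, lr=None, ap=None, cc=None, mv=None)
    sp, sg = surface_points(pred), surface_points(gt)
    di_p, di_g = degree_of_inclusion(pred, gt)
    lr, ap, cc = center_of_mass_shift(pred, gt)
    return OverlapReport(
        dsc=dsc,
        ci=ci,
        hd=hausdorff(sp, sg),
        msd=mean_surface_distance(sp, sg),
        di_pred_in_gt=di_p,
        di_gt_in_pred=di_g,
        lr=lr,
        ap=ap,
        cc=cc,
        mv=motion_vector(lr, ap, cc),
    )
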