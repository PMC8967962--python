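"""Gross tumor volume estimators and RECIST-style diameters.

Two estimators are provided:

* **ETECIM** (equivalent truncated elliptical cone integral method): each
  axial slice's lesion is summarized by its equivalent ellipse, and the
  tissue between adjacent slice centers is modeled as a truncated elliptical
  cone (frustum).  The total GTV is the sum of the frustum volumes

      V = (pi * h / 6) * (2 (a1 b1 + a2 b2) + a1 b2 + b1 a2)

  over adjacent slice pairs, with h the slice spacing.

* **voxel summation**: foreground voxel count times voxel volume.  This
  baseline systematically overestimates because boundary voxels are counted
  whole; on an n-slice cylinder the two estimators differ by exactly the
  factor (n-1)/n, since ETECIM integrates between outermost slice centers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

from .ellipse import EllipseFit, fit_stack
from .errors import EmptyForegroundError
from .io import MaskVolume

__all__ = [
    "VolumeEstimate",
    "frustum_volume",
    "etecim_volume",
    "voxel_sum_volume",
    "estimate_gtv",
    "recist_diameters",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("etecim", "voxel_sum")


@dataclass(frozen=True)
class VolumeEstimate:
    """A GTV value in mm^3 with its provenance.

    ``gap_contributions`` lists, for the ETECIM method, the frustum volume
    attributed to each adjacent slice pair as
    ``(lower_slice_index, upper_slice_index, volume_mm3)``; ``runs`` lists
    the contiguous slice ranges ``(first, last)`` that were integrated
    independently.
    """

    method: str
    volume: float
    gap_contributions: list[tuple[int, int, float]] = field(default_factory=list)
    runs: list[tuple[int, int]] = field(default_factory=list)


def frustum_volume(a_lower: float, b_lower: float, a_upper: float, b_upper: float, h: float) -> float:
    """Volume of a truncated elliptical cone between two parallel ellipses.

    The two faces have semi-axes (a_lower, b_lower) and (a_upper, b_upper)
    and are h mm apart.  Reduces to the circular frustum
    (pi h / 3)(R^2 + R r + r^2) when both faces are circles, to the
    elliptical cylinder pi a b h when the faces are equal, and to the cone
    (pi h / 3) a b when one face shrinks to a point.
    """
    for name, v in (("a_lower", a_lower), ("b_lower", b_lower), ("a_upper", a_upper), ("b_upper", b_upper)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if h <= 0:
        raise ValueError(f"h must be > 0, got {h}")
    return (math.pi * h / 6.0) * (
        2.0 * (a_lower * b_lower + a_upper * b_upper) + a_lower * b_upper + b_lower * a_upper
    )


def _contiguous_runs(fits: list[EllipseFit]) -> list[list[EllipseFit]]:
    runs: list[list[EllipseFit]] = [[fits[0]]]
    for fit in fits[1:]:
        if fit.slice_index == runs[-1][-1].slice_index + 1:
            runs[-1].append(fit)
        else:
            runs.append([fit])
    return runs


def etecim_volume(fits: list[EllipseFit], h: float) -> VolumeEstimate:
    """Integrate fitted slice ellipses into a GTV estimate.

    Fits are partitioned into contiguous-slice runs; within a run the
    volume is the sum of frusta between adjacent slices.  A run consisting
    of a single slice contributes an elliptical cylinder pi*a*b*h, since one
    slice represents h mm of tissue.  Runs separated by empty slices are
    summed independently (no interpolation across gaps).
    """
    if not fits:
        raise EmptyForegroundError("no ellipse fits to integrate")
    if h <= 0:
        raise ValueError(f"h must be > 0, got {h}")
    fits = sorted(fits, key=lambda f: f.slice_index)
    runs = _contiguous_runs(fits)
    if len(runs) > 1:
        logger.warning(
            "mask foreground spans %d non-contiguous slice runs; integrating each independently",
            len(runs),
        )
    gap_contributions: list[tuple[int, int, float]] = []
    run_ranges: list[tuple[int, int]] = []
    total = 0.0
    for run in runs:
        run_ranges.append((run[0].slice_index, run[-1].slice_index))
        if len(run) == 1:
            f = run[0]
            total += math.pi * f.a * f.b * h
            continue
        for lo, up in zip(run[:-1], run[1:]):
            v = frustum_volume(lo.a, lo.b, up.a, up.b, h)
            gap_contributions.append((lo.slice_index, up.slice_index, v))
            total += v
    return VolumeEstimate(
        method="etecim", volume=total, gap_contributions=gap_contributions, runs=run_ranges
    )


def voxel_sum_volume(mask: MaskVolume) -> VolumeEstimate:
    """Baseline GTV: foreground voxel count times voxel volume (mm^3)."""
    return VolumeEstimate(
        method="voxel_sum",
        volume=mask.foreground_count() * mask.voxel_volume_mm3,
    )


def estimate_gtv(mask: MaskVolume, method: str = "etecim") -> VolumeEstimate:
    """Dispatch to an estimator; for ETECIM, h is the axial spacing sz."""
    if method == "etecim":
        return etecim_volume(fit_stack(mask), h=mask.spacing[2])
    if method == "voxel_sum":
        return voxel_sum_volume(mask)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def recist_diameters(fits: list[EllipseFit]) -> tuple[float, float, int]:
    """Longest and shortest lesion diameters over a fitted stack.

    Returns ``(longest, shortest, slice_of_longest)`` in mm: the longest is
    ``max(2a)`` over slices, the shortest ``min(2b)``; ties break toward the
    lowest slice index.  An all-degenerate stack warns and reports zeros.
    """
    if not fits:
        raise EmptyForegroundError("no ellipse fits to measure")
    fits = sorted(fits, key=lambda f: f.slice_index)
    if all(f.degenerate for f in fits):
        warnings.warn(
            "all slices are degenerate (tiny or collinear foreground); diameters reported as 0",
            stacklevel=2,
        )
        return 0.0, 0.0, fits[0].slice_index
    longest_fit = max(fits, key=lambda f: (f.a, -f.slice_index))
    shortest = min(2.0 * f.b for f in fits)
    return 2.0 * longest_fit.a, shortest, longest_fit.slice_index
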