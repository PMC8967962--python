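"""Equivalent (inertia) ellipse fitting of axial mask slices.

The foreground of an axial slice is treated as a system of N unit-mass
points at the pixel centers.  Its central second moments

    A = sum (x_i - cx)^2,   B = sum (y_i - cy)^2,   H = sum (x_i - cx)(y_i - cy)

(in mm^2 * count, coordinates in mm) define an inertia ellipse whose
principal half-axes are

    a = sqrt(2 * [(A + B) + sqrt((A - B)^2 + 4 H^2)] / N)
    b = sqrt(2 * [(A + B) - sqrt((A - B)^2 + 4 H^2)] / N)

For an ideal uniform ellipse these recover the true semi-axes exactly
(second moment of a uniform ellipse about a principal axis is N * axis^2 / 4),
and the ellipse area pi*a*b matches the pixel area M up to discretization.
Orientation comes from the principal eigen-direction of the scatter matrix
[[A, H], [H, B]] in a y-up mm frame; the long-axis angle phi1 is reported in
degrees in (-90, 90] relative to the positive x-axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyForegroundError
from .io import MaskVolume

__all__ = ["SliceMoments", "EllipseFit", "slice_moments", "fit_equivalent_ellipse", "fit_stack"]

logger = logging.getLogger(__name__)

# relative scale below which the scatter matrix is treated as isotropic
_ISOTROPY_RTOL = 1e-9


@dataclass(frozen=True)
class SliceMoments:
    """Raw foreground moments of one axial slice (unnormalized, mm units)."""

    slice_index: int
    pixel_count: int
    centroid: tuple[float, float]  # (cx, cy) mm
    second_moment_xx: float  # A = sum (x-cx)^2, mm^2 * count
    second_moment_yy: float  # B = sum (y-cy)^2
    product_moment: float  # H = sum (x-cx)(y-cy)
    area: float  # M = N * sx * sy, mm^2


@dataclass(frozen=True)
class EllipseFit:
    """Equivalent-ellipse parameters of one slice.

    ``phi1`` is the long-axis angle, ``phi2`` the short-axis angle
    (``phi1 +/- 90`` wrapped back into (-90, 90]); both in degrees.
    ``degenerate`` marks slices too small to carry a meaningful ellipse
    (fewer than 3 pixels, or collinear foreground).
    """

    slice_index: int
    a: float  # long half-axis, mm
    b: float  # short half-axis, mm
    phi1: float  # degrees in (-90, 90]
    phi2: float
    centroid: tuple[float, float]
    area: float
    pixel_count: int
    degenerate: bool = False


def slice_moments(mask: MaskVolume, slice_index: int) -> SliceMoments:
    """Compute centroid and central second moments of one axial slice.

    Coordinates are pixel centers in mm (x = column * sx, y = row * sy).
    Raises :class:`EmptyForegroundError` if the slice has no foreground.
    """
    sx, sy, _ = mask.spacing
    plane = mask.voxels[slice_index]
    rows, cols = np.nonzero(plane)
    n = rows.size
    if n == 0:
        raise EmptyForegroundError(f"slice {slice_index} has no foreground pixels")
    _warn_multicomponent(plane, slice_index)
    x = cols * sx
    y = rows * sy
    cx = float(x.mean())
    cy = float(y.mean())
    dx = x - cx
    dy = y - cy
    return SliceMoments(
        slice_index=int(slice_index),
        pixel_count=int(n),
        centroid=(cx, cy),
        second_moment_xx=float(np.dot(dx, dx)),
        second_moment_yy=float(np.dot(dy, dy)),
        product_moment=float(np.dot(dx, dy)),
        area=float(n * sx * sy),
    )


def _warn_multicomponent(plane: np.ndarray, slice_index: int) -> None:
    # 4-connectivity: pixels touching by an edge form one lesion component
    _, n_comp = ndimage.label(plane)
    if n_comp > 1:
        logger.warning(
            "slice %d has %d connected components; pooling all foreground "
            "pixels into a single equivalent ellipse",
            slice_index,
            n_comp,
        )


def fit_equivalent_ellipse(moments: SliceMoments) -> EllipseFit:
    """Fit the equivalent ellipse from slice moments.

    The pixel count N (not the mm^2 area) is the normalizer, so the
    half-axes come out in mm for any in-plane spacing.  A slice of fewer
    than 3 pixels, or with collinear foreground (b = 0), is flagged
    degenerate; its a, b are still reported (possibly 0).
    """
    A = moments.second_moment_xx
    B = moments.second_moment_yy
    H = moments.product_moment
    n = moments.pixel_count

    radical = math.hypot(A - B, 2.0 * H)
    a_sq = 2.0 * ((A + B) + radical) / n
    b_sq = 2.0 * ((A + B) - radical) / n
    a = math.sqrt(max(a_sq, 0.0))
    b = math.sqrt(max(b_sq, 0.0))

    if radical <= _ISOTROPY_RTOL * (A + B) or (A + B) == 0.0:
        # circle (or point): orientation is conventional
        phi1 = 0.0
    else:
        # long axis = principal eigenvector of [[A, H], [H, B]]
        evals, evecs = np.linalg.eigh(np.array([[A, H], [H, B]]))
        vx, vy = evecs[:, np.argmax(evals)]
        phi1 = math.degrees(math.atan2(vy, vx))
        phi1 = _wrap_half_open(phi1)
    phi2 = _wrap_half_open(phi1 + 90.0)

    degenerate = n < 3 or b == 0.0
    return EllipseFit(
        slice_index=moments.slice_index,
        a=a,
        b=b,
        phi1=phi1,
        phi2=phi2,
        centroid=moments.centroid,
        area=moments.area,
        pixel_count=n,
        degenerate=degenerate,
    )


def _wrap_half_open(angle_deg: float) -> float:
    """Wrap an angle in degrees into (-90, 90]."""
    wrapped = (angle_deg + 90.0) % 180.0 - 90.0
    if wrapped == -90.0:
        wrapped = 90.0
    return wrapped


def fit_stack(mask: MaskVolume) -> list[EllipseFit]:
    """Fit every axial slice that contains foreground, cranial to caudal.

    Empty slices are omitted (their indices simply do not appear); a fully
    empty mask raises :class:`EmptyForegroundError`.
    """
    occupied = np.flatnonzero(mask.voxels.any(axis=(1, 2)))
    if occupied.size == 0:
        raise EmptyForegroundError("mask has no foreground voxels")
    return [fit_equivalent_ellipse(slice_moments(mask, int(k))) for k in occupied]
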