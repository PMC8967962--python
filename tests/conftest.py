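import math

import numpy as np
import pytest

from etecim import MaskVolume
from etecim.phantoms import PhantomSpec, SliceEllipse, make_ellipsoid_mask, make_tube_phantom


def single_ellipse_mask(a0, b0, theta_deg, spacing=(1.0, 1.0, 5.0), margin=6):
    """One-slice mask holding a rasterized rotated ellipse (semi-axes in mm)."""
    sx, sy, _ = spacing
    n = int(2 * max(a0, b0) / min(sx, sy)) + 2 * margin
    c = (n - 1) / 2
    spec = PhantomSpec(
        shape="elliptical_tube",
        lattice=(3, n, n),
        spacing=spacing,
        slices=(SliceEllipse(slice_index=1, a=a0, b=b0, phi_deg=theta_deg, center=(c * sx, c * sy)),),
    )
    return make_tube_phantom(spec).mask


def cylinder_mask(radius_mm=10.0, n_slices=11, spacing=(1.0, 1.0, 5.0)):
    sx, sy, _ = spacing
    n = int(2 * radius_mm / min(sx, sy)) + 12
    c = (n - 1) / 2
    slices = tuple(
        SliceEllipse(slice_index=k, a=radius_mm, b=radius_mm, phi_deg=0.0, center=(c * sx, c * sy))
        for k in range(n_slices)
    )
    spec = PhantomSpec(shape="elliptical_tube", lattice=(n_slices, n, n), spacing=spacing, slices=slices)
    return make_tube_phantom(spec)


def cube_mask(side=4, shape=(12, 12, 12), offset=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
    vox = np.zeros(shape, dtype=np.uint8)
    oz, oy, ox = offset
    vox[oz : oz + side, oy : oy + side, ox : ox + side] = 1
    return MaskVolume(voxels=vox, spacing=spacing)


@pytest.fixture
def ellipsoid_phantom():
    """Rasterized ellipsoid, semi-axes (15, 10, 30) mm at (1, 1, 5) mm spacing."""
    spec = PhantomSpec(shape="ellipsoid", lattice=(30, 80, 80), spacing=(1.0, 1.0, 5.0), semi_axes=(15.0, 10.0, 30.0))
    return make_ellipsoid_mask(spec)


@pytest.fixture
def cylinder_phantom():
    """11 identical circular slices r = 10 mm, h = 5 mm (analytic 5000*pi)."""
    return cylinder_mask()


def angle_diff_deg(a, b):
    """Smallest difference between two axis orientations, mod 180 degrees."""
    return abs((a - b + 90.0) % 180.0 - 90.0)


def analytic_cylinder_volume(radius_mm=10.0, n_slices=11, h=5.0):
    return (n_slices - 1) * math.pi * radius_mm**2 * h
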