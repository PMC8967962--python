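"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — double loops, all-pairs distance
matrices, textbook formulas — and shares no code with the package paths it
verifies.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import t as t_dist


def moments_double_loop(plane: np.ndarray, sx: float, sy: float):
    """Central second moments of a 2-D binary slice by explicit loops."""
    pts = [(c * sx, r * sy) for r in range(plane.shape[0]) for c in range(plane.shape[1]) if plane[r, c]]
    n = len(pts)
    cx = sum(p[0] for p in pts) / n
    cy = sum(p[1] for p in pts) / n
    A = sum((p[0] - cx) ** 2 for p in pts)
    B = sum((p[1] - cy) ** 2 for p in pts)
    H = sum((p[0] - cx) * (p[1] - cy) for p in pts)
    return n, (cx, cy), A, B, H


def hausdorff_allpairs(p: np.ndarray, g: np.ndarray) -> float:
    d = cdist(p, g)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def msd_allpairs(p: np.ndarray, g: np.ndarray) -> float:
    d = cdist(p, g)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def surface_voxels_loop(vox: np.ndarray) -> set[tuple[int, int, int]]:
    """Foreground voxels with >=1 background face-neighbor, by explicit check."""
    nz, ny, nx = vox.shape
    out = set()
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                if not vox[k, j, i]:
                    continue
                for dk, dj, di in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    kk, jj, ii = k + dk, j + dj, i + di
                    if not (0 <= kk < nz and 0 <= jj < ny and 0 <= ii < nx) or not vox[kk, jj, ii]:
                        out.add((k, j, i))
                        break
    return out


def pearson_formula(x: np.ndarray, y: np.ndarray):
    n = len(x)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = math.sqrt(float(((x - mx) ** 2).sum()) * float(((y - my) ** 2).sum()))
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * t_dist.sf(abs(t), n - 2)
    return r, p


def one_sample_t_formula(v: np.ndarray, mu0: float):
    n = len(v)
    sd = math.sqrt(float(((v - v.mean()) ** 2).sum()) / (n - 1))
    t = (v.mean() - mu0) / (sd / math.sqrt(n))
    return t, 2 * t_dist.sf(abs(t), n - 1)


def quantile_sort_interp(v: np.ndarray, q: float) -> float:
    """Linear interpolation between order statistics, written from scratch."""
    s = sorted(float(x) for x in v)
    if len(s) == 1:
        return s[0]
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def ols_formula(x: np.ndarray, y: np.ndarray):
    """Slope, intercept and the slope's standard error, textbook forms."""
    n = len(x)
    mx, my = x.mean(), y.mean()
    sxx = float(((x - mx) ** 2).sum())
    slope = float(((x - mx) * (y - my)).sum()) / sxx
    intercept = my - slope * mx
    resid = y - (slope * x + intercept)
    se_slope = math.sqrt(float((resid**2).sum()) / (n - 2) / sxx)
    return slope, intercept, se_slope
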