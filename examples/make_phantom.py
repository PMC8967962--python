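"""Generate phantom masks with known analytic geometry and save them.

Phantoms are the test bed for every estimator: each one carries its exact
analytic volume and per-slice ellipse parameters.
"""

import os
import tempfile

import numpy as np

from etecim import estimate_gtv, save_mask
from etecim.phantoms import make_tube_phantom, random_tube_spec

rng = np.random.default_rng(7)
phantom = make_tube_phantom(random_tube_spec(rng))

print(f"slices occupied     : {len(phantom.slice_params)}")
print(f"analytic volume     : {phantom.analytic_volume:.1f} mm^3 (frustum chain)")
est = estimate_gtv(phantom.mask, "etecim")
print(f"ETECIM on raster    : {est.volume:.1f} mm^3 "
      f"({100 * (est.volume - phantom.analytic_volume) / phantom.analytic_volume:+.1f}%)")

with tempfile.TemporaryDirectory() as d:
    path = save_mask(phantom.mask, os.path.join(d, "tube.nii.gz"))
    print(f"saved               : {os.path.basename(path)} "
          f"({os.path.getsize(path)} bytes, deterministic gzip)")
print("\nThe residual is pure rasterization error: the estimator is exact on")
print("the analytic per-slice ellipses by construction.")
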