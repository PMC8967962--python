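"""Fit per-slice equivalent ellipses and read off RECIST-style diameters.

The equivalent (inertia) ellipse of a slice matches the second moments of
the lesion's pixel set; its half-axes a >= b and orientation phi1 summarize
the slice shape.
"""

from etecim import fit_stack, recist_diameters
from etecim.phantoms import PhantomSpec, make_ellipsoid_mask

spec = PhantomSpec(shape="ellipsoid", lattice=(30, 80, 80), spacing=(1.0, 1.0, 5.0),
                   semi_axes=(15.0, 10.0, 30.0))
mask = make_ellipsoid_mask(spec).mask

fits = fit_stack(mask)
print("slice   a_mm   b_mm  phi1_deg  area_mm2  pixels")
for f in fits:
    print(f"{f.slice_index:5d} {f.a:6.2f} {f.b:6.2f} {f.phi1:9.2f} {f.area:9.1f} {f.pixel_count:7d}")

longest, shortest, at = recist_diameters(fits)
print(f"\nlongest diameter  : {longest:.1f} mm (slice {at})")
print(f"shortest diameter : {shortest:.1f} mm")
print("\nThe longest diameter is the RECIST measurement axis; the per-slice")
print("half-axes feed the frustum chain of the ETECIM volume estimate.")
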