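"""Implied orientation and orientation gradients of texture structure.

Evaluates the orientation a concentric (circular) texture implies at the
occluded test location, the gradient of that structure along the
iso-eccentric arc, and the arithmetic of quantizing a linear orientation
gradient into constant-orientation spatial bands.
"""

from remotetae import (
    OrientationField,
    band_step,
    distinct_band_orientations,
    implied_orientation,
    local_gradient,
    quantize_field,
    test_location,
)

site = test_location()  # 10 deg eccentricity, polar angle 15 deg
concentric = OrientationField("concentric")

print(f"test site: ({site[0]:.2f}, {site[1]:.2f}) deg from fixation")
print(f"implied orientation there: {implied_orientation(concentric, site):+.1f} deg "
      "(counter-clockwise of vertical)")
print(f"orientation gradient along the arc: {local_gradient(concentric, site):.2f} "
      "deg orientation per deg of visual angle")

lin = OrientationField("linear_gradient", gradient_rate=5.0,
                       anchor_point=site, anchor_orientation=15.0)
print(f"\nlinear gradient, rate {lin.gradient_rate:g} deg/deg "
      f"(spatial period {180 / lin.gradient_rate:g} deg):")
for width in (8.0, 12.0, 36.0):
    q = quantize_field(lin, width)
    n = len(distinct_band_orientations(q))
    print(f"  {width:>4g} deg bands -> inter-band step {band_step(q):5.1f} deg, "
          f"{n} distinct orientation(s) per cycle")

# The 8 deg bands (40 deg steps) still support the aftereffect; 12 deg
# bands (60 deg steps) render the gradient unreadable; 36 deg bands leave
# an iso-oriented texture with no gradient at all.
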