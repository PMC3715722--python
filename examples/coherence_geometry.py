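"""Signal/noise coherence of annular noise layouts.

A "proximal noise" adaptor confines all randomly oriented elements to an
annulus around the test site.  Under uniform element density, the
structure coherence (fraction of visible elements carrying the circular
structure) is a deterministic function of the annulus outer radius; this
script computes it by area integration and inverts it for target
coherence levels.
"""

from remotetae import LayoutGeometry, coherence_for_radius, solve_noise_radius

layout = LayoutGeometry(noise_layout="proximal", annulus_outer_radius=9.53)

coh = coherence_for_radius(layout, 9.53)
print(f"outer radius 9.53 deg -> structure coherence {100 * coh:.1f}%")

for target in (0.9, 0.75, 0.5, 0.25):
    radius = solve_noise_radius(layout, target)
    print(f"coherence {target:4.0%} needs outer radius {radius:5.2f} deg")

# Every signal element is at least the quoted radius away from the test
# site, yet the aftereffect there survives: remote adaptation spans large
# regions of the visual field.
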