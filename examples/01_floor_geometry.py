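"""Floor geometry: module types, field centroids and resolution figures.

Builds the three standard module types and prints their sensor densities
and per-field areas, then shows the eight triangle centroids of one
gait-resolution module.
"""

import gaitfloor as gf

for name, (lx, ly) in {
    "low resolution (1.00 x 0.50 m)": (1.0, 0.5),
    "high resolution (0.50 x 0.50 m)": (0.5, 0.5),
    "gait resolution (0.38 x 0.38 m)": (0.38, 0.38),
}.items():
    density = gf.fields_per_square_meter(lx, ly)
    print(f"{name}: {density:5.1f} fields/m^2")

print(f"\ngait-resolution field area: {gf.field_area(0.38):.5f} m^2")

module = gf.ModuleGeometry("m0", center=(0.0, 0.0), edge=0.38)
print("\nfield centroids of a module at the origin (slot order 1..8):")
for j, (x, y) in enumerate(gf.field_centroids(module), start=1):
    print(f"  slot {j}: ({x:+.5f}, {y:+.5f}) m")

# The centroids are the +-(2/3)(l/2) and +-(1/3)(l/2) offset combinations:
# eight triangles per module double the density of a square grid of the
# same edge, which is the point of the triangular cut.
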