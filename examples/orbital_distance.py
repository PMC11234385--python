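"""Orbital distance: comparing the function of two dynamical systems.

The Fréchet distance between arc-length-resampled, max-normalized orbits
is the shortest "leash" joining a walker on each curve — a bottleneck
measure that penalises local deformations of the gene-expression sequence
but is blind to tempo.  DTW (aggregate) and Hausdorff (set-based) are
provided as alternatives.
"""

import numpy as np

from orbitempo import (
    dtw_distance,
    frechet_distance,
    hausdorff_distance,
    orbit_from_points,
)

theta = np.linspace(0.0, 2 * np.pi, 200, endpoint=False)
circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)
ellipse = np.stack([1.3 * np.cos(theta), 0.8 * np.sin(theta)], axis=1)

a = orbit_from_points(circle, closed=True)
b = orbit_from_points(ellipse, closed=True)
# a cyclically re-indexed copy of the circle: the same closed orbit
c = orbit_from_points(np.roll(circle, 57, axis=0), closed=True)

print("pair                         frechet      dtw     hausdorff")
for name, other in [("circle vs itself (recut)", c), ("circle vs ellipse", b)]:
    f = frechet_distance(a, other, compute_alignment=False).value
    d = dtw_distance(a, other).value
    h = hausdorff_distance(a, other).value
    print(f"{name:<26} {f:9.4f} {d:9.3f} {h:9.4f}")

print()
print("Re-cutting a closed orbit at another start point costs nothing: the")
print("closed-curve search over cyclic shifts recognises the same cycle")
print("(distance 0).  The ellipse differs by 0.3 at the bottleneck — exactly")
print("its maximal deviation from the circle — while DTW accumulates cost")
print("along the whole curve, and Hausdorff lower-bounds Frechet.")
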