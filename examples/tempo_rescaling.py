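"""Orbital equivalence in neural-tube differentiation.

Scaling protein production and degradation together by any positive tempo
profile mu(t) — constant, stepped, sinusoidal, or state-dependent — leaves
the gene-expression orbit of the Pax6/Olig2/Nkx2-2/Irx3 network identical
while freely changing when each state is reached.
"""

import numpy as np

from orbitempo import (
    apply_scalar_prefactor,
    build_neural_tube,
    default_initial_state,
    frechet_distance,
    integrate,
    normalize_orbit,
    orbit_from_trajectory,
    resample_arclength,
    time_factor,
)

model = build_neural_tube(shh_level=1.0)
x0 = default_initial_state(model)
reference = integrate(model, x0, (0.0, 80.0))
orbit_ref = normalize_orbit(resample_arclength(orbit_from_trajectory(reference), 500))

profiles = {
    "constant x2": lambda x, t: 2.0,
    "step 0.5 -> 2.5": lambda x, t: 0.5 if t < 15.0 else 2.5,
    "sinusoidal": lambda x, t: 1.5 + np.sin(0.3 * t),
    "state-dependent": lambda x, t: 0.5 + 1.5 * x[2] / (x[2] + 0.2),
}

print("tempo profile          Frechet distance   time factor")
for name, mu in profiles.items():
    traj = integrate(apply_scalar_prefactor(model, mu), x0, (0.0, 240.0))
    orbit = normalize_orbit(resample_arclength(orbit_from_trajectory(traj), 500))
    d = frechet_distance(orbit_ref, orbit, closed=False,
                         compute_alignment=False).value
    tf = time_factor(reference, traj)
    print(f"{name:<22} {d:>12.2e}      {tf:8.3f}")

print()
print("Every profile leaves the orbit numerically identical (distance ~1e-4")
print("on max-normalized expression) while the time to reach the Nkx2-2")
print("half-activation event shifts by the printed factor: tempo and")
print("function are independently controllable.")
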