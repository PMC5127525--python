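"""Check the solver against the textbook eddy-current formula |E| = π f B0 r⊥.

A homogeneous conducting sphere in a uniform axial magnetic flux density
induces a purely azimuthal electric field growing linearly with the distance
from the axis. A synthetic uniform-B incident map drives the solver and the
interior field is compared with the closed form.

Runtime: ~20 s on one core.
"""

import numpy as np
from scipy.ndimage import binary_erosion

from qsdose import (
    TissueProperties,
    build_sphere_phantom,
    qs_fdtd_solve,
    uniform_b_incident_field,
)

f, b0 = 1e6, 1e-6  # 1 MHz, 1 µT peak
phantom = build_sphere_phantom(
    0.020, 0.002, TissueProperties("sphere", 40.0, 1.0, 1000.0), padding_voxels=10
)
incident = uniform_b_incident_field(phantom.grid, b0, f)
solution = qs_fdtd_solve(phantom, incident)

interior = binary_erosion(phantom.tissue_mask, iterations=3)
x, y, _ = phantom.grid.voxel_center_coords()
rperp = np.sqrt(
    np.broadcast_to(x, interior.shape) ** 2 + np.broadcast_to(y, interior.shape) ** 2
)
theory = np.pi * f * b0 * rperp
sel = interior & (theory > 0)
rel = np.abs(solution.magnitude()[sel] - theory[sel]) / theory[sel] * 100

print(f"steps to converge      : {solution.steps_to_converge}")
print(f"interior voxels        : {sel.sum()}")
print(f"median |error|         : {np.median(rel):.3f} %")
print(f"worst interior |error| : {rel.max():.3f} %")
print(
    "\nAgreement within a few percent everywhere (a few tenths of a percent "
    "in the median) "
    "confirms the α=ω peak-equivalence convention: the steady ramp response "
    "equals the peak sinusoidal internal field π·f·B0·r⊥."
)
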