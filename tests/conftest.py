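"""Shared fixtures: small phantoms and pre-solved fields reused across modules."""

import numpy as np
import pytest

from qsdose import (
    FieldSolution,
    SolverConfig,
    TissueProperties,
    build_sphere_phantom,
    qs_fdtd_solve,
    uniform_b_incident_field,
)
from qsdose._grid import Grid

SPHERE_TISSUE = TissueProperties("sphere", 40.0, 1.0, 1000.0)


@pytest.fixture(scope="session")
def small_sphere_phantom():
    """20 mm-radius sphere at 2 mm spacing — cheap solver-scale phantom."""
    return build_sphere_phantom(0.020, 0.002, SPHERE_TISSUE, padding_voxels=10)


@pytest.fixture(scope="session")
def uniform_solution(small_sphere_phantom):
    """Solved uniform-axial-B exposure of the small sphere (1 µT, 1 MHz)."""
    inc = uniform_b_incident_field(small_sphere_phantom.grid, 1e-6, 1e6)
    return qs_fdtd_solve(small_sphere_phantom, inc, config=SolverConfig())


def make_uniform_field_solution(phantom, value):
    """Synthetic FieldSolution with |E| = ``value`` everywhere (all in Ez)."""
    grid = phantom.grid
    ex = np.zeros(grid.component_shape("ex"))
    ey = np.zeros(grid.component_shape("ey"))
    ez = np.full(grid.component_shape("ez"), float(value))
    return FieldSolution(ex, ey, ez, grid, 0, np.zeros((0, 2)))


@pytest.fixture()
def tiny_grid():
    return Grid((4, 4, 4), 0.002)


@pytest.fixture(scope="session")
def sphere_verification_run():
    """Scaled verification geometry solved against the analytic oracle.

    50 mm-radius sphere at the published electrical contrast (εr=40, σ=1 S/m,
    2 mm grid, z-polarized dipole on the axis at 4× the radius, 1 MHz);
    returns the point-by-point interior error statistics and step count.
    """
    import numpy as np
    from scipy.ndimage import binary_erosion

    from qsdose import (
        MagneticDipoleSource,
        SphereProblem,
        dipole_incident_field,
        sphere_interior_field,
    )

    radius, spacing = 0.050, 0.002
    phantom = build_sphere_phantom(radius, spacing, SPHERE_TISSUE, padding_voxels=10)
    src = MagneticDipoleSource(1.0, (0.0, 0.0, 4 * radius), 1.0e6)
    incident = dipole_incident_field(src, phantom.grid)
    solution = qs_fdtd_solve(phantom, incident, config=SolverConfig())

    mask = phantom.tissue_mask
    interior = binary_erosion(mask, iterations=3)
    x, y, z = phantom.grid.voxel_center_coords()
    pts = np.stack(
        [np.broadcast_to(c, mask.shape)[interior] for c in (x, y, z)], axis=1
    )
    problem = SphereProblem(radius, 40.0, 1.0, src)
    theory = np.linalg.norm(np.abs(sphere_interior_field(problem, pts)), axis=1)
    computed = solution.magnitude()[interior]
    rel = np.abs(computed - theory) / theory * 100.0
    return {
        "median_pct": float(np.median(rel)),
        "max_field_pct": float(abs(computed.max() - theory.max()) / theory.max() * 100.0),
        "steps": solution.steps_to_converge,
        "solution": solution,
        "phantom": phantom,
    }


@pytest.fixture(scope="session")
def stylized_body_run(tmp_path_factory):
    """Coarse stylized-body exposure in front of the 20-turn charging coil."""
    from qsdose import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("body")
    cfg = RunConfig(
        phantom={"fixture": "stylized_body", "height": 1.0, "spacing": 0.02},
        source={"kind": "coil", "turns": 20, "diameter": 0.1, "pitch": 0.001,
                "current": 1.0, "center": [0.0, -0.35, 0.94],
                "axis": [0, 1, 0], "segments_per_turn": 32},
        frequency=150e3,
        output_dir=str(out),
        write_fields=False,
    )
    report, artifacts = run_pipeline(cfg)
    return {"report": report, "artifacts": artifacts, "out": out}
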