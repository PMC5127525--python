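"""Staggered (Yee) grid geometry shared by phantoms, incident fields and solver.

Conventions
-----------
* Voxel array index order is (x, y, z); the raw-file layout is x-fastest
  (Fortran order on these arrays).
* World coordinates are right-handed with z up; the voxel (i, j, k) centre sits
  at ``origin + (i+0.5, j+0.5, k+0.5) * spacing``.
* Corner node (i, j, k) sits at ``origin + (i, j, k) * spacing``; E components
  live on cell edges (Ex along x at transverse corner positions, etc.), H
  components on cell faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Edge offsets (in units of spacing) of each E component relative to a corner.
_E_OFFSETS = {"ex": (0.5, 0.0, 0.0), "ey": (0.0, 0.5, 0.0), "ez": (0.0, 0.0, 0.5)}


@dataclass(frozen=True)
class Grid:
    """Uniform isotropic voxel grid: ``shape`` voxels of edge ``spacing`` metres."""

    shape: tuple[int, int, int]
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    # ---- component array shapes ------------------------------------------------
    def component_shape(self, comp: str) -> tuple[int, int, int]:
        nx, ny, nz = self.shape
        if comp == "ex":
            return (nx, ny + 1, nz + 1)
        if comp == "ey":
            return (nx + 1, ny, nz + 1)
        if comp == "ez":
            return (nx + 1, ny + 1, nz)
        if comp == "hx":
            return (nx + 1, ny, nz)
        if comp == "hy":
            return (nx, ny + 1, nz)
        if comp == "hz":
            return (nx, ny, nz + 1)
        raise ValueError(f"unknown component {comp!r}")

    # ---- node positions --------------------------------------------------------
    def component_coords(self, comp: str):
        """Open-meshgrid world coordinates (X, Y, Z) of the nodes of ``comp``."""
        if comp not in _E_OFFSETS:
            raise ValueError(f"coordinates implemented for E components, got {comp!r}")
        off = _E_OFFSETS[comp]
        shape = self.component_shape(comp)
        axes = [
            self.origin[a] + (np.arange(shape[a]) + off[a]) * self.spacing
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def voxel_center_coords(self):
        """Open-meshgrid world coordinates of voxel centres."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def matches(self, other: "Grid", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.spacing, other.spacing, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-12)
        )

    def describe(self) -> str:
        return (
            f"shape={self.shape}, spacing={self.spacing:g} m, "
            f"origin=({self.origin[0]:g}, {self.origin[1]:g}, {self.origin[2]:g}) m"
        )
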