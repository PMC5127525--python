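"""Voxel phantoms: construction, dielectric properties, and raw+JSON I/O.

A phantom is a 3-D integer label array (0 = free space) on an isotropic grid,
with a per-label table of tissue properties (relative permittivity εr,
conductivity σ in S/m, mass density ρ in kg/m³, an IEEE tissue group for the
E5mm classification and a CNS flag). Tissue property values at a given
frequency can be evaluated from Gabriel-style 4-pole Cole-Cole dispersion
parameters, or supplied directly; the fixtures in :mod:`qsdose.pipeline` ship
generic, non-authoritative values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.constants import epsilon_0

from ._grid import Grid
from .errors import FormatError

TISSUE_GROUPS = ("brain", "heart", "limbs", "other")

PHANTOM_FORMAT = "qsdose-phantom-v1"


@dataclass(frozen=True)
class TissueProperties:
    """Dielectric and dosimetric properties of one tissue at one frequency.

    ``group`` is the IEEE electrostimulation tissue class used for the E5mm
    limit (brain / heart / limbs / other); ``is_cns`` marks central-nervous-
    system tissues for the CNS-restricted metrics.
    """

    name: str
    relative_permittivity: float
    conductivity: float
    mass_density: float
    group: str = "other"
    is_cns: bool = False

    def __post_init__(self):
        if self.relative_permittivity < 1:
            raise ValueError(f"{self.name}: relative permittivity must be >= 1")
        if self.conductivity < 0:
            raise ValueError(f"{self.name}: conductivity must be >= 0")
        if self.mass_density <= 0:
            raise ValueError(f"{self.name}: mass density must be > 0")
        if self.group not in TISSUE_GROUPS:
            raise ValueError(
                f"{self.name}: group {self.group!r} not one of {TISSUE_GROUPS}"
            )


@dataclass(frozen=True)
class ColeColeParams:
    """4-pole Cole-Cole dispersion parameters (Gabriel parameterization).

    ε̂(ω) = ε_inf + Σₙ Δεₙ / (1 + (jωτₙ)^(1−αₙ)) + σ_ionic / (jωε0)
    """

    eps_inf: float
    delta_eps: tuple[float, ...] = ()
    tau: tuple[float, ...] = ()
    alpha: tuple[float, ...] = ()
    sigma_ionic: float = 0.0

    def __post_init__(self):
        if not (len(self.delta_eps) == len(self.tau) == len(self.alpha)):
            raise ValueError("delta_eps, tau and alpha must have equal lengths")
        if any(d < 0 for d in self.delta_eps):
            raise ValueError("all delta_eps must be >= 0")
        if any(t <= 0 for t in self.tau):
            raise ValueError("all tau must be > 0")
        if any(not (0 <= a < 1) for a in self.alpha):
            raise ValueError("all alpha must lie in [0, 1)")
        if self.sigma_ionic < 0:
            raise ValueError("sigma_ionic must be >= 0")


def cole_cole_permittivity(params: ColeColeParams, frequency: float):
    """Evaluate (εr, σ) of a Cole-Cole medium at ``frequency`` (Hz).

    Returns the real relative permittivity and the total conductivity
    σ = −ω ε0 Im ε̂ (which includes the ionic term).
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    omega = 2.0 * np.pi * frequency
    eps_hat = complex(params.eps_inf)
    for de, tau, alpha in zip(params.delta_eps, params.tau, params.alpha):
        eps_hat += de / (1.0 + (1j * omega * tau) ** (1.0 - alpha))
    eps_hat += params.sigma_ionic / (1j * omega * epsilon_0)
    eps_r = eps_hat.real
    sigma = -omega * epsilon_0 * eps_hat.imag
    return eps_r, sigma


@dataclass
class VoxelPhantom:
    """3-D tissue-label grid plus tissue property table.

    ``labels`` has index order (x, y, z); 0 means free space and every nonzero
    label must appear in ``tissue_table``.
    """

    labels: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tissue_table: dict[int, TissueProperties] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.tissue_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from tissue_table")
        if 0 in self.tissue_table:
            raise ValueError("label 0 is reserved for free space")

    # ---- derived views ---------------------------------------------------------
    @property
    def grid(self) -> Grid:
        return Grid(self.labels.shape, self.spacing, self.origin)

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != 0

    def property_volumes(self):
        """Per-voxel (ε absolute, σ, ρ) arrays; free space is (ε0, 0, 0)."""
        eps = np.full(self.labels.shape, epsilon_0)
        sigma = np.zeros(self.labels.shape)
        rho = np.zeros(self.labels.shape)
        for lab, t in self.tissue_table.items():
            m = self.labels == lab
            eps[m] = t.relative_permittivity * epsilon_0
            sigma[m] = t.conductivity
            rho[m] = t.mass_density
        return eps, sigma, rho

    def group_volume(self) -> np.ndarray:
        """Per-voxel IEEE group id (index into TISSUE_GROUPS); −1 in free space."""
        g = np.full(self.labels.shape, -1, dtype=np.int8)
        for lab, t in self.tissue_table.items():
            g[self.labels == lab] = TISSUE_GROUPS.index(t.group)
        return g

    def cns_mask(self) -> np.ndarray:
        m = np.zeros(self.labels.shape, dtype=bool)
        for lab, t in self.tissue_table.items():
            if t.is_cns:
                m |= self.labels == lab
        return m

    def total_mass(self) -> float:
        """Total tissue mass in kg (voxel volume × density summed)."""
        _, _, rho = self.property_volumes()
        return float(rho.sum() * self.spacing**3)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_sphere_phantom(
    radius: float,
    spacing: float,
    properties: TissueProperties,
    padding_voxels: int = 10,
    label: int = 1,
) -> VoxelPhantom:
    """Voxelize a homogeneous sphere, centred in the array with free-space padding.

    A voxel is tissue iff its centre lies within ``radius`` of the sphere
    centre (voxel-centre membership; staircase surfaces are accepted).
    """
    if radius < spacing:
        raise ValueError("radius must be at least one voxel spacing")
    if padding_voxels < 0:
        raise ValueError("padding_voxels must be >= 0")
    half = int(np.ceil(radius / spacing - 0.5))  # voxels whose centre can be inside
    n = 2 * (half + 1) + 2 * padding_voxels
    origin = (-0.5 * n * spacing,) * 3
    grid = Grid((n, n, n), spacing, origin)
    x, y, z = grid.voxel_center_coords()
    inside = x**2 + y**2 + z**2 <= radius**2
    labels = np.where(inside, label, 0).astype(np.uint16)
    return VoxelPhantom(labels, spacing, origin, {label: properties})


#: Generic, non-authoritative tissue values for the stylized body fixture.
#: Conductivities and densities are of realistic ~100–200 kHz magnitude; the
#: permittivities are deliberately kept at the low end of the dispersive
#: range so that σ/(ωε) ≫ 1 and the charge-relaxation times ε/σ stay well
#: inside the conduction-dominated regime the quasi-static solve assumes.
STYLIZED_TISSUES = {
    1: TissueProperties("skin_fat", 150.0, 0.05, 950.0, "other", False),
    2: TissueProperties("muscle", 800.0, 0.40, 1050.0, "other", False),
    3: TissueProperties("bone", 120.0, 0.02, 1900.0, "other", False),
    4: TissueProperties("brain", 600.0, 0.15, 1040.0, "brain", True),
    5: TissueProperties("heart", 800.0, 0.30, 1050.0, "heart", False),
}


def build_stylized_body_phantom(
    height: float,
    spacing: float,
    tissue_table: dict[int, TissueProperties] | None = None,
    padding_voxels: int = 10,
) -> VoxelPhantom:
    """Deterministic stylized body: layered ellipsoid trunk + spherical head.

    A synthetic stand-in for anatomical voxel models: an outer skin/fat shell,
    muscle bulk, an ellipsoidal bone core, a heart blob in the chest and a
    brain (CNS) inside the head sphere. Axes: z from foot (0) to head
    (``height``), x left-right, y back-front; the body is centred on the z
    axis.
    """
    if height < 10 * spacing:
        raise ValueError("height must be at least 10 voxel spacings")
    table = dict(tissue_table) if tissue_table is not None else dict(STYLIZED_TISSUES)
    if not any(t.is_cns for t in table.values()):
        raise ValueError("tissue table must flag at least one CNS tissue")

    head_r = height / 17.0
    trunk_az = (height - 2.0 * head_r) / 2.0
    trunk_ax = height / 11.0
    trunk_ay = height / 16.0
    head_cz = height - head_r
    shell = max(spacing, 0.012 * height)

    nx = int(np.ceil(2 * trunk_ax / spacing)) + 2 * padding_voxels
    ny = int(np.ceil(2 * trunk_ay / spacing)) + 2 * padding_voxels
    nz = int(np.ceil(height / spacing)) + 2 * padding_voxels
    origin = (
        -0.5 * nx * spacing,
        -0.5 * ny * spacing,
        -padding_voxels * spacing,
    )
    grid = Grid((nx, ny, nz), spacing, origin)
    x, y, z = grid.voxel_center_coords()

    def ellipsoid(ax, ay, az, cz):
        return (x / ax) ** 2 + (y / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    labels = np.zeros((nx, ny, nz), dtype=np.uint16)
    trunk = ellipsoid(trunk_ax, trunk_ay, trunk_az, trunk_az)
    trunk_core = ellipsoid(
        max(trunk_ax - shell, spacing),
        max(trunk_ay - shell, spacing),
        max(trunk_az - shell, spacing),
        trunk_az,
    )
    labels[trunk] = 1                               # skin/fat shell
    labels[trunk_core] = 2                          # muscle bulk
    bone = ellipsoid(0.35 * trunk_ax, 0.35 * trunk_ay, 0.8 * trunk_az, trunk_az)
    labels[bone & trunk_core] = 3

    heart_c = (0.0, 0.0, 1.35 * trunk_az)
    heart_r = 0.30 * trunk_ay
    heart = (x - heart_c[0]) ** 2 + (y - heart_c[1]) ** 2 + (
        z - heart_c[2]
    ) ** 2 <= heart_r**2
    labels[heart & trunk_core] = 5

    head = x**2 + y**2 + (z - head_cz) ** 2 <= head_r**2
    brain = x**2 + y**2 + (z - head_cz) ** 2 <= max(head_r - shell, spacing) ** 2
    labels[head] = 1
    labels[brain] = 4
    return VoxelPhantom(labels, spacing, origin, table)


# ---------------------------------------------------------------------------
# I/O: raw little-endian uint16 volume + JSON sidecar
# ---------------------------------------------------------------------------

def write_phantom(phantom: VoxelPhantom, path) -> Path:
    """Write ``<stem>.raw`` (uint16, little-endian, x fastest) + JSON sidecar.

    ``path`` names the sidecar; returns its path.
    """
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    raw = path.with_suffix(".raw")
    data = np.asarray(phantom.labels, dtype="<u2")
    raw.write_bytes(data.tobytes(order="F"))
    sidecar = {
        "format": PHANTOM_FORMAT,
        "dims": list(phantom.labels.shape),
        "spacing_m": phantom.spacing,
        "origin_m": list(phantom.origin),
        "index_order": "xyz",
        "byte_order": "little",
        "dtype": "uint16",
        "raw_file": raw.name,
        "tissues": {
            str(lab): {
                "name": t.name,
                "eps_r": t.relative_permittivity,
                "sigma": t.conductivity,
                "rho": t.mass_density,
                "group": t.group,
                "is_cns": t.is_cns,
            }
            for lab, t in sorted(phantom.tissue_table.items())
        },
    }
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_phantom(path) -> VoxelPhantom:
    """Read a phantom written by :func:`write_phantom` (or a compatible sidecar)."""
    path = Path(path)
    try:
        meta = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: sidecar is not valid JSON: {e}") from e
    for key in ("dims", "spacing_m", "origin_m", "tissues"):
        if key not in meta:
            raise FormatError(f"{path}: sidecar missing required key {key!r}")
    dims = tuple(int(d) for d in meta["dims"])
    if meta.get("index_order", "xyz") != "xyz":
        raise FormatError(f"{path}: unsupported index_order {meta['index_order']!r}")
    if meta.get("byte_order", "little") != "little":
        raise FormatError(f"{path}: unsupported byte_order {meta['byte_order']!r}")
    if meta.get("dtype", "uint16") != "uint16":
        raise FormatError(f"{path}: unsupported dtype {meta['dtype']!r}")
    raw = path.parent / meta.get("raw_file", path.with_suffix(".raw").name)
    buf = raw.read_bytes()
    expected = int(np.prod(dims)) * 2
    if len(buf) != expected:
        raise FormatError(
            f"{raw}: expected {expected} bytes for dims {dims}, found {len(buf)}"
        )
    labels = np.frombuffer(buf, dtype="<u2").reshape(dims, order="F").copy()
    table = {}
    for lab, t in meta["tissues"].items():
        table[int(lab)] = TissueProperties(
            name=t["name"],
            relative_permittivity=float(t["eps_r"]),
            conductivity=float(t["sigma"]),
            mass_density=float(t["rho"]),
            group=t.get("group", "other"),
            is_cns=bool(t.get("is_cns", False)),
        )
    present = set(np.unique(labels).tolist()) - {0}
    unknown = present - set(table)
    if unknown:
        raise FormatError(
            f"{path}: labels {sorted(unknown)} present in volume but absent "
            "from the sidecar tissue map"
        )
    try:
        return VoxelPhantom(
            labels,
            float(meta["spacing_m"]),
            tuple(float(v) for v in meta["origin_m"]),
            table,
        )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
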