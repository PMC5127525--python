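"""Step 1 of the two-step method: incident (body-absent) fields and excitation.

Providers sample the quasi-static phasor electric field E = −jωA of a source
on the staggered E-node positions of the solver grid (peak amplitudes, e^{+jωt}
time convention). Under the quasi-static approximation the external field has
a single global phase, so the solver can drive the grid with the real peak
pattern of the map and a ramp excitation.

The ramp excitation (smooth cosh onset followed by a linear branch) describes
the *source strength* as a function of time; the incident electric field the
solver applies is proportional to the ramp's slope, which settles at a
constant once the linear branch is reached.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.constants import mu_0

from ._grid import Grid
from .errors import FormatError, SingularSourceError

FIELD_MAP_FORMAT = "qsdose-fieldmap-v1"

#: Dimensionless onset curvature k·(τ−t0) of the cosh branch. Any positive
#: value gives a C1 waveform; 3 keeps the onset smooth while reaching the
#: linear branch quickly.
RAMP_ONSET_CURVATURE = 3.0


# ---------------------------------------------------------------------------
# Ramp excitation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RampWaveform:
    """Modified ramp excitation: zero, smooth cosh onset on (t0, τ], then linear.

    v(t) = 0                          for t <= t0
         = β (cosh(k (t−t0)) − 1)     for t0 < t <= τ
         = α (t−τ) + v(τ)             for t > τ

    with k = RAMP_ONSET_CURVATURE / (τ−t0) and β = α / (k sinh(k(τ−t0))) so
    that value and slope are continuous everywhere; ``alpha`` (1/s) is the
    slope of the linear branch.
    """

    t0: float
    tau: float
    alpha: float

    def __post_init__(self):
        if not self.t0 < self.tau:
            raise ValueError("t0 must be < tau")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    @property
    def _k(self) -> float:
        return RAMP_ONSET_CURVATURE / (self.tau - self.t0)

    @property
    def _beta(self) -> float:
        return self.alpha / (self._k * np.sinh(RAMP_ONSET_CURVATURE))

    def value(self, t):
        t = np.asarray(t, dtype=float)
        k, beta = self._k, self._beta
        v_tau = beta * (np.cosh(RAMP_ONSET_CURVATURE) - 1.0)
        onset = beta * (np.cosh(k * np.clip(t - self.t0, 0.0, self.tau - self.t0)) - 1.0)
        out = np.where(t <= self.t0, 0.0, np.where(t <= self.tau, onset,
                                                   self.alpha * (t - self.tau) + v_tau))
        return out if out.ndim else float(out)

    def slope(self, t):
        t = np.asarray(t, dtype=float)
        k, beta = self._k, self._beta
        onset = beta * k * np.sinh(k * np.clip(t - self.t0, 0.0, self.tau - self.t0))
        out = np.where(t <= self.t0, 0.0, np.where(t <= self.tau, onset, self.alpha))
        return out if out.ndim else float(out)

    def curvature(self, t):
        """Second time derivative (1/s²); zero outside the onset branch."""
        t = np.asarray(t, dtype=float)
        k, beta = self._k, self._beta
        onset = beta * k * k * np.cosh(k * np.clip(t - self.t0, 0.0, self.tau - self.t0))
        out = np.where((t <= self.t0) | (t > self.tau), 0.0, onset)
        return out if out.ndim else float(out)


def ramp_value(w: RampWaveform, t):
    """Value of the modified ramp at time ``t`` (dimensionless)."""
    return w.value(t)


def ramp_slope(w: RampWaveform, t):
    """Exact time derivative of :func:`ramp_value` (1/s)."""
    return w.slope(t)


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis vector")
    return v / n


@dataclass(frozen=True)
class MagneticDipoleSource:
    """Point magnetic dipole: ``moment`` A·m² along ``axis`` at ``position``."""

    moment: float
    position: tuple[float, float, float]
    frequency: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        object.__setattr__(self, "axis", tuple(_unit(self.axis)))
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))

    @property
    def moment_vector(self) -> np.ndarray:
        return self.moment * np.asarray(self.axis)


@dataclass(frozen=True)
class CoilSource:
    """Multi-turn filamentary coil: a helical stack of circular loops.

    ``turns`` loops of ``diameter`` spaced ``pitch`` apart along ``axis``,
    centred at ``center``, carrying ``current`` A peak at ``frequency``.
    ``inductance``/``capacitance`` are optional lumped circuit values used
    only by :func:`resonant_frequency`.
    """

    turns: int
    diameter: float
    pitch: float
    center: tuple[float, float, float]
    frequency: float
    current: float = 1.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    inductance: float | None = None
    capacitance: float | None = None

    def __post_init__(self):
        if self.turns < 1:
            raise ValueError("turns must be >= 1")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        object.__setattr__(self, "axis", tuple(_unit(self.axis)))
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))


def resonant_frequency(inductance: float, capacitance: float) -> float:
    """Series-resonance frequency 1/(2π√(LC)) in Hz."""
    if inductance <= 0 or capacitance <= 0:
        raise ValueError("inductance and capacitance must be > 0")
    return 1.0 / (2.0 * np.pi * np.sqrt(inductance * capacitance))


# ---------------------------------------------------------------------------
# Incident field map
# ---------------------------------------------------------------------------

@dataclass
class IncidentFieldMap:
    """Phasor incident E (complex V/m, peak) on the staggered E nodes of a grid."""

    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray
    grid: Grid
    frequency: float

    def __post_init__(self):
        for comp in ("ex", "ey", "ez"):
            arr = np.asarray(getattr(self, comp), dtype=complex)
            want = self.grid.component_shape(comp)
            if arr.shape != want:
                raise ValueError(
                    f"{comp} has shape {arr.shape}, expected {want} for grid "
                    f"{self.grid.describe()}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{comp} contains non-finite values")
            setattr(self, comp, arr)
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")

    def scaled(self, factor: complex) -> "IncidentFieldMap":
        return IncidentFieldMap(
            self.ex * factor, self.ey * factor, self.ez * factor,
            self.grid, self.frequency,
        )

    def max_magnitude(self) -> float:
        return max(
            float(np.abs(self.ex).max(initial=0.0)),
            float(np.abs(self.ey).max(initial=0.0)),
            float(np.abs(self.ez).max(initial=0.0)),
        )

    def real_peak_pattern(self, phase_tol: float = 1e-6):
        """Rotate out the global phase and return real peak patterns (px, py, pz).

        Valid under the quasi-static assumption that the external field has a
        single phase everywhere; a residual imaginary part above ``phase_tol``
        of the peak triggers a warning (the map is then only approximately
        quasi-static and the residual is discarded).
        """
        scale = self.max_magnitude()
        if scale == 0.0:
            z = [np.zeros_like(self.ex, dtype=float),
                 np.zeros_like(self.ey, dtype=float),
                 np.zeros_like(self.ez, dtype=float)]
            return z[0], z[1], z[2]
        # phase of the largest-magnitude sample across the three components
        best = max(
            ((np.abs(c).max(), c) for c in (self.ex, self.ey, self.ez)),
            key=lambda t: t[0],
        )[1]
        idx = np.unravel_index(np.argmax(np.abs(best)), best.shape)
        rot = np.exp(-1j * np.angle(best[idx]))
        comps = [self.ex * rot, self.ey * rot, self.ez * rot]
        resid = max(float(np.abs(c.imag).max(initial=0.0)) for c in comps)
        if resid > phase_tol * scale:
            warnings.warn(
                f"incident map is not single-phase: residual imaginary part "
                f"{resid:.3g} of peak {scale:.3g} discarded",
                stacklevel=2,
            )
        return comps[0].real.copy(), comps[1].real.copy(), comps[2].real.copy()


# ---------------------------------------------------------------------------
# Providers
# ---------------------------------------------------------------------------

def _dipole_vector_potential(src: MagneticDipoleSource, x, y, z, min_dist):
    """Magnetostatic A of a point dipole: μ0/(4π) m×r / |r|³ (broadcastable)."""
    rx = x - src.position[0]
    ry = y - src.position[1]
    rz = z - src.position[2]
    r2 = rx**2 + ry**2 + rz**2
    rmin2 = float(np.min(r2))
    if rmin2 < min_dist**2:
        raise SingularSourceError(
            f"grid node within {np.sqrt(rmin2):.3g} m of the dipole position; "
            "the dipole field is singular there"
        )
    mx, my, mz = src.moment_vector
    inv_r3 = r2 ** (-1.5)
    pref = mu_0 / (4.0 * np.pi)
    ax = pref * (my * rz - mz * ry) * inv_r3
    ay = pref * (mz * rx - mx * rz) * inv_r3
    az = pref * (mx * ry - my * rx) * inv_r3
    return ax, ay, az


def dipole_incident_field(src: MagneticDipoleSource, grid: Grid) -> IncidentFieldMap:
    """Quasi-static phasor E = −jωA of a magnetic dipole on the grid's E nodes.

    The magnitude is ω μ0 |m| sinθ / (4π r²) at distance r and polar angle θ
    from the moment axis, azimuthal about that axis.
    """
    omega = 2.0 * np.pi * src.frequency
    comps = {}
    sel = {"ex": 0, "ey": 1, "ez": 2}
    for comp, k in sel.items():
        x, y, z = grid.component_coords(comp)
        a = _dipole_vector_potential(src, x, y, z, min_dist=1e-9)[k]
        comps[comp] = (-1j * omega) * np.broadcast_to(
            a, grid.component_shape(comp)
        ).astype(complex)
    return IncidentFieldMap(comps["ex"], comps["ey"], comps["ez"], grid, src.frequency)


def _coil_segments(src: CoilSource, segments_per_turn: int):
    """Midpoints and directed lengths of the filament segments of all loops."""
    n = segments_per_turn
    axis = np.asarray(src.axis)
    # orthonormal frame (u, v, axis)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(axis @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(axis, trial))
    v = np.cross(axis, u)
    radius = 0.5 * src.diameter
    theta_mid = 2.0 * np.pi * (np.arange(n) + 0.5) / n
    theta_end = 2.0 * np.pi * np.arange(n + 1) / n
    ring_mid = radius * (np.outer(np.cos(theta_mid), u) + np.outer(np.sin(theta_mid), v))
    ends = radius * (np.outer(np.cos(theta_end), u) + np.outer(np.sin(theta_end), v))
    ring_dl = np.diff(ends, axis=0)
    offsets = (np.arange(src.turns) - (src.turns - 1) / 2.0) * src.pitch
    center = np.asarray(src.center)
    mids = np.concatenate([ring_mid + center + off * axis for off in offsets])
    dls = np.tile(ring_dl, (src.turns, 1))
    return mids, dls


def coil_incident_field(
    src: CoilSource, grid: Grid, segments_per_turn: int = 256
) -> IncidentFieldMap:
    """Phasor E = −jωA of the multi-turn filamentary coil by segment quadrature.

    A(r) = μ0 I/(4π) Σ_s dl_s / |r − r_s| summed over ``segments_per_turn``
    straight segments per loop. Raises :class:`SingularSourceError` when a
    grid node lies within one segment length of the filament.
    """
    if segments_per_turn < 8:
        raise ValueError("segments_per_turn must be >= 8")
    mids, dls = _coil_segments(src, segments_per_turn)
    seg_len = np.pi * src.diameter / segments_per_turn
    omega = 2.0 * np.pi * src.frequency
    pref = mu_0 * src.current / (4.0 * np.pi)
    comps = {}
    for comp in ("ex", "ey", "ez"):
        x, y, z = grid.component_coords(comp)
        shape = grid.component_shape(comp)
        pts = np.stack(
            [np.broadcast_to(c, shape).ravel() for c in (x, y, z)], axis=1
        )
        a = np.zeros((pts.shape[0], 3))
        min_d = np.inf
        min_idx = 0
        chunk = 128
        for s0 in range(0, mids.shape[0], chunk):
            m = mids[s0 : s0 + chunk]
            d = dls[s0 : s0 + chunk]
            dist2 = (pts[:, 0:1] - m[:, 0]) ** 2
            dist2 += (pts[:, 1:2] - m[:, 1]) ** 2
            dist2 += (pts[:, 2:3] - m[:, 2]) ** 2
            np.sqrt(dist2, out=dist2)
            dmin = dist2.min(axis=1)
            i = int(np.argmin(dmin))
            if dmin[i] < min_d:
                min_d = float(dmin[i])
                min_idx = i
            np.reciprocal(dist2, out=dist2)
            a += dist2 @ d
        if min_d < seg_len:
            bad = pts[min_idx]
            raise SingularSourceError(
                f"{comp} node at ({bad[0]:.4g}, {bad[1]:.4g}, {bad[2]:.4g}) m "
                f"is {min_d:.3g} m from the coil filament (< segment length "
                f"{seg_len:.3g} m); refine the coil quadrature or move the grid"
            )
        a *= pref
        k = {"ex": 0, "ey": 1, "ez": 2}[comp]
        comps[comp] = ((-1j * omega) * a[:, k]).reshape(shape)
    return IncidentFieldMap(comps["ex"], comps["ey"], comps["ez"], grid, src.frequency)


def uniform_b_incident_field(
    grid: Grid,
    b0: float,
    frequency: float,
    axis=(0.0, 0.0, 1.0),
    center=(0.0, 0.0, 0.0),
) -> IncidentFieldMap:
    """Synthetic incident map of a uniform axial flux density of peak ``b0`` T.

    E = −jω (B0/2) (n̂ × r) — the vector-potential field of a uniform B along
    ``axis`` about ``center``; used by the closed-form eddy-current checks.
    """
    n = _unit(axis)
    c = np.asarray(center, dtype=float)
    omega = 2.0 * np.pi * frequency
    comps = {}
    for comp, k in (("ex", 0), ("ey", 1), ("ez", 2)):
        x, y, z = grid.component_coords(comp)
        rx, ry, rz = x - c[0], y - c[1], z - c[2]
        cross = (
            n[1] * rz - n[2] * ry,
            n[2] * rx - n[0] * rz,
            n[0] * ry - n[1] * rx,
        )[k]
        comps[comp] = (-0.5j * omega * b0) * np.broadcast_to(
            cross, grid.component_shape(comp)
        ).astype(complex)
    return IncidentFieldMap(comps["ex"], comps["ey"], comps["ez"], grid, frequency)


# ---------------------------------------------------------------------------
# Field-map I/O: raw little-endian complex128 triplet + JSON sidecar
# ---------------------------------------------------------------------------

def write_incident_field_map(fmap: IncidentFieldMap, path) -> Path:
    """Write ``<stem>_{ex,ey,ez}.raw`` (complex128, x fastest) + JSON sidecar."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    files = {}
    for comp in ("ex", "ey", "ez"):
        f = path.with_name(path.stem + f"_{comp}.raw")
        f.write_bytes(np.asarray(getattr(fmap, comp), dtype="<c16").tobytes(order="F"))
        files[comp] = f.name
    sidecar = {
        "format": FIELD_MAP_FORMAT,
        "dims": list(fmap.grid.shape),
        "spacing_m": fmap.grid.spacing,
        "origin_m": list(fmap.grid.origin),
        "frequency_hz": fmap.frequency,
        "index_order": "xyz",
        "byte_order": "little",
        "dtype": "complex128",
        "components": files,
    }
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_incident_field_map(path, grid: Grid) -> IncidentFieldMap:
    """Read a field map and check its grid metadata against ``grid``."""
    path = Path(path)
    try:
        meta = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: sidecar is not valid JSON: {e}") from e
    for key in ("dims", "spacing_m", "origin_m", "frequency_hz", "components"):
        if key not in meta:
            raise FormatError(f"{path}: sidecar missing required key {key!r}")
    file_grid = Grid(
        tuple(int(d) for d in meta["dims"]),
        float(meta["spacing_m"]),
        tuple(float(v) for v in meta["origin_m"]),
    )
    if not file_grid.matches(grid):
        raise FormatError(
            f"{path}: grid mismatch — file has {file_grid.describe()}; "
            f"phantom has {grid.describe()}"
        )
    comps = {}
    for comp in ("ex", "ey", "ez"):
        f = path.parent / meta["components"][comp]
        want = grid.component_shape(comp)
        buf = f.read_bytes()
        expected = int(np.prod(want)) * 16
        if len(buf) != expected:
            raise FormatError(
                f"{f}: expected {expected} bytes for shape {want}, found {len(buf)}"
            )
        comps[comp] = np.frombuffer(buf, dtype="<c16").reshape(want, order="F").copy()
    return IncidentFieldMap(
        comps["ex"], comps["ey"], comps["ez"], grid, float(meta["frequency_hz"])
    )
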