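"""Dosimetric metrics from a field solution and phantom.

Conventions
-----------
* Fields are stored as *peak* sinusoidal amplitudes; point SAR is therefore
  σ|E_peak|²/(2ρ).
* |E| at a voxel centre comes from component-wise averaging of the staggered
  edge samples surrounding the centre.
* Percentiles are nearest-rank (deterministic, no interpolation).
* E5mm scans the 13 axis/face-diagonal/body-diagonal directions of the cubic
  lattice with 11 equally spaced trilinear samples per 5-mm segment,
  restricted to segments that stay inside the same IEEE tissue group.
* The 10 g (or 1 g) averaging volume is a voxel-aligned cube grown around the
  target voxel until it contains the required tissue mass; air inside the
  cube contributes neither mass nor power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .phantoms import TISSUE_GROUPS, VoxelPhantom
from .solver import FieldSolution

#: The 13 unique lattice directions (3 axes, 6 face diagonals, 4 body diagonals).
_DIRECTIONS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=float,
)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)

_N_SAMPLES = 11  # samples per averaging segment


def _check_grids(solution: FieldSolution, phantom: VoxelPhantom):
    if not solution.grid.matches(phantom.grid):
        raise ValueError(
            f"field grid ({solution.grid.describe()}) does not match phantom "
            f"grid ({phantom.grid.describe()})"
        )


def field_magnitude(solution: FieldSolution) -> np.ndarray:
    """Peak |E| (V/m) at voxel centres."""
    return solution.magnitude()


def current_density(solution: FieldSolution, phantom: VoxelPhantom) -> np.ndarray:
    """Per-voxel induced current density J = σ|E| (A/m²); NaN in free space."""
    _check_grids(solution, phantom)
    _, sigma, _ = phantom.property_volumes()
    j = sigma * solution.magnitude()
    j[~phantom.tissue_mask] = np.nan
    return j


def _select_mask(
    phantom: VoxelPhantom,
    tissue: int | str | None = None,
    group: str | None = None,
    cns: bool = False,
) -> np.ndarray:
    if tissue is not None:
        if isinstance(tissue, str):
            matches = [
                lab for lab, t in phantom.tissue_table.items() if t.name == tissue
            ]
            if not matches:
                raise ValueError(f"no tissue named {tissue!r} in the phantom")
            m = np.isin(phantom.labels, matches)
        else:
            m = phantom.labels == tissue
    elif group is not None:
        if group not in TISSUE_GROUPS:
            raise ValueError(f"group {group!r} not one of {TISSUE_GROUPS}")
        m = phantom.group_volume() == TISSUE_GROUPS.index(group)
    else:
        m = phantom.tissue_mask
    if cns:
        m = m & phantom.cns_mask()
    return m


def percentile_field(
    solution: FieldSolution,
    phantom: VoxelPhantom,
    tissue: int | str | None = None,
    group: str | None = None,
    cns: bool = False,
    q: float = 99.0,
) -> float:
    """Nearest-rank q-th percentile of |E| over the selected voxels (V/m)."""
    _check_grids(solution, phantom)
    m = _select_mask(phantom, tissue, group, cns)
    vals = solution.magnitude()[m]
    if vals.size == 0:
        raise ValueError(
            f"no voxels selected (tissue={tissue!r}, group={group!r}, cns={cns})"
        )
    vals = np.sort(vals)
    rank = int(np.ceil(q / 100.0 * vals.size))  # 1-based nearest rank
    return float(vals[max(rank, 1) - 1])


def line_averaged_field(
    solution: FieldSolution,
    phantom: VoxelPhantom,
    segment_length: float = 5e-3,
):
    """Line-averaged field E5mm per voxel and the fallback flag mask.

    For each tissue voxel: the maximum over the 13 lattice directions of the
    mean |E| along a ``segment_length`` segment centred on the voxel, keeping
    only segments whose samples all stay inside tissue of the same IEEE
    group. Voxels with no admissible segment fall back to the voxel |E| and
    are flagged. Returns ``(e5mm, flagged)`` arrays (NaN / False outside
    tissue).
    """
    _check_grids(solution, phantom)
    h = phantom.spacing
    if segment_length < h:
        raise ValueError("segment_length must be at least the voxel spacing")
    mag = solution.magnitude()
    group = phantom.group_volume().astype(float)  # -1 in free space
    mask = phantom.tissue_mask
    centers = np.array(np.nonzero(mask), dtype=float)  # (3, N) voxel indices
    own_group = group[mask]
    offsets = (np.linspace(0.0, 1.0, _N_SAMPLES) - 0.5) * (segment_length / h)

    best = np.full(centers.shape[1], -np.inf)
    admissible = np.zeros(centers.shape[1], dtype=bool)
    for d in _DIRECTIONS:
        # (3, N, S) fractional voxel-index coordinates of the samples
        coords = centers[:, :, None] + d[:, None, None] * offsets[None, None, :]
        flat = coords.reshape(3, -1)
        g = map_coordinates(group, flat, order=0, mode="constant", cval=-1.0)
        g = g.reshape(-1, _N_SAMPLES)
        ok = np.all(g == own_group[:, None], axis=1)
        if not ok.any():
            continue
        v = map_coordinates(mag, flat, order=1, mode="nearest")
        means = v.reshape(-1, _N_SAMPLES).mean(axis=1)
        means[~ok] = -np.inf
        best = np.maximum(best, means)
        admissible |= ok

    e5 = np.full(phantom.labels.shape, np.nan)
    flagged = np.zeros(phantom.labels.shape, dtype=bool)
    vals = np.where(admissible, best, mag[mask])
    e5[mask] = vals
    fl = np.zeros(centers.shape[1], dtype=bool)
    fl[~admissible] = True
    flagged[mask] = fl
    return e5, flagged


def point_sar(solution: FieldSolution, phantom: VoxelPhantom) -> np.ndarray:
    """Point SAR = σ|E_peak|²/(2ρ) (W/kg); NaN in free space."""
    _check_grids(solution, phantom)
    _, sigma, rho = phantom.property_volumes()
    with np.errstate(divide="ignore", invalid="ignore"):
        sar = sigma * solution.magnitude() ** 2 / (2.0 * rho)
    sar[~phantom.tissue_mask] = np.nan
    return sar


def whole_mass_sar(solution: FieldSolution, phantom: VoxelPhantom) -> float:
    """Whole-mass average SAR: total absorbed power / total tissue mass (W/kg)."""
    _check_grids(solution, phantom)
    _, sigma, rho = phantom.property_volumes()
    mask = phantom.tissue_mask
    vol = phantom.spacing**3
    power = 0.5 * (sigma * solution.magnitude() ** 2)[mask].sum() * vol
    mass = rho[mask].sum() * vol
    if mass == 0:
        raise ValueError("phantom has no tissue mass")
    return float(power / mass)


def averaged_sar(
    solution: FieldSolution,
    phantom: VoxelPhantom,
    mass: float = 0.010,
):
    """Cube-averaged SAR per voxel for a target tissue ``mass`` in kg.

    Grows a voxel-aligned cube (side +2 voxels per step) centred on each
    tissue voxel until the tissue mass inside reaches ``mass``; the averaged
    SAR is the absorbed power over the tissue mass in that cube. Voxels whose
    cube would leave the domain before reaching the mass are flagged invalid
    (NaN) and must be excluded from maxima. Returns ``(sar_avg, valid)``.
    """
    _check_grids(solution, phantom)
    if mass <= 0:
        raise ValueError("mass must be > 0")
    _, sigma, rho = phantom.property_volumes()
    if phantom.total_mass() < mass:
        raise ValueError(
            f"phantom mass {phantom.total_mass():.4g} kg < averaging mass {mass:g} kg"
        )
    vol = phantom.spacing**3
    mass_vox = rho * vol
    power_vox = 0.5 * sigma * solution.magnitude() ** 2 * vol

    # inclusive 3-D prefix sums, zero-padded at the front
    def prefix(a):
        p = np.zeros(tuple(s + 1 for s in a.shape))
        p[1:, 1:, 1:] = a.cumsum(0).cumsum(1).cumsum(2)
        return p

    pm, pp = prefix(mass_vox), prefix(power_vox)

    def box_sum(p, lo, hi):
        # sum over voxels [lo, hi) per axis; lo/hi are (N,3) int arrays
        s = np.zeros(lo.shape[0])
        for sx, cx in ((1, hi[:, 0]), (-1, lo[:, 0])):
            for sy, cy in ((1, hi[:, 1]), (-1, lo[:, 1])):
                for sz, cz in ((1, hi[:, 2]), (-1, lo[:, 2])):
                    s += sx * sy * sz * p[cx, cy, cz]
        return s

    mask = phantom.tissue_mask
    idx = np.array(np.nonzero(mask)).T  # (N, 3)
    n = idx.shape[0]
    out = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    remaining = np.ones(n, dtype=bool)
    dims = np.array(phantom.labels.shape)
    half = 0
    while remaining.any() and half <= int(dims.max()):
        lo = idx - half
        hi = idx + half + 1
        inside = np.all(lo >= 0, axis=1) & np.all(hi <= dims, axis=1)
        active = remaining & inside
        if active.any():
            m = box_sum(pm, lo[active], hi[active])
            done_sel = np.nonzero(active)[0][m >= mass]
            if done_sel.size:
                p = box_sum(pp, lo[done_sel], hi[done_sel])
                out[done_sel] = p / box_sum(pm, lo[done_sel], hi[done_sel])
                valid[done_sel] = True
                remaining[done_sel] = False
        # a cube that has left the domain can only keep growing outside it:
        # those voxels can never reach the mass and stay flagged invalid
        remaining &= inside
        half += 1

    sar_avg = np.full(phantom.labels.shape, np.nan)
    ok = np.zeros(phantom.labels.shape, dtype=bool)
    sar_avg[mask] = out
    ok[mask] = valid
    return sar_avg, ok


def maximum_allowable_power(
    metric: float, limit: float, p_ref: float, scaling: str
) -> float:
    """Maximum allowable source power for a metric computed at ``p_ref`` watts.

    Internal fields scale as √P (``scaling='field'``: J, E99, E5mm), SAR
    scales as P (``scaling='power'``).
    """
    if metric <= 0:
        raise ValueError("metric must be > 0 to extrapolate a power limit")
    if p_ref <= 0:
        raise ValueError("reference power must be > 0")
    if scaling == "field":
        return p_ref * (limit / metric) ** 2
    if scaling == "power":
        return p_ref * (limit / metric)
    raise ValueError(f"scaling must be 'field' or 'power', got {scaling!r}")


# ---------------------------------------------------------------------------
# Dose report
# ---------------------------------------------------------------------------

@dataclass
class DoseReport:
    """Whole-body and per-tissue dosimetric summary at a stated input power.

    Scalar entries mirror the usual reporting: maximum J over tissue voxels
    (with the tissue it occurs in), maximum per-tissue E99, maximum E5mm per
    IEEE group, maximum 1 g / 10 g cube-averaged SAR, whole-mass SAR, and the
    CNS-restricted variants.
    """

    frequency: float
    input_power: float
    j_max: float
    j_max_tissue: str
    e99: float
    e99_tissue: str
    e5mm: float
    e5mm_tissue: str
    e5mm_groups: dict[str, float]
    sar_1g: float
    sar_1g_tissue: str
    sar_10g: float
    sar_10g_tissue: str
    sar_10g_head_trunk: float
    sar_10g_limbs: float | None
    sar_wm: float
    j_cns: float | None = None
    j_cns_tissue: str | None = None
    e99_cns: float | None = None
    e99_cns_tissue: str | None = None
    e5mm_cns: float | None = None
    per_tissue: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "per_tissue" and not isinstance(v, pd.DataFrame)
        }
        if self.per_tissue is not None:
            d["per_tissue"] = self.per_tissue.to_dict(orient="records")
        return d


def _tissue_max(arr: np.ndarray, phantom: VoxelPhantom, mask=None):
    """(max value, tissue name) of ``arr`` over tissue voxels (NaN-aware)."""
    m = phantom.tissue_mask if mask is None else mask
    vals = np.where(m, arr, np.nan)
    if not np.isfinite(vals).any():
        return 0.0, ""
    flat = np.nanargmax(vals)
    ijk = np.unravel_index(flat, arr.shape)
    lab = int(phantom.labels[ijk])
    return float(vals[ijk]), phantom.tissue_table[lab].name


def compute_dose_report(
    solution: FieldSolution,
    phantom: VoxelPhantom,
    frequency: float,
    input_power: float = 1.0,
    e5mm_segment: float | None = None,
) -> DoseReport:
    """Evaluate every dosimetric metric on a solved field.

    ``e5mm_segment`` defaults to the larger of 5 mm and the voxel spacing:
    on grids coarser than the nominal 5 mm segment the line average
    degenerates to a single-voxel sample, so the report widens the segment
    to one voxel instead.
    """
    _check_grids(solution, phantom)
    if e5mm_segment is None:
        e5mm_segment = max(5e-3, phantom.spacing)
    mag = solution.magnitude()
    j = current_density(solution, phantom)
    e5, _ = line_averaged_field(solution, phantom, segment_length=e5mm_segment)
    sar1, ok1 = averaged_sar(solution, phantom, mass=0.001)
    sar10, ok10 = averaged_sar(solution, phantom, mass=0.010)
    cns = phantom.cns_mask()
    group_vol = phantom.group_volume()

    j_max, j_tis = _tissue_max(j, phantom)
    e5_max, e5_tis = _tissue_max(e5, phantom)
    sar1_max, sar1_tis = _tissue_max(np.where(ok1, sar1, np.nan), phantom)
    sar10_max, sar10_tis = _tissue_max(np.where(ok10, sar10, np.nan), phantom)

    limbs_idx = TISSUE_GROUPS.index("limbs")
    head_trunk = phantom.tissue_mask & (group_vol != limbs_idx)
    limbs = phantom.tissue_mask & (group_vol == limbs_idx)
    sar10_ht, _ = _tissue_max(np.where(ok10, sar10, np.nan), phantom, head_trunk)
    sar10_limbs = (
        _tissue_max(np.where(ok10, sar10, np.nan), phantom, limbs)[0]
        if limbs.any()
        else None
    )

    # per-tissue table; E99 is a per-tissue metric, report its max over tissues
    rows = []
    for lab, t in sorted(phantom.tissue_table.items()):
        m = phantom.labels == lab
        if not m.any():
            continue
        rows.append(
            {
                "label": lab,
                "tissue": t.name,
                "group": t.group,
                "is_cns": t.is_cns,
                "voxels": int(m.sum()),
                "J_max": float(np.nanmax(np.where(m, j, np.nan))),
                "E99": percentile_field(solution, phantom, tissue=lab),
                "E5mm_max": float(np.nanmax(np.where(m, e5, np.nan))),
                "SAR_1g_max": float(np.nanmax(np.where(m & ok1, sar1, np.nan)))
                if (m & ok1).any()
                else np.nan,
                "SAR_10g_max": float(np.nanmax(np.where(m & ok10, sar10, np.nan)))
                if (m & ok10).any()
                else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    best_e99 = table.loc[table["E99"].idxmax()]

    e5mm_groups = {}
    for gname in TISSUE_GROUPS:
        gm = group_vol == TISSUE_GROUPS.index(gname)
        if gm.any():
            e5mm_groups[gname] = float(np.nanmax(np.where(gm, e5, np.nan)))

    report = DoseReport(
        frequency=frequency,
        input_power=input_power,
        j_max=j_max,
        j_max_tissue=j_tis,
        e99=float(best_e99["E99"]),
        e99_tissue=str(best_e99["tissue"]),
        e5mm=e5_max,
        e5mm_tissue=e5_tis,
        e5mm_groups=e5mm_groups,
        sar_1g=sar1_max,
        sar_1g_tissue=sar1_tis,
        sar_10g=sar10_max,
        sar_10g_tissue=sar10_tis,
        sar_10g_head_trunk=sar10_ht,
        sar_10g_limbs=sar10_limbs,
        sar_wm=whole_mass_sar(solution, phantom),
        per_tissue=table,
    )
    if cns.any():
        report.j_cns, report.j_cns_tissue = _tissue_max(j, phantom, cns)
        cns_tissues = table[table["is_cns"]]
        best = cns_tissues.loc[cns_tissues["E99"].idxmax()]
        report.e99_cns = float(best["E99"])
        report.e99_cns_tissue = str(best["tissue"])
        report.e5mm_cns = _tissue_max(e5, phantom, cns)[0]
    return report
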