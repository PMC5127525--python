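"""Analytic interior field of a homogeneous lossy sphere in a dipole's near field.

Ground truth for solver validation. In the quasi-static regime (body size ≪
wavelength and ≪ skin depth) the interior electric field of a homogeneous
sphere exposed to an external magnetic dipole is

    E = −jω (A + ∇ψ),

where A is the magnetostatic vector potential of the dipole and ψ solves the
interior Neumann problem ∇²ψ = 0, ∂ψ/∂r|_{r=a} = −A·r̂|_{r=a}, which enforces
vanishing normal current at the surface (the exterior displacement current is
smaller by ~ωε0/|σ+jωε| and is neglected). ψ is expanded in spherical
harmonics about the sphere centre, truncated at a configurable order with
automatic doubling until convergence. For a dipole on the axis through the
sphere centre with an axial moment, A·r̂ ≡ 0 and the correction vanishes
identically; off-axis placements exercise the full expansion.

The material properties drop out of the interior solution for a homogeneous
sphere (they only set the neglected boundary correction); they are kept on
:class:`SphereProblem` as part of the problem description.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import roots_legendre, sph_harm_y_all

from .incident import MagneticDipoleSource, _dipole_vector_potential


@dataclass(frozen=True)
class SphereProblem:
    """Homogeneous lossy sphere exposed to an external magnetic dipole."""

    radius: float
    relative_permittivity: float
    conductivity: float
    source: MagneticDipoleSource
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    truncation_order: int = 20

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.truncation_order < 1:
            raise ValueError("truncation order must be >= 1")
        d = np.linalg.norm(np.asarray(self.source.position) - np.asarray(self.center))
        if d <= self.radius:
            raise ValueError("dipole must lie strictly outside the sphere")


def uniform_field_sphere(
    radius: float,
    conductivity: float,
    frequency: float,
    b0: float,
    points,
    axis=(0.0, 0.0, 1.0),
    center=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Closed-form eddy field of a homogeneous sphere in a uniform axial B.

    E = −jπf B0 (n̂ × r); peak magnitude π f B0 r⊥ with r⊥ the perpendicular
    distance from the axis. The radius only bounds the evaluation domain and
    the conductivity drops out (kept for the problem description).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center)
    if np.any(np.linalg.norm(pts, axis=1) > radius * (1 + 1e-9)):
        raise ValueError("all points must lie inside the sphere")
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    return -1j * np.pi * frequency * b0 * np.cross(np.broadcast_to(n, pts.shape), pts)


# ---------------------------------------------------------------------------
# Spherical-harmonic Neumann correction
# ---------------------------------------------------------------------------

def _spherical_angles(pts: np.ndarray):
    r = np.linalg.norm(pts, axis=1)
    r_safe = np.where(r > 0, r, 1.0)
    theta = np.arccos(np.clip(pts[:, 2] / r_safe, -1.0, 1.0))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    return r, theta, phi


def _neumann_coefficients(problem: SphereProblem, order: int) -> np.ndarray:
    """Expand g(θ,φ) = −A_r(a) in orthonormal spherical harmonics up to ``order``.

    Returns a complex array ``g[l, m]`` (m wraps negatively, matching the
    layout of :func:`scipy.special.sph_harm_y_all`). Quadrature:
    Gauss-Legendre in cosθ × uniform trapezoid in φ, sized generously beyond
    the truncation so the smooth (geometrically decaying) data is integrated
    exactly at every retained degree.
    """
    a = problem.radius
    n_theta = order + 26
    n_phi = 2 * n_theta
    xg, wg = roots_legendre(n_theta)
    theta = np.arccos(xg)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    st = np.sin(tt)
    pts = a * np.stack(
        [st * np.cos(pp), st * np.sin(pp), np.cos(tt) * np.ones_like(pp)], axis=-1
    )
    shifted = pts + np.asarray(problem.center)
    ax, ay, az = _dipole_vector_potential(
        problem.source, shifted[..., 0], shifted[..., 1], shifted[..., 2], min_dist=1e-9
    )
    rhat = pts / a
    g = -(ax * rhat[..., 0] + ay * rhat[..., 1] + az * rhat[..., 2])
    weight = (2.0 * np.pi / n_phi) * wg[:, None]
    y = sph_harm_y_all(order, order, tt, pp)  # (order+1, 2·order+1, nθ, nφ)
    return np.einsum("tp,lmtp->lm", g * weight, np.conj(y))


def _psi(problem: SphereProblem, coeffs: np.ndarray, order: int,
         pts: np.ndarray) -> np.ndarray:
    """Interior harmonic ψ = Σ (a/l) g_lm (r/a)^l Y_lm at ``pts`` (sphere frame).

    Only degrees 1..``order`` of the coefficient table are summed.
    """
    a = problem.radius
    r, theta, phi = _spherical_angles(pts)
    y = sph_harm_y_all(order, order, theta, phi)  # (order+1, 2·order+1, N)
    rr = r / a
    ls = np.arange(1, order + 1)
    radial = rr[None, :] ** ls[:, None] * (a / ls)[:, None]  # (order, N)
    # reduce the coefficient table to the wrapped m-layout of this order
    c = np.concatenate(
        [coeffs[1 : order + 1, : order + 1], coeffs[1 : order + 1, -order:]],
        axis=1,
    )
    terms = np.einsum("lm,lmp->lp", c, y[1 : order + 1])
    return np.einsum("lp,lp->p", terms, radial.astype(complex))


def _grad_psi(problem: SphereProblem, coeffs: np.ndarray, order: int,
              pts: np.ndarray) -> np.ndarray:
    """∇ψ by central differences (ψ is a smooth truncated harmonic polynomial)."""
    h = 1e-5 * problem.radius
    stencil = np.concatenate(
        [pts + h * np.eye(3)[k] for k in range(3)]
        + [pts - h * np.eye(3)[k] for k in range(3)]
    )
    vals = _psi(problem, coeffs, order, stencil)
    n = pts.shape[0]
    grad = np.empty(pts.shape, dtype=complex)
    for k in range(3):
        grad[:, k] = (vals[k * n : (k + 1) * n] - vals[(3 + k) * n : (4 + k) * n]) / (
            2 * h
        )
    return grad


def sphere_interior_field(problem: SphereProblem, points) -> np.ndarray:
    """Interior phasor E (complex, peak V/m) at ``points`` (N, 3 world metres).

    The truncation order doubles automatically until the field changes by less
    than 1e-4 in relative max norm; a warning reports both values if the cap
    is hit without convergence.
    """
    pts_world = np.atleast_2d(np.asarray(points, dtype=float))
    pts = pts_world - np.asarray(problem.center)
    r = np.linalg.norm(pts, axis=1)
    if np.any(r > problem.radius * (1 + 1e-9)):
        bad = pts_world[int(np.argmax(r))]
        raise ValueError(f"point {bad} lies outside the sphere")
    omega = 2.0 * np.pi * problem.source.frequency
    ax, ay, az = _dipole_vector_potential(
        problem.source, pts_world[:, 0], pts_world[:, 1], pts_world[:, 2], min_dist=1e-9
    )
    a_vec = np.stack([ax, ay, az], axis=1).astype(complex)

    if problem.source.moment == 0.0:
        return np.zeros_like(a_vec)

    # A·r̂ on the sphere is proportional to (m × p)·r̂ (p = dipole offset from
    # the centre): for a coaxial dipole the Neumann data vanishes identically
    # and no correction is needed.
    p_off = np.asarray(problem.source.position) - np.asarray(problem.center)
    mxp = np.cross(problem.source.moment_vector, p_off)
    if np.linalg.norm(mxp) < 1e-12 * abs(problem.source.moment) * np.linalg.norm(
        p_off
    ):
        return -1j * omega * a_vec

    order = problem.truncation_order
    hi = 2 * order
    coeffs = _neumann_coefficients(problem, hi)

    max_order = 128
    grad_lo = _grad_psi(problem, coeffs, order, pts)
    while True:
        grad_hi = _grad_psi(problem, coeffs, hi, pts)
        scale = float(np.abs(a_vec + grad_hi).max())
        change = float(np.abs(grad_hi - grad_lo).max())
        if change <= 1e-4 * scale:
            break
        if hi >= max_order:
            warnings.warn(
                f"harmonic correction not converged at order {hi}: "
                f"last change {change:.3g} vs field scale {scale:.3g}",
                stacklevel=2,
            )
            break
        order, hi = hi, 2 * hi
        coeffs = _neumann_coefficients(problem, hi)
        grad_lo = grad_hi
    return -1j * omega * (a_vec + grad_hi)
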