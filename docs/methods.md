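# Methods

## The two-step quasi-static method

At WPT frequencies the body is electrically small (at 150 kHz, λ ≈ 2 km) and
the exposure problem is quasi-static: the field outside the body has a
single phase, and the internal field is proportional to the time derivative
of the incident field. `qsdose` exploits this in two steps.

**Step 1 — incident field.** The phasor electric field of the source with
the body absent, E_inc = −jωA (peak amplitude, e^{+jωt} convention), is
sampled at the staggered E-node positions of the Yee grid. A is the
magnetostatic vector potential: the point-dipole closed form, a fixed-order
segment quadrature over a helical stack of filamentary loops for coils
(default 256 segments per turn; doubling changes the field by <0.01% in the
validation), the analytic A = (B0/2)(n̂×r) for synthetic uniform-B maps, or
an imported map from any external solver on the same grid.

**Step 2 — scattered-field QS-FDTD.** Total fields are split into incident
plus scattered; only the scattered fields are time-stepped:

    μ0 ∂H_s/∂t = −∇×E_s
    ε ∂E_s/∂t + σ E_s = ∇×H_s − (ε−ε0) ∂E_inc/∂t − σ E_inc

Because tissue is non-magnetic the H update needs no incident-field term:
the whole drive enters through the incident *electric* field. The update
coefficients are the standard lossy-dielectric pair
ca = (2ε−σΔt)/(2ε+σΔt), cb = 2Δt/(2ε+σΔt), with (ε, σ) arithmetic-averaged
over the (up to) four voxels sharing each E edge; out-of-domain neighbours
count as free space. Δt defaults to the Courant limit Δx/(√3·c) with
c = 3×10⁸ m/s (the rounded value that reproduces the quoted 0.38 ps at
Δx = 0.2 mm and the 5773-fold speedup arithmetic).

## Excitation and the peak-equivalence convention

The excitation is the modified ramp

    v(t) = 0                        t ≤ t0
         = β(cosh(k(t−t0)) − 1)     t0 < t ≤ τ
         = α(t−τ) + v(τ)            t > τ

with k(τ−t0) = 3 (a fixed dimensionless onset curvature) and
β = α/(k·sinh(k(τ−t0))) so value and slope are continuous everywhere;
τ−t0 defaults to 100 Δt. The ramp describes the **source strength** m(t):
the incident electric field the solver applies is its normalized derivative,

    E_inc(r,t) = P(r) · v′(t)/α ,

where P is the real peak pattern of the phasor map (the single global phase
of the quasi-static external field is rotated out; a residual imaginary part
above 10⁻⁶ of the peak raises a warning). After the onset, E_inc is constant
at P while the implied source flux grows linearly — exactly the regime in
which external fields change linearly and internal fields are constant. The
steady internal total field then *is* the peak sinusoidal internal field,
because the interior eddy response to the constant dB/dt equals the response
to the sinusoid's peak dB/dt = ω·B̂.

Driving the incident electric field itself with the ramp (rather than its
slope) would be correct only for conservative (charge-coupled) exposures;
for solenoidal magnetic coupling it makes the interior response grow without
bound. The implemented convention sacrifices the purely capacitive part of
the response, which is smaller by ~ωε0/σ (≈5×10⁻⁵ for the verification
sphere) and negligible for the magnetic near-field sources this package
targets. The convention is not assumed: it is validated against the analytic
sphere solution and the π·f·B0·r⊥ closed form in the test suite.

## Convergence criterion

The solver monitors the maximum tissue-voxel |E_total| (voxel-centre
interpolated) every 10 steps and declares steady state when the monitored
value varies by less than 0.01% (relative) over a trailing 100-step window.
The published account of this method reports steady state without stating a
criterion; the 0.01% default was chosen because the slowest interior
transients (magnetic diffusion μ0σa² and charge relaxation ε/σ) have a small
signature on the surface-dominated maximum, and a looser 0.1% window stops
~600 steps early with a ~1% residual interior transient — incompatible with
the sub-1% interior accuracy the method is known to achieve. With the
default, the 50 mm verification sphere converges in 1460 steps and the
100 mm geometry in 1830, matching the reported ~2000-step scale.
Non-convergence within `max_steps` raises an error carrying the monitor
trace.

## Boundary condition

First-order Mur on the tangential scattered E at all six faces, with at
least 10 free-space padding voxels required around the tissue (checked at
solve time). Scattered fields are small and decay quasi-statically, so in
steady state Mur-1 reduces to a zero-normal-gradient condition whose
residual error is absorbed in the validated error budget; a PML is not
implemented and the configuration rejects it explicitly.

## Analytic sphere oracle

For a homogeneous sphere of radius a exposed to an external magnetic dipole,
the quasi-static interior field is E = −jω(A + ∇ψ) where ψ solves the
interior Neumann problem ∂ψ/∂r|_a = −A·r̂|_a (vanishing normal current; the
exterior displacement coupling is smaller by ~ωε0/|σ̂| ≈ 5×10⁻⁵ here). On the
sphere surface A·r̂ ∝ (m×p)·r̂, so a coaxial dipole (moment along the
centre-to-dipole axis, the verification geometry) needs no correction and
the oracle is the closed form E = −jωA. Off-axis placements expand the
Neumann data in orthonormal spherical harmonics (Gauss–Legendre × trapezoid
quadrature sized beyond the truncation), starting at order 20 and doubling
until the field changes by <10⁻⁴ relative, capped at order 128 with a
warning. ∇ψ is evaluated by central differences with h = 10⁻⁵a on the smooth
truncated harmonic sum.

The oracle is quasi-static: it omits the secondary induction correction of
order (a/δ)² (skin depth δ; ≈0.8% at a = 100 mm, ≈0.2% at 50 mm for εr=40,
σ=1 S/m, 1 MHz), which the FDTD solve *does* capture. This is part of the
validation error budget, and one reason the scaled 50 mm geometry is used
for the routine checks.

## Dosimetric metrics

* Voxel-centre field: each Cartesian component is the mean of the four
  staggered edge samples surrounding the centre; |E| is the vector norm.
  Fields are stored as **peak** amplitudes, so point SAR = σ|E|²/(2ρ). The
  peak-vs-RMS choice changes SAR by 2× and is stated here prominently
  because published tables often leave it implicit.
* E99: nearest-rank percentile (deterministic, interpolation-free) of |E|
  over a tissue's voxels; reported per tissue with CNS-restricted variants.
* E5mm: for each tissue voxel, the maximum over the 13 lattice directions
  (3 axes, 6 face diagonals, 4 body diagonals) of the mean of 11 equally
  spaced trilinear samples along a 5-mm segment centred on the voxel,
  restricted to segments whose samples stay inside the same IEEE tissue
  group (brain / heart / limbs / other). Voxels with no admissible segment
  fall back to the voxel value and are flagged. On grids coarser than 5 mm
  the dose report widens the segment to one voxel spacing (the line average
  degenerates below that).
* SAR_1g / SAR_10g: a voxel-aligned cube grown in side +2 voxel steps around
  each tissue voxel until the contained tissue mass reaches the target;
  average = absorbed power over tissue mass in the cube. Air inside the cube
  contributes neither mass nor power; voxels whose cube leaves the domain
  before reaching the mass are flagged invalid and excluded from maxima.
  Maxima are reported for head-and-trunk vs limbs groups (IEEE limit split).
* MAP: for a metric computed at reference power P_ref, the maximum allowable
  power is P_ref·(limit/metric)² for field metrics (internal fields scale as
  √P) and P_ref·(limit/metric) for SAR (scales as P).

## Guideline limits

General-public basic restrictions only, refused outside each guideline's
validity band rather than extrapolated: ICNIRP 1998 J = f/500 mA/m²
(100 kHz–10 MHz), ICNIRP 2010 E99 = 1.35×10⁻⁴·f V/m, IEEE E5mm =
coefficient · f/f_e per tissue group (100 kHz–5 MHz; brain 5.89×10⁻³·f/20,
heart 0.943·f/167, limbs 2.1·f/3350, other 0.701·f/3350 V/m), and the
band-constant SAR limits 2 / 4 / 0.08 W/kg (10 g head-and-trunk, 10 g limbs,
whole-mass). At 150 kHz these evaluate to 0.3 A/m², 20.25 V/m, 44.175 /
847.006 / 94.0299 / 31.3881 V/m — the regression the test suite pins
exactly.

## Synthetic phantoms: what they do and do not show

* **Verification sphere** — homogeneous εr=40, σ=1 S/m, ρ=1000 kg/m³ sphere
  voxelized by voxel-centre membership on a 2 mm grid (staircase surfaces
  accepted, as in voxel-model practice). Defaults reproduce the published
  verification geometry (100 mm radius, z-polarized dipole on the axis at
  400 mm, 1 MHz); the routine checks use the 50 mm variant at the same
  electrical contrast and grid, which runs in ~30 s.
* **Stylized body** — a deterministic layered ellipsoid trunk with skin/fat
  shell, muscle bulk, bone core, a heart blob, and a spherical head with a
  CNS-flagged brain. Tissue values are generic and non-authoritative:
  conductivities and densities of realistic 100–200 kHz magnitude, with
  permittivities kept at the low end of the dispersive range so that
  σ/(ωε) ≫ 1 — inside the conduction-dominated regime the quasi-static
  method assumes (at the full Gabriel-model permittivities of some tissues,
  ωε/σ reaches ~0.1 and the charge-relaxation transient ε/σ stretches over
  thousands of time steps; the method's accuracy claim is for the
  conduction-dominated limit either way). Cole–Cole evaluation
  (`cole_cole_permittivity`) is provided for users who supply their own
  dispersion parameters.

Passing tests on these fixtures demonstrate the correctness of the solver,
metrics and compliance machinery — not anatomical fidelity. Absolute dose
values for a real human require a segmented anatomical model (pluggable via
the phantom format) and authoritative tissue properties at the exposure
frequency.

## Problem sizes and numerical defaults

The test suite and the acceptance script run desk-scale problems chosen to
exercise the same physics at small cost: the 50 mm verification sphere
(72³ grid, ~66k tissue voxels, 1460 steps), a 20 mm sphere for the
uniform-field closed form, and a 1.0 m / 20 mm stylized body for the
end-to-end pipeline (regression-pinned). The full published geometry
(100 mm sphere, 122³ grid) runs unchanged through the same fixtures in
~6 minutes and was used to confirm the same error behaviour (0.055% median,
1.09% maximum-field error, 1830 steps).

Other defaults: monitor stride 10 steps; convergence window 100 steps;
ramp τ−t0 = 100 Δt; Mur padding ≥10 voxels; double precision throughout;
no randomness anywhere (identical inputs give bit-identical outputs).

## Known limitations

* Capacitive (charge-coupled) exposure paths are outside the excitation
  convention (see above); use a conservative-field solver for power-line
  style exposures.
* The filamentary coil model has no wire radius, skin/proximity effects,
  ferrite shielding or receiving-coil load; circuit values enter only
  through the resonance helper 1/(2π√(LC)). (The published coil's
  L = 0.412 µH and C = 0.273 nF resonate near 15 MHz, not the stated
  150 kHz; the package exposes the arithmetic and leaves consistent values
  to the user.)
* Frequency-dependent dispersion within a single run, magnetic materials,
  and anisotropic tissues are unsupported.
* Mur-1 is the only boundary; accuracy was validated for quasi-static
  scattered fields with ≥10 padding voxels, not for radiating problems.
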