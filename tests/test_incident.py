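"""Ramp waveform, incident-field providers, and field-map I/O."""

import numpy as np
import pytest
from scipy.constants import mu_0

from qsdose import (
    CoilSource,
    FormatError,
    MagneticDipoleSource,
    RampWaveform,
    SingularSourceError,
    coil_incident_field,
    dipole_incident_field,
    ramp_slope,
    ramp_value,
    read_incident_field_map,
    resonant_frequency,
    uniform_b_incident_field,
    write_incident_field_map,
)
from qsdose._grid import Grid


class TestRampWaveform:
    W = RampWaveform(t0=1e-9, tau=11e-9, alpha=2 * np.pi * 1e6)

    def test_zero_before_and_at_start(self):
        assert ramp_value(self.W, self.W.t0) == 0.0
        assert ramp_value(self.W, self.W.t0 - 1e-9) == 0.0
        assert ramp_slope(self.W, self.W.t0) == 0.0

    def test_linear_branch_gains_exactly_one_per_inverse_alpha(self):
        w = self.W
        assert ramp_value(w, w.tau + 1.0 / w.alpha) - ramp_value(w, w.tau) == (
            pytest.approx(1.0, rel=1e-12)
        )

    def test_slope_matches_finite_difference(self):
        """Central difference with h = 1e-6·τ agrees to 1e-6 relative."""
        w = self.W
        h = 1e-6 * w.tau
        for t in (w.t0 + 2e-9, 0.5 * (w.t0 + w.tau), w.tau - 1e-9,
                  w.tau + 1e-9, w.tau + 5e-9):
            fd = (ramp_value(w, t + h) - ramp_value(w, t - h)) / (2 * h)
            assert ramp_slope(w, t) == pytest.approx(fd, rel=1e-6)

    def test_value_and_slope_continuous_at_tau(self):
        w = self.W
        eps = 1e-6 * (w.tau - w.t0)
        assert ramp_value(w, w.tau + eps) == pytest.approx(
            ramp_value(w, w.tau - eps), rel=1e-4
        )
        assert ramp_slope(w, w.tau + eps) == pytest.approx(
            ramp_slope(w, w.tau - eps), rel=1e-4
        )
        assert ramp_slope(w, w.tau) == pytest.approx(w.alpha, rel=1e-12)

    def test_curvature_is_slope_derivative(self):
        w = self.W
        h = 1e-7 * w.tau
        t = 0.5 * (w.t0 + w.tau)
        fd = (ramp_slope(w, t + h) - ramp_slope(w, t - h)) / (2 * h)
        assert w.curvature(t) == pytest.approx(fd, rel=1e-5)

    def test_validation(self):
        with pytest.raises(ValueError):
            RampWaveform(t0=1e-9, tau=1e-9, alpha=1.0)
        with pytest.raises(ValueError):
            RampWaveform(t0=0.0, tau=1e-9, alpha=0.0)


class TestDipoleField:
    GRID = Grid((12, 12, 12), 0.002, (-0.012, -0.012, -0.012))
    SRC = MagneticDipoleSource(2.0, (0.0, 0.0, 0.1), 1e6)

    def test_zero_on_moment_axis(self):
        """sinθ factor: E vanishes on the dipole axis."""
        fmap = dipole_incident_field(self.SRC, self.GRID)
        # Ez nodes on the z axis (x=y=0): those at i=j=6 sit at x=y=0
        on_axis = np.abs(fmap.ez[6, 6, :])
        assert np.all(on_axis < 1e-12 * fmap.max_magnitude())

    def test_inverse_square_falloff(self):
        """Near-zone |E| drops 4× when the distance doubles at fixed θ=90°."""
        omega = 2 * np.pi * self.SRC.frequency

        def mag_at(r):
            # θ=90°: point in the dipole's equatorial plane
            expected = omega * mu_0 * self.SRC.moment / (4 * np.pi * r**2)
            return expected

        assert mag_at(0.2) / mag_at(0.4) == pytest.approx(4.0, rel=1e-12)
        # and the sampled map agrees with the closed form at a node
        fmap = dipole_incident_field(self.SRC, self.GRID)
        x, y, z = self.GRID.component_coords("ey")
        i, j, k = 2, 1, 6  # well off the dipole axis
        pos = np.array([x[i, 0, 0], y[0, j, 0], z[0, 0, k]])
        rvec = pos - np.asarray(self.SRC.position)
        r = np.linalg.norm(rvec)
        sin_theta = np.linalg.norm(rvec[:2]) / r
        expected = omega * mu_0 * self.SRC.moment * sin_theta / (4 * np.pi * r**2)
        e_here = np.sqrt(
            np.abs(fmap.ex[i, j, k]) ** 2
            + np.abs(fmap.ey[i, j, k]) ** 2
            + np.abs(fmap.ez[i, j, k]) ** 2
        )
        # ex/ey/ez staggered positions differ by ≤ h/2: compare loosely
        assert e_here == pytest.approx(expected, rel=0.15)

    def test_discrete_divergence_free(self):
        """Quasi-static dipole E has vanishing discrete divergence off-source."""
        grid = Grid((20, 20, 20), 0.002, (-0.02, -0.02, -0.02))
        fmap = dipole_incident_field(self.SRC, grid)
        h = grid.spacing
        div = (
            np.diff(fmap.ex, axis=0)[:, 1:-1, 1:-1]
            + np.diff(fmap.ey, axis=1)[1:-1, :, 1:-1]
            + np.diff(fmap.ez, axis=2)[1:-1, 1:-1, :]
        ) / h
        scale = fmap.max_magnitude() / h
        assert np.abs(div).max() < 1e-6 * scale

    def test_singularity_guard(self):
        # dipole exactly on an Ex node position
        src = MagneticDipoleSource(1.0, (-0.011, -0.012, -0.012), 1e6)
        with pytest.raises(SingularSourceError):
            dipole_incident_field(src, self.GRID)


class TestCoilField:
    def test_zero_on_coil_axis(self):
        """Azimuthal A has no component on the axis: |E| ≈ 0 there."""
        grid = Grid((8, 8, 8), 0.004, (-0.016, -0.016, -0.016))
        src = CoilSource(3, 0.08, 0.002, (0.0, 0.0, 0.1), 1e6)
        fmap = coil_incident_field(src, grid, segments_per_turn=64)
        axis_mag = np.sqrt(
            np.abs(fmap.ex[4, 4, :]) ** 2 + np.abs(fmap.ey[4, 4, :]) ** 2
        )
        # Ex/Ey nodes nearest the axis sit h/2 off it; compare to map peak
        assert np.abs(fmap.ez[4, 4, :]).max() < 1e-10 * fmap.max_magnitude()
        assert axis_mag.max() < 0.2 * fmap.max_magnitude()

    def test_single_turn_matches_dipole_in_far_zone(self):
        """1-turn loop at r ≥ 10·d agrees with m = I·π(d/2)² dipole to 1%."""
        d = 0.02
        current = 1.5
        grid = Grid((6, 6, 6), 0.004, (-0.012, -0.012, 0.24))
        coil = CoilSource(1, d, 0.001, (0.0, 0.0, 0.0), 1e6, current=current)
        m = current * np.pi * (d / 2) ** 2
        dip = MagneticDipoleSource(m, (0.0, 0.0, 0.0), 1e6)
        fc = coil_incident_field(coil, grid, segments_per_turn=128)
        fd_ = dipole_incident_field(dip, grid)
        scale = fd_.max_magnitude()
        for comp in ("ex", "ey", "ez"):
            a, b = getattr(fc, comp), getattr(fd_, comp)
            assert np.abs(a - b).max() < 0.01 * scale

    def test_loop_to_dipole_limit_tiny_loop(self):
        """1 mm-radius loop at 1 m reproduces the point-dipole field to 0.1%."""
        grid = Grid((3, 3, 3), 0.01, (0.98, -0.015, -0.015))
        coil = CoilSource(1, 0.002, 0.0005, (0.0, 0.0, 0.0), 1e6, current=2.0)
        m = 2.0 * np.pi * 0.001**2
        dip = MagneticDipoleSource(m, (0.0, 0.0, 0.0), 1e6)
        fc = coil_incident_field(coil, grid, segments_per_turn=64)
        fd_ = dipole_incident_field(dip, grid)
        scale = max(np.abs(fd_.ex).max(), np.abs(fd_.ey).max(), np.abs(fd_.ez).max())
        for comp in ("ex", "ey", "ez"):
            err = np.abs(getattr(fc, comp) - getattr(fd_, comp)).max()
            assert err < 1e-3 * scale

    def test_linear_in_current(self):
        grid = Grid((5, 5, 5), 0.004, (-0.01, -0.01, 0.05))
        a = CoilSource(2, 0.03, 0.001, (0.0, 0.0, 0.0), 1e6, current=1.0)
        b = CoilSource(2, 0.03, 0.001, (0.0, 0.0, 0.0), 1e6, current=2.0)
        fa = coil_incident_field(a, grid, segments_per_turn=32)
        fb = coil_incident_field(b, grid, segments_per_turn=32)
        assert np.array_equal(fb.ex, 2.0 * fa.ex)
        assert np.array_equal(fb.ey, 2.0 * fa.ey)
        assert np.array_equal(fb.ez, 2.0 * fa.ez)

    def test_quadrature_convergence(self):
        """Doubling the segment count changes the map by < 0.01%."""
        grid = Grid((6, 6, 6), 0.004, (-0.012, -0.012, 0.03))
        src = CoilSource(4, 0.04, 0.001, (0.0, 0.0, 0.0), 1e6)
        f1 = coil_incident_field(src, grid, segments_per_turn=256)
        f2 = coil_incident_field(src, grid, segments_per_turn=512)
        scale = f2.max_magnitude()
        for comp in ("ex", "ey", "ez"):
            change = np.abs(getattr(f1, comp) - getattr(f2, comp)).max()
            assert change < 1e-4 * scale

    def test_proximity_error_names_node(self):
        grid = Grid((8, 8, 8), 0.005, (-0.02, -0.02, -0.02))
        src = CoilSource(2, 0.03, 0.001, (0.0, 0.0, 0.0), 1e6)
        with pytest.raises(SingularSourceError, match="node at"):
            coil_incident_field(src, grid, segments_per_turn=64)


class TestResonantFrequency:
    def test_hand_evaluated_example(self):
        """L=1 µH, C=1 µF → 1/(2π·10⁻⁶) Hz ≈ 159.155 kHz."""
        assert resonant_frequency(1e-6, 1e-6) == pytest.approx(159154.94, rel=1e-6)

    def test_square_root_law(self):
        f1 = resonant_frequency(1e-6, 1e-9)
        f2 = resonant_frequency(1e-6, 4e-9)
        assert f1 / f2 == pytest.approx(2.0, rel=1e-12)

    def test_printed_wpt_circuit_values_resonate_at_15mhz_not_150khz(self):
        """The published coil L=0.412 µH with C=0.273 nF resonates near 15 MHz,
        inconsistent with the stated 150 kHz operating point."""
        f = resonant_frequency(0.412e-6, 0.273e-9)
        assert f == pytest.approx(15.0e6, rel=0.01)
        assert abs(f - 150e3) / 150e3 > 50

    def test_validation(self):
        with pytest.raises(ValueError):
            resonant_frequency(0.0, 1e-9)


class TestFieldMapIO:
    def test_roundtrip_bitwise(self, tmp_path, tiny_grid):
        src = MagneticDipoleSource(1.0, (0.0, 0.0, 0.1), 1e6)
        fmap = dipole_incident_field(src, tiny_grid)
        path = write_incident_field_map(fmap, tmp_path / "map.json")
        back = read_incident_field_map(path, tiny_grid)
        assert np.array_equal(back.ex, fmap.ex)
        assert np.array_equal(back.ey, fmap.ey)
        assert np.array_equal(back.ez, fmap.ez)
        assert back.frequency == fmap.frequency

    def test_grid_mismatch_lists_both_geometries(self, tmp_path, tiny_grid):
        src = MagneticDipoleSource(1.0, (0.0, 0.0, 0.1), 1e6)
        fmap = dipole_incident_field(src, tiny_grid)
        path = write_incident_field_map(fmap, tmp_path / "map.json")
        other = Grid((4, 4, 4), 0.004)
        with pytest.raises(FormatError, match="spacing"):
            read_incident_field_map(path, other)

    def test_real_peak_pattern_recovers_magnitude(self, tiny_grid):
        fmap = uniform_b_incident_field(tiny_grid, 1e-6, 1e6)
        px, py, pz = fmap.real_peak_pattern()
        assert np.allclose(np.abs(px), np.abs(fmap.ex))
        assert np.allclose(np.abs(pz), np.abs(fmap.ez))

    def test_linear_in_b0(self, tiny_grid):
        f1 = uniform_b_incident_field(tiny_grid, 1e-6, 1e6)
        f2 = uniform_b_incident_field(tiny_grid, 3e-6, 1e6)
        assert np.allclose(f2.ey, 3.0 * f1.ey)
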