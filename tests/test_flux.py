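"""Coil flux closed forms, shape factor, induced voltage, differential signal."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import femtomag as fm
from femtomag.device import MU0, CoilGeometry, Vector3
from femtomag.flux import (
    InvalidStandoffError,
    UnsupportedOrientationError,
    signal_from_dipoles,
)
from femtomag.magnetostatics import Dipole

from conftest import quad_flux_oracle


class TestCornerFlux:
    def test_degenerate_rectangle(self):
        assert fm.corner_flux(0.0, 1e-3, 1e-3, 1e-12) == 0.0

    def test_against_quadrature_oracle(self):
        """Corner primitive equals direct 2-D quadrature of the dipole Bz."""
        from scipy.integrate import dblquad

        a = b = p = 1e-3
        m = 1e-12

        def Bz(y, x):
            r2 = x * x + y * y + p * p
            return (MU0 * m / (4 * math.pi)) * (3 * p * p - r2) / r2**2.5

        oracle, _ = dblquad(Bz, 0, a, 0, b, epsabs=1e-28, epsrel=1e-12)
        assert fm.corner_flux(a, b, p, m) == pytest.approx(oracle, rel=1e-8)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.floats(1e-5, 1e-2),
        b=st.floats(1e-5, 1e-2),
        p=st.floats(1e-5, 5e-3),
    )
    def test_xy_symmetry(self, a, b, p):
        assert fm.corner_flux(a, b, p, 1e-12) == pytest.approx(
            fm.corner_flux(b, a, p, 1e-12), rel=1e-14
        )

    def test_sign_flip_on_negative_extent(self):
        v = fm.corner_flux(1e-3, 2e-3, 0.5e-3, 1e-12)
        assert fm.corner_flux(-1e-3, 2e-3, 0.5e-3, 1e-12) == pytest.approx(-v, rel=1e-14)

    def test_invalid_standoff(self):
        with pytest.raises(InvalidStandoffError):
            fm.corner_flux(1e-3, 1e-3, 0.0, 1e-12)

    def test_vanishes_at_large_standoff_and_extent(self):
        base = fm.corner_flux(1e-3, 1e-3, 1e-3, 1e-12)
        far = fm.corner_flux(1e-3, 1e-3, 1.0, 1e-12)
        # the corner (quarter-plane) flux decays only as 1/a, so the
        # infinite-plane limit needs a genuinely large extent
        huge = fm.corner_flux(1e4, 1e4, 1e-3, 1e-12)
        assert abs(far) < 1e-6 * abs(base)
        assert abs(huge) < 1e-6 * abs(base)
        # monotone decay beyond the turnover in p
        ps = np.geomspace(2e-3, 1.0, 30)
        vals = [fm.corner_flux(1e-3, 1e-3, p, 1e-12) for p in ps]
        assert np.all(np.diff(np.abs(vals)) < 0)


class TestRectFlux:
    def test_zero_moment(self):
        coil = CoilGeometry(0.5e-3, 0.5e-3, Vector3(0, 0, 0.3e-3))
        r = fm.rect_flux_closed(coil, Dipole(Vector3(0, 0, 0), Vector3(0, 0, 0)))
        assert r.flux_phi_z == 0.0

    def test_centered_equals_four_corners(self):
        t, h, p, m = 0.5e-3, 0.5e-3, 0.3e-3, 1e-12
        coil = CoilGeometry(t, h, Vector3(0, 0, p))
        r = fm.rect_flux_closed(coil, Dipole(Vector3(0, 0, 0), Vector3(0, 0, m)))
        assert r.flux_phi_z == pytest.approx(4 * fm.corner_flux(t, h, p, m), rel=1e-14)

    def test_off_center_matches_quadrature(self):
        """Inclusion–exclusion vs the independent oracle, in and out of the
        coil footprint (seeded random offsets)."""
        rng = np.random.default_rng(11)
        t, h, p = 0.8e-3, 2e-3, 0.4e-3
        coil = CoilGeometry(t, h, Vector3(0, 0, p))
        for _ in range(15):
            x0 = rng.uniform(-2.5 * t, 2.5 * t)
            y0 = rng.uniform(-2.5 * h, 2.5 * h)
            d = Dipole(Vector3(x0, y0, 0), Vector3(0, 0, 1e-12))
            closed = fm.rect_flux_closed(coil, d).flux_phi_z
            oracle = quad_flux_oracle(coil, d)
            assert closed == pytest.approx(oracle, rel=1e-6, abs=1e-30)

    def test_non_z_moment_routed_to_quadrature(self):
        coil = CoilGeometry(0.5e-3, 0.5e-3, Vector3(0, 0, 0.3e-3))
        d = Dipole(Vector3(0, 0, 0), Vector3(1e-12, 0, 0))
        with pytest.raises(UnsupportedOrientationError):
            fm.rect_flux_closed(coil, d)
        q = fm.rect_flux_quadrature(coil, d)
        # x-moment centered under the coil: antisymmetric integrand, zero flux
        assert abs(q.flux_phi_z) < 1e-12 * abs(
            fm.rect_flux_quadrature(coil, Dipole(d.position, Vector3(0, 0, 1e-12))).flux_phi_z
        )

    def test_quadrature_zero_moment(self):
        coil = CoilGeometry(0.5e-3, 0.5e-3, Vector3(0, 0, 0.3e-3))
        r = fm.rect_flux_quadrature(coil, Dipole(Vector3(0, 0, 0), Vector3(0, 0, 0)))
        assert r.flux_phi_z == 0.0 and r.est_error == 0.0

    def test_quadrature_reproduces_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t, h = rng.uniform(0.2e-3, 3e-3, 2)
            p = rng.uniform(0.1e-3, 1e-3)
            coil = CoilGeometry(t, h, Vector3(0, 0, p))
            d = Dipole(Vector3(0, 0, 0), Vector3(0, 0, 1e-12))
            c = fm.rect_flux_closed(coil, d).flux_phi_z
            q = fm.rect_flux_quadrature(coil, d, tol=1e-9).flux_phi_z
            assert q == pytest.approx(c, rel=1e-8)


class TestShapeFactor:
    def test_definitional_consistency(self, device, reporter):
        """alpha·(chi·V·Ha) equals the centered closed-form flux."""
        p = 0.25e-3
        coil = device.sense_coil
        sf = fm.shape_factor(coil, p)
        H0 = 2.4e4
        m_z = reporter.susceptibility_chi * reporter.volume_V * H0
        d = Dipole(
            Vector3(coil.center.x, coil.center.y, coil.center.z - p), Vector3(0, 0, m_z)
        )
        assert sf.alpha * m_z == pytest.approx(
            fm.rect_flux_closed(coil, d).flux_phi_z, rel=1e-12
        )

    def test_inverse_cube_asymptote(self):
        coil = CoilGeometry(0.5e-3, 0.5e-3)
        span = 10 * max(coil.half_width_t, coil.half_height_h)
        ps = np.geomspace(span, 10 * span, 40)
        alphas = [fm.shape_factor(coil, p).alpha for p in ps]
        slope = np.polyfit(np.log(ps), np.log(alphas), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.01)

    def test_vanishes_for_infinite_coil(self):
        # net dipole flux through an ever-larger plane goes to zero,
        # but only as 1/extent (return flux just outside the loop)
        p = 0.3e-3
        a1 = fm.shape_factor(CoilGeometry(1e-3, 1e-3), p).alpha
        a2 = fm.shape_factor(CoilGeometry(10.0, 10.0), p).alpha
        a3 = fm.shape_factor(CoilGeometry(1e5, 1e5), p).alpha
        assert a2 < 1e-3 * a1
        assert a3 < 1e-3 * a2

    def test_invalid_standoff(self):
        with pytest.raises(InvalidStandoffError):
            fm.shape_factor(CoilGeometry(1e-3, 1e-3), -0.1e-3)


class TestInducedVoltage:
    def test_zero_field(self, device, reporter):
        sf = fm.shape_factor(device.sense_coil, 0.2e-3)
        assert fm.induced_voltage(sf, device.drive, reporter, 0.0).voltage_amplitude_eps == 0.0

    def test_convention_ratio_is_2pi(self, device, reporter):
        sf = fm.shape_factor(device.sense_coil, 0.2e-3)
        phys = fm.induced_voltage(sf, device.drive, reporter, 1e3, convention="physical")
        ds = fm.induced_voltage(sf, device.drive, reporter, 1e3, convention="datasheet")
        assert phys.voltage_amplitude_eps / ds.voltage_amplitude_eps == pytest.approx(
            2 * math.pi, rel=1e-14
        )
        assert phys.convention == "physical" and ds.convention == "datasheet"

    @pytest.mark.parametrize("param", ["f", "chi", "V", "H0"])
    def test_linearity_in_each_factor(self, device, reporter, param):
        sf = fm.shape_factor(device.sense_coil, 0.2e-3)
        H0 = 1e3
        base = fm.induced_voltage(sf, device.drive, reporter, H0).voltage_amplitude_eps
        drive, rep, H = device.drive, reporter, H0
        if param == "f":
            drive = dataclasses.replace(drive, frequency_f=2 * drive.frequency_f)
        elif param == "chi":
            rep = dataclasses.replace(rep, susceptibility_chi=2 * rep.susceptibility_chi)
        elif param == "V":
            rep = dataclasses.replace(rep, volume_V=2 * rep.volume_V)
        else:
            H = 2 * H0
        doubled = fm.induced_voltage(sf, drive, rep, H).voltage_amplitude_eps
        assert doubled == pytest.approx(2 * base, rel=1e-14)


class TestDetectorSignal:
    def test_empty_strip_null(self, device, reporter):
        strip = fm.generate_strip([], reporter=reporter, seed=0)
        assert fm.detector_signal(strip, device, 0.0) == 0.0

    def test_mirror_balanced_dipoles_cancel(self, device):
        """One dipole under each coil at mirror-congruent positions: the
        counter-wound difference nulls to floating-point."""
        xr = device.reference_coil.center.x
        for dx, dy in [(0.0, 0.0), (0.05e-3, 0.3e-3), (0.1e-3, -1e-3)]:
            pos = np.array([[dx, dy, 0.1e-3], [xr - dx, dy, 0.1e-3]])
            m = np.array([1e-18, 1e-18])
            total = signal_from_dipoles(pos, m, device)
            single = abs(signal_from_dipoles(pos[:1], m[:1], device))
            assert abs(total) < 1e-12 * single

    def test_superposition_over_dipoles(self, device, reporter):
        """N dipoles equal the sum of per-dipole closed-form signals."""
        rng = np.random.default_rng(5)
        n = 40
        pos = np.column_stack(
            [
                rng.uniform(-0.5e-3, 0.5e-3, n),
                rng.uniform(-2e-3, 2e-3, n),
                rng.uniform(0.02e-3, 0.18e-3, n),
            ]
        )
        H0 = float(device.drive.field_amplitude_H0)
        m_z = np.full(n, reporter.susceptibility_chi * reporter.volume_V * H0)
        total = signal_from_dipoles(pos, m_z, device)
        per = sum(
            signal_from_dipoles(pos[i : i + 1], m_z[i : i + 1], device) for i in range(n)
        )
        assert total == pytest.approx(per, rel=1e-12)

    def test_linear_in_total_moment(self, device):
        rng = np.random.default_rng(9)
        pos = np.column_stack(
            [rng.uniform(-1e-3, 1e-3, 10), rng.uniform(-2e-3, 2e-3, 10), rng.uniform(0.05e-3, 0.15e-3, 10)]
        )
        m = rng.uniform(0.5e-18, 2e-18, 10)
        k = 3.7
        assert signal_from_dipoles(pos, k * m, device) == pytest.approx(
            k * signal_from_dipoles(pos, m, device), rel=1e-12
        )

    def test_sense_to_reference_sign_flip(self, device):
        dx, dy, z = 0.06e-3, 0.4e-3, 0.1e-3
        under_sense = np.array([[device.sense_coil.center.x + dx, dy, z]])
        under_ref = np.array([[device.reference_coil.center.x + dx, dy, z]])
        m = np.array([1e-18])
        s1 = signal_from_dipoles(under_sense, m, device)
        s2 = signal_from_dipoles(under_ref, m, device)
        # magnitudes agree to the (tiny) cross-coupling, signs are opposite
        assert s1 > 0 > s2
        assert abs(s1 + s2) < 1e-3 * abs(s1)

    def test_reference_isolation_is_computed(self, device):
        # default geometry: test-line flux into the reference coil is
        # < 0.1% of the sense-coil flux (computed, not assumed)
        assert fm.reference_coupling_ratio(device) < 1e-3
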