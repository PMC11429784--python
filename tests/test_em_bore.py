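"""Waveguide mode physics: cutoffs, dispersion, fields, fluxes."""

import math

import numpy as np
import pytest
from scipy import optimize, special
from scipy.constants import c as C_LIGHT

import bptsim as b
from bptsim.em_bore import surface_flux


def _bessel_root_bisect(family: str, n: int, m: int) -> float:
    """Independent root finder: bracketed bisection on J_n (TM) or J_n' (TE)."""
    if family == "TE":
        fn = lambda x: special.jv(n - 1, x) - special.jv(n + 1, x)  # 2 J_n'
    else:
        fn = lambda x: special.jv(n, x)
    roots, x, step = [], 1e-6 if (family == "TE" and n >= 1) or family == "TM" else 1e-6, 0.05
    # TE n=0: J0' has a trivial zero at 0; start past it
    if family == "TE" and n == 0:
        x = 0.5
    prev = fn(x)
    while len(roots) < m:
        x2 = x + step
        cur = fn(x2)
        if prev == 0.0:
            roots.append(x)
        elif prev * cur < 0:
            roots.append(optimize.brentq(fn, x, x2, xtol=1e-14))
        x, prev = x2, cur
    return roots[m - 1]


class TestModeCutoff:
    def test_te11_cutoff_is_251_mhz(self):
        """Dominant mode of a 70 cm bore cuts off at 251.1 MHz (+-0.5%)."""
        fc = b.mode_cutoff("TE", 1, 1, 0.35)
        assert fc / 1e6 == pytest.approx(251.1, rel=5e-3)

    def test_cutoff_scales_inversely_with_radius(self):
        assert b.mode_cutoff("TE", 1, 1, 0.70) == pytest.approx(
            b.mode_cutoff("TE", 1, 1, 0.35) / 2.0, rel=1e-12)

    def test_tm01_cutoff_matches_bisection_oracle(self):
        p = _bessel_root_bisect("TM", 0, 1)
        fc = p * C_LIGHT / (2 * math.pi * 0.35)
        assert b.mode_cutoff("TM", 0, 1, 0.35) == pytest.approx(fc, rel=1e-9)
        assert fc / 1e6 == pytest.approx(327.8, abs=0.1)

    @pytest.mark.parametrize("family", ["TE", "TM"])
    def test_first_roots_match_bisection_oracle(self, family):
        """First 10 modes (n=0..4, m=1..2) agree with the independent root solver."""
        for n in range(5):
            for m in (1, 2):
                expect = _bessel_root_bisect(family, n, m)
                fc = b.mode_cutoff(family, n, m, 0.35)
                assert fc == pytest.approx(
                    expect * C_LIGHT / (2 * math.pi * 0.35), rel=1e-9)

    @pytest.mark.parametrize("family", ["TE", "TM"])
    def test_cutoff_increases_with_radial_index(self, family):
        cuts = [b.mode_cutoff(family, 1, m, 0.35) for m in range(1, 6)]
        assert np.all(np.diff(cuts) > 0)

    def test_invalid_indices_rejected(self):
        with pytest.raises(ValueError, match="radial"):
            b.mode_cutoff("TE", 1, 0, 0.35)
        with pytest.raises(ValueError, match="azimuthal"):
            b.mode_cutoff("TE", -1, 1, 0.35)
        with pytest.raises(ValueError, match="radius"):
            b.mode_cutoff("TE", 1, 1, -0.1)


class TestPropagationConstant:
    def test_zero_at_band_edge(self, te11):
        kz = b.propagation_constant(te11, te11.cutoff_frequency)
        assert abs(kz) < 1e-3

    def test_evanescent_decay_rate_closed_form(self, te11):
        """alpha = (2 pi / c) sqrt(fc^2 - f^2); ~4.5 Np/m at 127.8 MHz."""
        kz = b.propagation_constant(te11, 127.8e6)
        fc = te11.cutoff_frequency
        alpha = 2 * math.pi / C_LIGHT * math.sqrt(fc**2 - 127.8e6**2)
        assert kz.real == 0.0
        assert -kz.imag == pytest.approx(alpha, rel=1e-12)
        assert alpha == pytest.approx(4.5, abs=0.1)
        # numeric dispersion-relation solve: beta^2 = k^2 - kc^2 root in f
        disp = lambda a: (2 * math.pi * fc / C_LIGHT) ** 2 \
            - (2 * math.pi * 127.8e6 / C_LIGHT) ** 2 - a**2
        a_num = optimize.brentq(disp, 0.0, 100.0, xtol=1e-12)
        assert -kz.imag == pytest.approx(a_num, rel=1e-9)

    def test_guide_wavelength_at_2400_mhz(self, te11):
        kz = b.propagation_constant(te11, 2400e6)
        lam_g = 2 * math.pi / kz.real
        fc = te11.cutoff_frequency
        expect = C_LIGHT / 2400e6 / math.sqrt(1 - (fc / 2400e6) ** 2)
        assert kz.imag == 0.0
        assert lam_g == pytest.approx(expect, rel=1e-12)
        assert lam_g == pytest.approx(0.126, abs=0.001)


class TestFieldAtPoints:
    def _line(self, n=60, y=-0.2, z0=-0.3, z1=0.5):
        return np.stack([np.zeros(n), np.full(n, y), np.linspace(z0, z1, n)],
                        axis=1)

    def test_travelling_wave_has_constant_magnitude(self, te11, source_24ghz):
        bore0 = b.BoreModel(end_reflection=0.0)
        fs = b.field_at_points(bore0, source_24ghz, [te11], self._line())
        mag = np.linalg.norm(fs.H, axis=1)
        assert mag.std() / mag.mean() < 1e-12

    def test_standing_wave_period_is_half_guide_wavelength(self, bore, te11,
                                                           source_24ghz):
        """Two-wave interference: |H| maxima spaced lambda_g / 2 apart."""
        pts = self._line(n=2000)
        fs = b.field_at_points(bore, source_24ghz, [te11], pts)
        mag = np.linalg.norm(fs.H, axis=1)
        from scipy.signal import find_peaks
        pk, _ = find_peaks(mag)
        lam_g = 2 * math.pi / b.propagation_constant(te11, 2400e6).real
        spacing = np.diff(pts[pk, 2])
        dz = pts[1, 2] - pts[0, 2]
        assert np.all(np.abs(spacing - lam_g / 2) < 2 * dz)

    def test_below_cutoff_field_decays_with_distance(self, te11):
        src = b.SourceSpec(position=(0.25, -math.pi / 2, -0.55),
                           frequency=127.8e6)
        bore0 = b.BoreModel(end_reflection=0.0)
        fs = b.field_at_points(bore0, src, [te11], self._line())
        mag = np.linalg.norm(fs.H, axis=1)
        assert np.all(np.diff(mag) < 0)

    def test_evanescent_log_slope_matches_alpha(self, te11):
        src = b.SourceSpec(position=(0.25, -math.pi / 2, -0.55),
                           frequency=127.8e6)
        bore0 = b.BoreModel(end_reflection=0.0)
        pts = self._line(n=200, z0=-0.3, z1=0.6)
        fs = b.field_at_points(bore0, src, [te11], pts)
        mag = np.linalg.norm(fs.H, axis=1)
        slope, _ = np.polyfit(pts[:, 2], np.log(mag), 1)
        alpha = -b.propagation_constant(te11, 127.8e6).imag
        assert slope == pytest.approx(-alpha, rel=1e-6)

    def test_field_linear_in_source_amplitude(self, bore, te11, source_24ghz):
        pts = self._line(n=20)
        f1 = b.field_at_points(bore, source_24ghz, [te11], pts)
        src2 = b.SourceSpec(position=source_24ghz.position,
                            frequency=source_24ghz.frequency,
                            amplitude=3.5 - 1.25j)
        f2 = b.field_at_points(bore, src2, [te11], pts)
        np.testing.assert_allclose(f2.H, (3.5 - 1.25j) * f1.H, rtol=1e-12)

    def test_empty_mode_set_and_outside_points_rejected(self, bore, source_24ghz,
                                                        te11):
        with pytest.raises(ValueError, match="non-empty"):
            b.field_at_points(bore, source_24ghz, [], np.zeros((1, 3)))
        with pytest.raises(ValueError, match="outside"):
            b.field_at_points(bore, source_24ghz, [te11],
                              np.array([[0.5, 0.0, 0.0]]))


class TestCoilFlux:
    def test_uniform_axial_field_gives_h0_times_area(self):
        coil = b.CoilSurface(center=(0.1, 0.0, 0.0), normal=(0, 0, 1.0),
                             width=0.10, height=0.14)
        H0 = 2.5 - 0.5j
        flux = surface_flux(lambda p: np.tile([0, 0, H0], (len(p), 1)), coil)
        assert flux == pytest.approx(H0 * coil.area, rel=1e-12)

    def test_orthogonal_field_gives_zero(self):
        coil = b.CoilSurface(center=(0.1, 0.0, 0.0), normal=(0, 0, 1.0))
        flux = surface_flux(lambda p: np.tile([1.0, 0, 0], (len(p), 1)), coil)
        assert abs(flux) < 1e-15

    def test_quadrature_matches_fine_grid_oracle(self, bore, te11, source_24ghz):
        """Adaptive result agrees with a 10x-finer fixed Gauss grid to 1e-6."""
        coil = b.CoilSurface(center=(0.30, -math.pi / 2, 0.05),
                             normal=(0.0, 1.0, 0.0))
        flux = b.coil_flux(bore, source_24ghz, [te11], coil)
        pts, wts = coil.grid(160)
        H = b.field_at_points(bore, source_24ghz, [te11], pts).H
        oracle = complex(np.sum((H @ np.asarray(coil.normal)) * wts))
        assert flux == pytest.approx(oracle, rel=1e-6)

    def test_coil_outside_bore_rejected(self, bore, te11, source_24ghz):
        coil = b.CoilSurface(center=(0.30, 0.0, 0.9), normal=(0, 1.0, 0))
        with pytest.raises(ValueError, match="bore"):
            b.coil_flux(bore, source_24ghz, [te11], coil)


class TestSweep:
    def test_zero_length_offset_list_gives_empty_series(self, bore, source_24ghz):
        coil = b.CoilSurface(center=(0.30, -math.pi / 2, 0.0), normal=(0, 1, 0))
        out = b.sweep_coil_positions(bore, source_24ghz, [coil], [])
        assert len(out) == 1 and out[0].flux.size == 0

    def test_flux_linearity_across_sweep(self, bore, source_24ghz):
        coil = b.CoilSurface(center=(0.30, -math.pi / 2, 0.0), normal=(0, 1, 0))
        offs = np.linspace(0, 0.05, 5)
        f1 = b.sweep_coil_positions(bore, source_24ghz, [coil], offs)[0].flux
        src2 = b.SourceSpec(position=source_24ghz.position,
                            frequency=source_24ghz.frequency, amplitude=2.0j)
        f2 = b.sweep_coil_positions(bore, src2, [coil], offs)[0].flux
        np.testing.assert_allclose(f2, 2.0j * f1, rtol=1e-9)

    def test_offsets_leaving_bore_rejected(self, bore, source_24ghz):
        coil = b.CoilSurface(center=(0.30, -math.pi / 2, 0.55), normal=(0, 1, 0))
        with pytest.raises(ValueError, match="outside the bore"):
            b.sweep_coil_positions(bore, source_24ghz, [coil], [0.0, 0.2])


class TestPowerDensity:
    def test_100mw_at_10cm_is_0_08(self):
        assert b.isotropic_power_density(100.0, 10.0) == pytest.approx(0.08,
                                                                       abs=5e-3)

    def test_inverse_square_law(self):
        assert b.isotropic_power_density(100.0, 20.0) == pytest.approx(
            b.isotropic_power_density(100.0, 10.0) / 4.0, rel=1e-12)

    def test_zero_power_and_bad_distance(self):
        assert b.isotropic_power_density(0.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            b.isotropic_power_density(100.0, 0.0)
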