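"""Stolt migration chain: spectra, dispersion remap, inverse, physical mapping."""

import dataclasses

import numpy as np
import pytest

from fkbeam import (
    ERMParams,
    ImageGrid,
    PlaneWaveTransmit,
    Scatterer,
    das_beamform,
    dispersion_g,
    envelope_image,
    erm_parameters,
    fk_migrate,
    forward_spectrum,
    inverse_wavefield,
    psf_report,
    simulate_channel_data,
    stolt_remap,
    to_physical_grid,
)
from fkbeam.fk import MigratedWavefield
from conftest import WAVELENGTH


class TestForwardSpectrum:
    def test_zero_in_zero_out(self, point_channel):
        ch = dataclasses.replace(point_channel, samples=np.zeros_like(point_channel.samples))
        assert not np.any(forward_spectrum(ch).coeffs)

    def test_impulse_has_flat_magnitude(self, small_array, medium, point_channel):
        from fkbeam import ChannelData

        samples = np.zeros((small_array.n_elements, 64))
        samples[5, 20] = 1.0
        ch = ChannelData(samples, 20e6, 0.0, 0.0, small_array, medium)
        spec = forward_spectrum(ch, pad_time=1)
        np.testing.assert_allclose(np.abs(spec.coeffs), 1.0, rtol=1e-12)

    def test_parseval(self, point_channel):
        spec = forward_spectrum(point_channel, pad_time=2)
        e_data = np.sum(point_channel.samples**2)  # zero-padding adds no energy
        assert spec.energy() == pytest.approx(e_data, rel=1e-10)

    def test_hermitian_symmetry_for_real_data(self, point_channel):
        spec = forward_spectrum(point_channel, pad_time=1)
        c = spec.coeffs
        flipped = np.conj(np.roll(c[::-1, ::-1], (1, 1), axis=(0, 1)))
        np.testing.assert_allclose(c, flipped, atol=1e-8 * np.max(np.abs(c)))

    def test_round_trip(self, point_channel):
        spec = forward_spectrum(point_channel, pad_time=1)
        back = np.fft.ifft2(spec.coeffs).real
        np.testing.assert_allclose(back, point_channel.samples, atol=1e-12)

    def test_bad_padding_rejected(self, point_channel):
        with pytest.raises(ValueError):
            forward_spectrum(point_channel, pad_time=0)


class TestDispersion:
    def test_zero_vertical_wavenumber(self):
        assert dispersion_g(0.0, 123.0, 1000.0) == 0.0

    def test_zero_lateral_wavenumber_is_linear(self):
        np.testing.assert_allclose(dispersion_g(np.array([-4.0, 4.0]), 0.0, 2.0),
                                   [-8.0, 8.0])

    def test_3_4_5(self):
        assert dispersion_g(4.0, 3.0, 2.0) == pytest.approx(10.0)

    def test_odd_and_monotone(self):
        kl = np.linspace(-50, 50, 101)
        g = dispersion_g(kl, 7.0, 1500.0)
        np.testing.assert_allclose(g, -g[::-1], atol=1e-9)
        assert np.all(np.diff(g) > 0)
        assert np.all(np.abs(g[kl != 0]) >= 1500.0 * 7.0)


class TestStoltRemap:
    def test_zero_spectrum(self, point_channel):
        ch = dataclasses.replace(point_channel, samples=np.zeros_like(point_channel.samples))
        spec = forward_spectrum(ch)
        out = stolt_remap(spec, 1000.0)
        assert not np.any(out.coeffs)

    def test_zero_lateral_column_is_pure_axis_rescale(self, point_channel):
        """At r_a = 0 the map is g = e_hat * r_l with constant weight e_hat."""
        e_hat = 1089.0
        spec = forward_spectrum(point_channel)
        out = stolt_remap(spec, e_hat)
        g_req = e_hat * out.axis2
        f_sorted = np.fft.fftshift(spec.axis2)
        row_sorted = np.fft.fftshift(spec.coeffs[0])
        expect = np.interp(g_req, f_sorted, row_sorted.real) + 1j * np.interp(
            g_req, f_sorted, row_sorted.imag
        )
        expect[np.abs(g_req) > f_sorted[-1]] = 0.0
        np.testing.assert_allclose(out.coeffs[0], e_hat * expect, rtol=1e-12)

    def test_energy_not_increased(self, point_channel):
        """Evanescent truncation only removes energy (unit-speed normalised)."""
        e_hat = 1089.0
        spec = forward_spectrum(point_channel)
        out = stolt_remap(spec, e_hat)
        # the printed Jacobian carries a uniform e_hat scale; normalise it out
        assert np.sum(np.abs(out.coeffs / e_hat) ** 2) <= np.sum(np.abs(spec.coeffs) ** 2) * (
            1 + 1e-9
        )

    def test_requires_frequency_domain(self, point_channel):
        spec = forward_spectrum(point_channel)
        out = stolt_remap(spec, 1000.0)
        with pytest.raises(ValueError):
            stolt_remap(out, 1000.0)


class TestInverseWavefield:
    def test_zero_in_zero_out(self, point_channel):
        ch = dataclasses.replace(point_channel, samples=np.zeros_like(point_channel.samples))
        out = inverse_wavefield(stolt_remap(forward_spectrum(ch), 1089.0))
        assert not np.any(out.values)

    def test_imaginary_residue_is_small(self, point_channel):
        out = inverse_wavefield(stolt_remap(forward_spectrum(point_channel), 1089.0))
        assert np.all(np.isfinite(out.values))

    def test_depth_axis_is_e_hat_times_time(self, point_channel):
        e_hat = 1089.0
        out = inverse_wavefield(
            stolt_remap(forward_spectrum(point_channel), e_hat), e_hat=e_hat
        )
        dt = 1.0 / point_channel.sampling_rate
        np.testing.assert_allclose(np.diff(out.l_hat), e_hat * dt, rtol=1e-9)


class TestToPhysicalGrid:
    def _field(self, grid_vals, a_axis, l_axis, params):
        return MigratedWavefield(grid_vals, a_axis, l_axis, params)

    def test_identity_params_resample_only(self):
        a = np.linspace(-5e-3, 5e-3, 21)
        l = np.linspace(0.0, 30e-3, 61)
        vals = np.add.outer(np.sin(1e3 * a), np.cos(500 * l))
        field = self._field(vals, a, l, ERMParams(1.0, 1.0, 0.0))
        grid = ImageGrid(a[2:-2], l[2:-2])
        img = to_physical_grid(field, ERMParams(1.0, 1.0, 0.0), grid)
        np.testing.assert_allclose(img.values, vals[2:-2, 2:-2], atol=1e-12)

    def test_unsteered_params_pure_depth_rescale(self):
        """Angle-0 mapping reads the field at sqrt(2) times the physical depth."""
        p = erm_parameters(0.0)
        a = np.linspace(-5e-3, 5e-3, 21)
        l = np.linspace(0.0, 60e-3, 241)
        blob_l_hat = 30e-3 * np.sqrt(2)
        vals = np.exp(-((l[None, :] - blob_l_hat) ** 2) / (2 * (1e-3) ** 2)) * np.ones(
            (a.size, 1)
        )
        field = self._field(vals, a, l, p)
        grid = ImageGrid.regular(-4e-3, 4e-3, 25e-3, 35e-3, 0.1e-3)
        img = to_physical_grid(field, p, grid)
        j = np.argmax(img.values[10])
        assert grid.depth[j] == pytest.approx(30e-3, abs=0.15e-3)

    def test_shear_moves_blob_laterally(self):
        chi = 0.2
        p = ERMParams(1.0, 1.0, chi)
        a = np.linspace(-10e-3, 10e-3, 81)
        l = np.linspace(0.0, 40e-3, 161)
        l0, a_hat0 = 20e-3, 4e-3
        vals = np.exp(
            -((a[:, None] - a_hat0) ** 2) / (2 * (0.5e-3) ** 2)
            - ((l[None, :] - l0) ** 2) / (2 * (0.5e-3) ** 2)
        )
        field = self._field(vals, a, l, p)
        grid = ImageGrid.regular(-8e-3, 8e-3, 15e-3, 25e-3, 0.1e-3)
        img = to_physical_grid(field, p, grid)
        i, j = np.unravel_index(np.argmax(img.values), img.values.shape)
        # physical lateral = a_hat - chi * l
        assert grid.lateral[i] == pytest.approx(a_hat0 - chi * l0, abs=0.2e-3)
        assert grid.depth[j] == pytest.approx(l0, abs=0.2e-3)

    def test_disjoint_footprint_rejected(self):
        p = ERMParams(1.0, 1.0, 0.0)
        field = self._field(np.zeros((5, 5)), np.linspace(0, 1e-3, 5),
                            np.linspace(0, 1e-3, 5), p)
        grid = ImageGrid.regular(50e-3, 60e-3, 50e-3, 60e-3, 1e-3)
        with pytest.raises(ValueError):
            to_physical_grid(field, p, grid)


class TestFkMigrate:
    def test_zero_in_zero_out(self, point_channel, point_grid):
        ch = dataclasses.replace(point_channel, samples=np.zeros_like(point_channel.samples))
        img = fk_migrate(ch, point_grid)
        assert not np.any(img.values)

    def test_linearity(self, array, medium, pulse, point_grid):
        tx = PlaneWaveTransmit(0.1)
        kw = dict(duration=5e-5)
        c1 = simulate_channel_data([Scatterer(-1e-3, 24e-3, 1.0)], array, medium, tx, pulse, **kw)
        c2 = simulate_channel_data([Scatterer(1e-3, 26e-3, -0.6)], array, medium, tx, pulse, **kw)
        c12 = dataclasses.replace(c1, samples=c1.samples + c2.samples)
        f1, f2, f12 = (fk_migrate(c, point_grid) for c in (c1, c2, c12))
        scale = np.max(np.abs(f12.values))
        assert np.max(np.abs(f12.values - (f1.values + f2.values))) <= 1e-8 * scale

    def test_point_target_recovered_unsteered(self, point_channel, point_grid):
        """Angle-0 migration localises a point within one wavelength of truth
        and within one grid cell of the DAS envelope peak."""
        img = fk_migrate(point_channel, point_grid)
        rf = psf_report(envelope_image(img), point_grid, (0.0, 25e-3))
        assert rf.localization_error <= WAVELENGTH
        das_img = das_beamform(point_channel, point_grid)
        rd = psf_report(envelope_image(das_img), point_grid, (0.0, 25e-3))
        cell = WAVELENGTH / 4
        assert abs(rf.peak_lateral - rd.peak_lateral) <= cell
        assert abs(rf.peak_depth - rd.peak_depth) <= cell

    def test_point_target_recovered_steered(self, array, medium, pulse):
        """Steered migration recovers the true position within one wavelength."""
        ch = simulate_channel_data(
            [Scatterer(0.0, 25e-3, 1.0)], array, medium,
            PlaneWaveTransmit(np.deg2rad(10)), pulse,
        )
        grid = ImageGrid.regular(-3e-3, 3e-3, 22e-3, 28e-3, WAVELENGTH / 4)
        rf = psf_report(envelope_image(fk_migrate(ch, grid)), grid, (0.0, 25e-3))
        assert rf.localization_error <= WAVELENGTH

    def test_e_hat_is_phi_times_e(self):
        p = erm_parameters(0.0)
        assert p.c_scale * 1540.0 == pytest.approx(1540.0 * np.sqrt(2) / 2, rel=1e-15)
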