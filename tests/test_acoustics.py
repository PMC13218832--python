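"""Photoacoustic forward model and universal back-projection."""

import numpy as np
import pytest

from ltu.phantom import VoxelGrid, preset
from ltu.thermal import TemperatureField, HeatSourceField
from ltu.acoustics import (GrueneisenModel, PressureField, TransducerArray,
                           RFData, NoiseSpec, initial_pressure,
                           forward_project, ubp_reconstruct,
                           estimate_deconvolution)

VS = 1500.0


@pytest.fixture
def free_grid():
    shape = (32, 32, 28)
    dl = 0.25e-3
    return VoxelGrid(shape=shape, dl=dl,
                     region_labels=np.zeros(shape, dtype=np.int32),
                     props={0: preset("chicken_breast_808")},
                     origin=(-shape[0] * dl / 2, -shape[1] * dl / 2, 0.0))


def field_with(grid, points):
    p0 = np.zeros(grid.shape)
    for (i, j, k), v in points:
        p0[i, j, k] = v
    return PressureField(p0=p0, grid=grid)


class TestGrueneisen:
    def test_constant_gamma_when_b_zero(self):
        gm = GrueneisenModel(A=0.11, B=0.0)
        assert gm.gamma(30.0) == gm.gamma(45.0) == 0.11

    def test_negative_gamma_in_range_rejected(self):
        with pytest.raises(ValueError):
            GrueneisenModel(A=-0.2, B=0.001)

    def test_default_relative_slope_scale(self):
        gm = GrueneisenModel()
        # soft-tissue photoacoustic amplitude slope, a few %/K at 36 C
        assert gm.B / gm.gamma(36.0) == pytest.approx(0.0354, rel=1e-3)


class TestInitialPressure:
    def test_temperature_ratio_closed_form(self, free_grid):
        gm = GrueneisenModel(A=0.1, B=0.004)
        S = HeatSourceField(S=np.ones(free_grid.shape))
        p36 = initial_pressure(S, free_grid, 36.0, gm).p0
        p37 = initial_pressure(S, free_grid, 37.0, gm).p0
        ratio = (0.1 + 37 * 0.004) / (0.1 + 36 * 0.004)
        np.testing.assert_allclose(p37 / p36, ratio)

    def test_zero_where_no_absorption(self, free_grid, slab_mc):
        from ltu.phantom import TissueProperties
        shape = free_grid.shape
        labels = np.zeros(shape, dtype=np.int32)
        labels[:, :, :5] = 1
        grid = VoxelGrid(
            shape=shape, dl=free_grid.dl, region_labels=labels,
            props={0: preset("chicken_breast_808"),
                   1: TissueProperties(mu_a=0.0, mu_s=100.0, g=0.5, rho=1000,
                                       cp=4000, kv=0.5, vs=1500)})
        from ltu.optics import FluenceField
        from ltu.optics import BeamSpec
        fl = FluenceField(phi=np.ones(shape), beam=BeamSpec())
        p0 = initial_pressure(fl, grid, 36.0, GrueneisenModel()).p0
        assert np.all(p0[:, :, :5] == 0)
        assert np.all(p0[:, :, 5:] > 0)

    def test_temperature_field_accepted(self, free_grid):
        gm = GrueneisenModel()
        S = HeatSourceField(S=np.ones(free_grid.shape))
        T = TemperatureField(T=np.full(free_grid.shape, 40.0))
        a = initial_pressure(S, free_grid, T, gm).p0
        b = initial_pressure(S, free_grid, 40.0, gm).p0
        np.testing.assert_array_equal(a, b)


class TestForwardProject:
    def test_time_of_flight_support(self, free_grid):
        pf = field_with(free_grid, [((16, 16, 20), 1.0)])
        arr = TransducerArray.linear(1, center=(0.0, 0.0, 0.0))
        rf = forward_project(pf, arr, VS)
        src = free_grid.origin + (np.array([16, 16, 20]) + 0.5) * free_grid.dl
        t_exp = np.linalg.norm(src) / VS
        peak_t = rf.times[np.argmax(np.abs(rf.samples[0]))]
        assert peak_t == pytest.approx(t_exp, abs=4 * rf.dt_sample
                                       + free_grid.dl / VS)

    def test_linearity_pre_noise(self, free_grid):
        arr = TransducerArray.linear(4, center=(0.0, 0.0, 0.0))
        rf1 = forward_project(field_with(free_grid, [((16, 16, 20), 1.0)]),
                              arr, VS)
        rf2 = forward_project(field_with(free_grid, [((16, 16, 20), 2.0)]),
                              arr, VS)
        np.testing.assert_allclose(rf2.samples, 2 * rf1.samples, atol=1e-30)

    def test_uniform_sphere_gives_bipolar_n_pulse(self, free_grid):
        ii, jj, kk = np.indices(free_grid.shape)
        r2 = (ii - 16.0) ** 2 + (jj - 16.0) ** 2 + (kk - 16.0) ** 2
        p0 = np.where(r2 <= 5.0**2, 1.0, 0.0)
        pf = PressureField(p0=p0, grid=free_grid)
        arr = TransducerArray.linear(1, center=(0.0, 0.0, 0.0))
        rf = forward_project(pf, arr, VS)
        tr = rf.samples[0]
        i_max, i_min = np.argmax(tr), np.argmin(tr)
        assert tr[i_max] > 0 and tr[i_min] < 0 and i_max < i_min
        center = free_grid.origin + (np.array([16, 16, 16]) + 0.5) * free_grid.dl
        t_center = np.linalg.norm(center) / VS
        lo, hi = sorted((i_max, i_min))
        seg = tr[lo:hi + 1]
        zc = rf.times[lo + np.argmin(np.abs(seg))]
        assert zc == pytest.approx(t_center, abs=3 * free_grid.dl / VS)

    def test_grid_behind_array_rejected(self, free_grid):
        pf = field_with(free_grid, [((16, 16, 20), 1.0)])
        arr = TransducerArray.linear(4, center=(0.0, 0.0, 2e-3))
        with pytest.raises(ValueError, match="behind"):
            forward_project(pf, arr, VS)

    def test_array_shift_shifts_time_of_flight(self, free_grid):
        pf = field_with(free_grid, [((16, 16, 20), 1.0)])
        arr = TransducerArray.linear(1, center=(0.0, 0.0, 0.0))
        rf0 = forward_project(pf, arr, VS)
        delta = 1.5e-3
        arr2 = arr.shifted((0.0, 0.0, -delta))
        rf1 = forward_project(pf, arr2, VS)
        t0 = rf0.times[np.argmax(np.abs(rf0.samples[0]))]
        t1 = rf1.times[np.argmax(np.abs(rf1.samples[0]))]
        # moving the detector 1.5 mm away delays arrival by ~delta/vs
        assert t1 - t0 == pytest.approx(delta / VS, abs=3 * rf0.dt_sample)

    def test_seeded_noise_is_reproducible(self, free_grid):
        pf = field_with(free_grid, [((16, 16, 20), 1.0)])
        arr = TransducerArray.linear(4, center=(0.0, 0.0, 0.0))
        ns = NoiseSpec(channel_snr_db=30.0, pulse_jitter_frac=0.02, seed=7)
        a = forward_project(pf, arr, VS, noise=ns)
        b = forward_project(pf, arr, VS, noise=ns)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestUBP:
    def test_zero_rf_gives_zero_image(self, free_grid):
        arr = TransducerArray.linear(8, center=(0.0, 0.0, 0.0))
        rf = RFData(samples=np.zeros((8, 512)), dt_sample=2.5e-8)
        rec = ubp_reconstruct(rf, arr, VS, free_grid)
        assert np.all(rec.p0 == 0)

    def test_point_source_round_trip(self, free_grid):
        pf = field_with(free_grid, [((16, 16, 18), 1.0)])
        arr = TransducerArray.planar(16, 16, 1e-3, center=(0.0, 0.0, 0.0))
        rf = forward_project(pf, arr, VS)
        rec = ubp_reconstruct(rf, arr, VS, free_grid)
        peak = np.array(np.unravel_index(np.argmax(np.abs(rec.p0)),
                                         free_grid.shape))
        assert np.abs(peak - np.array([16, 16, 18])).max() <= 1

    def test_two_point_amplitude_ratio(self, free_grid):
        pf = field_with(free_grid, [((11, 16, 16), 2.0), ((21, 16, 20), 1.0)])
        arr = TransducerArray.planar(16, 16, 1.2e-3, center=(0.0, 0.0, 0.0))
        rf = forward_project(pf, arr, VS)
        rec = ubp_reconstruct(rf, arr, VS, free_grid)
        a = np.abs(rec.p0[9:14, 14:19, 14:19]).max()
        b = np.abs(rec.p0[19:24, 14:19, 18:23]).max()
        assert a / b == pytest.approx(2.0, rel=0.05)

    def test_elements_outside_coverage_warn_not_silent(self, free_grid):
        arr = TransducerArray.linear(8, center=(0.0, 0.0, 0.0))
        rf = RFData(samples=np.random.default_rng(0).standard_normal((8, 32)),
                    dt_sample=2.5e-8)
        with pytest.warns(UserWarning, match="time coverage"):
            ubp_reconstruct(rf, arr, VS, free_grid)

    def test_limited_view_concentrates_on_upper_surface(self, free_grid):
        """Top-lit absorbing sphere: the reconstruction images the proximal
        cap and does not invent energy below the sphere center."""
        ii, jj, kk = np.indices(free_grid.shape)
        r2 = (ii - 16.0) ** 2 + (jj - 16.0) ** 2 + (kk - 16.0) ** 2
        shell = ((r2 <= 6.0**2) & (r2 >= 4.0**2)).astype(float)
        # illumination from the surface decays into the absorber
        shell *= np.exp(-(kk - 10.0) / 3.0)
        pf = PressureField(p0=shell, grid=free_grid)
        arr = TransducerArray.linear(64, 0.4e-3, center=(0.0, 0.0, 0.0))
        rf = forward_project(pf, arr, VS, slab=(0.0, free_grid.dl))
        rec = ubp_reconstruct(rf, arr, VS, free_grid, slab=(0.0, free_grid.dl))
        mag = np.abs(rec.p0)
        strong = mag >= 0.25 * mag.max()
        kz = np.indices(free_grid.shape)[2]
        centroid_z = (mag * strong * kz).sum() / (mag * strong).sum()
        assert centroid_z < 16.0  # energy sits above the sphere center


class TestTransducerArray:
    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="sampling_rate"):
            TransducerArray(sampling_rate=8e6)

    def test_default_is_128_element_linear(self):
        arr = TransducerArray()
        assert arr.n_elements == 128
        assert arr.center_frequency == 5.5e6
        assert np.allclose(arr.element_positions[:, 1:], 0.0)


class TestDeconvolution:
    def test_identity_mode_passthrough(self):
        rf = RFData(samples=np.random.default_rng(0).standard_normal((2, 256)),
                    dt_sample=2.5e-8)
        arr = TransducerArray.linear(2)
        out = estimate_deconvolution(rf, arr)
        np.testing.assert_array_equal(out.samples, rf.samples)

    def test_equalize_flattens_in_band_spectrum(self):
        arr = TransducerArray.linear(1)
        n = 1024
        dt = 1.0 / arr.sampling_rate
        t = np.arange(n) * dt
        fc = arr.center_frequency
        sigma = arr.bandwidth * fc / 2.355
        # band-limited pulse: gaussian envelope carrier
        pulse = np.exp(-0.5 * ((t - n // 2 * dt) * 2 * np.pi * sigma) ** 2) \
            * np.cos(2 * np.pi * fc * (t - n // 2 * dt))
        rf = RFData(samples=pulse[None, :], dt_sample=dt)
        with pytest.warns(UserWarning, match="idempotent"):
            out = estimate_deconvolution(rf, arr, mode="equalize")
        freqs = np.fft.rfftfreq(n, dt)
        band = (freqs > fc * 0.8) & (freqs < fc * 1.2)
        spec_in = np.abs(np.fft.rfft(rf.samples[0]))[band]
        spec_out = np.abs(np.fft.rfft(out.samples[0]))[band]
        # equalization reduces in-band spectral ripple
        assert (spec_out.std() / spec_out.mean()
                < spec_in.std() / spec_in.mean())

    def test_equalize_not_idempotent(self):
        arr = TransducerArray.linear(1)
        rf = RFData(samples=np.random.default_rng(1).standard_normal((1, 256)),
                    dt_sample=1.0 / arr.sampling_rate)
        with pytest.warns(UserWarning):
            once = estimate_deconvolution(rf, arr, mode="equalize")
        with pytest.warns(UserWarning):
            twice = estimate_deconvolution(once, arr, mode="equalize")
        assert not np.allclose(once.samples, twice.samples)
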