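"""Directional phase gradient analysis: filters, autocorrelation, k maps."""

import numpy as np
import pytest

import asyncoce as ao
from asyncoce.dpga import (
    WindowSpec,
    aggregate_directions,
    phase_gradient_k,
    windowed_autocorrelation,
    windowed_autocorrelation_direct,
)


def complex_exponential(shape, kx, ky, dx, dy):
    x = np.arange(shape[0])[:, None] * dx
    y = np.arange(shape[1])[None, :] * dy
    return np.exp(1j * 2 * np.pi * (kx * x + ky * y))


class TestFilterBank:
    def test_squared_gains_partition_azimuth(self, grid75):
        """Sum over directions of gain^2 is azimuth-independent (within 5%)."""
        bank = ao.build_filter_bank((75, 75), grid75.dx, grid75.dy)
        g2 = np.sum(bank.gains**2, axis=0)
        kx = np.fft.fftfreq(75, grid75.dx)[:, None]
        ky = np.fft.fftfreq(75, grid75.dy)[None, :]
        r = np.hypot(kx * np.ones((1, 75)), ky * np.ones((75, 1)))
        ring = (r > 500) & (r < 2500)
        vals = g2[ring]
        assert (vals.max() - vals.min()) / vals.mean() < 0.05

    def test_opposite_filters_have_disjoint_support(self, grid75):
        bank = ao.build_filter_bank((75, 75), grid75.dx, grid75.dy)
        for d in range(16):
            overlap = bank.gains[d] * bank.gains[d + 16]
            assert np.all(overlap == 0)

    def test_narrow_filters_approach_quadrant_masks(self, grid75):
        bank = ao.build_filter_bank((75, 75), grid75.dx, grid75.dy, n_dirs=4, sigma_theta=1e-3)
        g = bank.gains[0]  # centered on +kx
        kx = np.fft.fftfreq(75, grid75.dx)[:, None] * np.ones((1, 75))
        ky = np.fft.fftfreq(75, grid75.dy)[None, :] * np.ones((75, 1))
        on_axis = (np.abs(np.arctan2(ky, kx)) < 1e-6) & (kx > 0)
        off_axis = np.abs(np.arctan2(ky, kx)) > 0.2
        assert np.all(g[on_axis] > 0.99)
        assert np.all(g[off_axis] < 1e-4)

    def test_invalid_parameters_rejected(self, grid75):
        with pytest.raises(ValueError):
            ao.build_filter_bank((75, 75), grid75.dx, grid75.dy, n_dirs=2)
        with pytest.raises(ValueError):
            ao.build_filter_bank((75, 75), grid75.dx, grid75.dy, sigma_theta=0.0)


class TestApplyFilters:
    def test_plane_wave_energy_concentrates_near_its_azimuth(self, grid75):
        f = complex_exponential((75, 75), 500.0, 0.0, grid75.dx, grid75.dy)
        bank = ao.build_filter_bank(f.shape, grid75.dx, grid75.dy)
        branches = ao.apply_filters(f, bank)
        energies = np.array([np.sum(np.abs(b) ** 2) for b in branches])
        near = [d % 32 for d in (-2, -1, 0, 1, 2)]
        assert energies[near].sum() / energies.sum() > 0.9

    def test_standing_wave_splits_into_travelling_branches(self, grid75):
        """Each half-plane branch of a standing wave matches the corresponding
        single travelling wave."""
        kx = 500.0
        fwd = complex_exponential((75, 75), kx, 0.0, grid75.dx, grid75.dy)
        bwd = complex_exponential((75, 75), -kx, 0.0, grid75.dx, grid75.dy)
        bank = ao.build_filter_bank((75, 75), grid75.dx, grid75.dy)
        branches = ao.apply_filters(fwd + bwd, bank)
        b_fwd = branches[0]  # sector at azimuth 0
        b_bwd = branches[16]  # opposite sector
        corr_f = abs(np.vdot(b_fwd, fwd)) / (np.linalg.norm(b_fwd) * np.linalg.norm(fwd))
        corr_b = abs(np.vdot(b_bwd, bwd)) / (np.linalg.norm(b_bwd) * np.linalg.norm(bwd))
        assert corr_f > 0.99 and corr_b > 0.99

    def test_zero_field_gives_zero_branches(self, grid75):
        bank = ao.build_filter_bank((75, 75), grid75.dx, grid75.dy)
        branches = ao.apply_filters(np.zeros((75, 75), complex), bank)
        assert np.all(branches == 0)

    def test_shape_mismatch_rejected(self, grid75):
        bank = ao.build_filter_bank((75, 75), grid75.dx, grid75.dy)
        with pytest.raises(ValueError):
            ao.apply_filters(np.zeros((10, 10), complex), bank)


class TestWindowedAutocorrelation:
    def test_zero_lag_is_window_energy(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        acd = windowed_autocorrelation(f, WindowSpec(w=2))
        c = acd["center"]
        zero_lag = acd["ac"][..., c, c]
        wins = f.reshape(4, 2, 4, 2).transpose(0, 2, 1, 3)
        energies = np.sum(np.abs(wins) ** 2, axis=(-2, -1))
        np.testing.assert_allclose(zero_lag.real, energies, rtol=1e-10)
        assert np.abs(zero_lag.imag).max() < 1e-12 * energies.max()

    def test_pure_exponential_lag_phase(self, grid75):
        """arg AC(+1, 0) = -2*pi*kx*dx exactly for a single complex exponential."""
        kx = 500.0
        f = complex_exponential((8, 8), kx, 0.0, grid75.dx, grid75.dy)
        acd = windowed_autocorrelation(f, WindowSpec(w=2))
        c = acd["center"]
        phases = np.angle(acd["ac"][..., c + 1, c])
        np.testing.assert_allclose(phases, -2 * np.pi * kx * grid75.dx, rtol=1e-10)

    @pytest.mark.parametrize("w", [2, 4, 8])
    def test_fft_path_matches_direct_lag_sums(self, w):
        """Transform-based linear autocorrelation equals the O(w^4) brute-force
        lag sum on every window."""
        rng = np.random.default_rng(w)
        f = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        spec = WindowSpec(w=w)
        a = windowed_autocorrelation(f, spec)
        b = windowed_autocorrelation_direct(f, spec)
        np.testing.assert_allclose(a["ac"], b["ac"], atol=1e-10)

    def test_window_larger_than_field_rejected(self):
        with pytest.raises(ValueError):
            windowed_autocorrelation(np.zeros((3, 3), complex), WindowSpec(w=4))


class TestPhaseGradient:
    def test_recovers_kx_closed_form(self, grid75):
        kx = 500.0
        f = complex_exponential((16, 16), kx, 0.0, grid75.dx, grid75.dy)
        acd = windowed_autocorrelation(f, WindowSpec(w=2))
        kx_est, ky_est, k_est = phase_gradient_k(acd, grid75.dx, grid75.dy)
        np.testing.assert_allclose(kx_est, kx, rtol=1e-3)
        np.testing.assert_allclose(ky_est, 0.0, atol=1e-6)
        np.testing.assert_allclose(k_est, kx, rtol=1e-3)

    def test_constant_field_gives_zero_k(self, grid75):
        f = np.ones((8, 8), complex)
        acd = windowed_autocorrelation(f, WindowSpec(w=2))
        _, _, k = phase_gradient_k(acd, grid75.dx, grid75.dy)
        np.testing.assert_allclose(k, 0.0, atol=1e-9)

    def test_zero_window_flagged_not_raised(self, grid75):
        f = np.zeros((4, 4), complex)
        f[2:, 2:] = 1.0
        acd = windowed_autocorrelation(f, WindowSpec(w=2))
        _, _, k = phase_gradient_k(acd, grid75.dx, grid75.dy)
        assert np.isnan(k[0, 0])

    def test_window_an_eighth_of_wavelength_gives_quarter_pi_step(self, grid75):
        """The phantom geometry: a 2-px window at lambda/8 sees a pi/4 ~ 0.8 rad
        phase step per pixel pair along propagation, well above noise floor."""
        lam = 8 * 2 * grid75.dx  # window (2 px) = lambda/8
        k = 1.0 / lam
        f = complex_exponential((16, 16), k, 0.0, grid75.dx, grid75.dy)
        acd = windowed_autocorrelation(f, WindowSpec(w=2))
        c = acd["center"]
        step = np.abs(np.angle(acd["ac"][..., c + 1, c]))
        np.testing.assert_allclose(step, 2 * np.pi / 16, rtol=1e-6)  # pi/8 per px
        # over the 2-px window: pi/4
        assert 2 * step.mean() == pytest.approx(np.pi / 4, rel=1e-6)


class TestMaskingAndAggregation:
    def test_noise_only_windows_are_masked(self, grid75):
        rng = np.random.default_rng(8)
        f = (rng.standard_normal((75, 75)) + 1j * rng.standard_normal((75, 75))) / np.sqrt(2)
        mask = ao.snr_mask(f, air_rows=slice(71, 75), threshold=2.0)
        assert mask.mean() < 0.01  # ratio ~1 almost never clears 2

    def test_signal_windows_survive(self, grid75):
        f = complex_exponential((75, 75), 400.0, 0.0, grid75.dx, grid75.dy)
        f[:, 71:] = 0.001 * f[:, 71:]
        mask = ao.snr_mask(f, air_rows=slice(71, 75), threshold=2.0)
        assert np.all(mask[:, :35])

    def test_threshold_zero_keeps_all(self, grid75):
        rng = np.random.default_rng(9)
        f = rng.standard_normal((75, 75)) + 0j
        assert np.all(ao.snr_mask(f, air_rows=slice(71, 75), threshold=0.0))

    def test_uniform_and_energy_modes_agree_for_one_wave(self, grid75):
        f = complex_exponential((75, 75), 500.0, 0.0, grid75.dx, grid75.dy)
        km_u = ao.dpga_map(f, grid75.dx, grid75.dy, agg_mode="uniform")
        km_e = ao.dpga_map(f, grid75.dx, grid75.dy, agg_mode="energy")
        assert km_u.median_k() == pytest.approx(km_e.median_k(), rel=0.02)

    def test_identical_directions_aggregate_to_common_value(self):
        k_stack = np.full((32, 5, 5), 123.0)
        mask = np.ones_like(k_stack, bool)
        out = aggregate_directions(k_stack, mask, "uniform")
        np.testing.assert_allclose(out, 123.0)
        out_e = aggregate_directions(k_stack, mask, "energy", weights=np.ones_like(k_stack))
        np.testing.assert_allclose(out_e, 123.0)

    def test_fully_masked_windows_propagate_missing(self):
        k_stack = np.full((4, 2, 2), 50.0)
        mask = np.zeros_like(k_stack, bool)
        out = aggregate_directions(k_stack, mask, "uniform")
        assert np.all(np.isnan(out))


class TestSpeedModulus:
    def test_direct_arithmetic(self):
        c, G = ao.k_to_speed_modulus(500.0, 2000.0, 1000.0)
        assert c == pytest.approx(4.0)
        assert G == pytest.approx(16000.0)

    def test_frequency_scaling_consistency(self):
        c1, _ = ao.k_to_speed_modulus(250.0, 1000.0)
        c2, _ = ao.k_to_speed_modulus(500.0, 2000.0)
        assert c1 == pytest.approx(c2)

    def test_density_linearity_and_zero_k(self):
        _, g1 = ao.k_to_speed_modulus(400.0, 2000.0, 1000.0)
        _, g2 = ao.k_to_speed_modulus(400.0, 2000.0, 2000.0)
        assert g2 == pytest.approx(2 * g1)
        c, G = ao.k_to_speed_modulus(0.0, 2000.0)
        assert np.isnan(c) and np.isnan(G)


class TestConventionalBaseline:
    def test_agrees_with_dpga_for_single_wave(self, grid75):
        """No interference: the undirectional gradient matches DPGA within 3%."""
        f = complex_exponential((75, 75), 400.0, 150.0, grid75.dx, grid75.dy)
        km_d = ao.dpga_map(f, grid75.dx, grid75.dy)
        km_c = ao.conventional_pg(f, grid75.dx, grid75.dy)
        assert km_c.median_k() == pytest.approx(km_d.median_k(), rel=0.03)

    def test_standing_wave_collapses_conventional_estimate(self, grid75):
        """Equal counter-propagating waves: constant phase, so the raw
        undirectional gradient collapses toward zero while DPGA holds."""
        k = 500.0
        comps = [
            ao.PlaneWaveComponent.inplane(0.0, k=k, s_ql=1e-7),
            ao.PlaneWaveComponent.inplane(np.pi, k=k, s_ql=1e-7),
        ]
        f = ao.synthesize_true_field(comps, grid75, 0.0, 2000.0)
        km_c = ao.conventional_pg(f, grid75.dx, grid75.dy, smooth_sigma_px=0.0)
        km_d = ao.dpga_map(f, grid75.dx, grid75.dy)
        assert km_c.median_k() < 0.2 * k
        assert km_d.median_k() == pytest.approx(k, rel=0.10)

    def test_diffuse_field_conventional_variance_exceeds_dpga(self, grid75):
        """Partially diffuse field: interference inflates the spatial spread of
        the undirectional estimate relative to DPGA."""
        med = ao.MediumMap(k_bg=444.0)
        src = ao.SourceSet(n_sources=6, amplitude_m=1e-7)
        f = ao.synthesize_prong_field(src, med, grid75, 0.0, 2000.0)
        km_d = ao.dpga_map(f, grid75.dx, grid75.dy)
        km_c = ao.conventional_pg(f, grid75.dx, grid75.dy, smooth_sigma_px=0.0)
        iqr = lambda a: np.subtract(*np.nanpercentile(a, [75, 25]))
        assert iqr(km_c.k) > iqr(km_d.k)


class TestSlabAndDecimation:
    def test_depth_invariant_slab_equals_single_slice(self, protocol_1k):
        p = protocol_1k
        gen = ao.plane_wave_generator(
            [ao.PlaneWaveComponent.inplane(0.0, k=300.0, s_ql=1e-7)], p.f0_hz
        )
        vol = ao.raster_sample(gen, p, n_z=4)
        slab = ao.surface_slab_average(vol, depth_m=0.0)
        np.testing.assert_allclose(slab, vol.S[0], rtol=1e-12)
        one = ao.surface_slab_average(vol, depth_m=0.0, thickness_slices=1)
        np.testing.assert_array_equal(one, vol.S[0])

    def test_slab_averaging_improves_snr_like_sqrt_n(self, protocol_1k):
        """Depth-decorrelated noise averages down by ~sqrt(n_slices)."""
        p = protocol_1k
        gen = ao.plane_wave_generator(
            [ao.PlaneWaveComponent.inplane(0.0, k=300.0, s_ql=1e-7)], p.f0_hz
        )
        n_z = 16
        vol = ao.raster_sample(gen, p, n_z=n_z, noise_sigma=2e-8, seed=13)
        clean = ao.raster_sample(gen, p, n_z=1).S[0]
        err_one = np.linalg.norm(vol.S[0] - clean)
        err_slab = np.linalg.norm(ao.surface_slab_average(vol, depth_m=0.0) - clean)
        assert err_one / err_slab == pytest.approx(np.sqrt(n_z), rel=0.2)

    def test_slab_outside_volume_rejected(self, protocol_1k):
        p = protocol_1k
        gen = ao.plane_wave_generator(
            [ao.PlaneWaveComponent.inplane(0.0, k=300.0, s_ql=1e-7)], p.f0_hz
        )
        vol = ao.raster_sample(gen, p, n_z=4, dz=10e-6)
        with pytest.raises(ValueError):
            ao.surface_slab_average(vol, depth_m=1.0)

    def test_decimation_preserves_in_band_k(self, grid75):
        """Windowed estimates on the 1394-column field and on its 75-column
        decimation agree within 3% for in-band wavenumbers."""
        k = 444.0
        grid_fine = ao.Grid.regular(1394, 75, 12e-3)
        f = complex_exponential((1394, 75), k * np.cos(0.4), k * np.sin(0.4), grid_fine.dx, grid_fine.dy)
        dec = ao.downsample_field(f, 75, axis=0)
        km_fine = ao.dpga_map(f, grid_fine.dx, grid_fine.dy)
        km_dec = ao.dpga_map(dec, 12e-3 / 75, grid_fine.dy)
        assert km_dec.median_k() == pytest.approx(km_fine.median_k(), rel=0.03)

    def test_window_size_independence_on_clean_wave(self, grid75):
        f = complex_exponential((76, 76), 400.0, 100.0, grid75.dx, grid75.dy)
        km2 = ao.dpga_map(f, grid75.dx, grid75.dy, win=WindowSpec(w=2))
        km4 = ao.dpga_map(f, grid75.dx, grid75.dy, win=WindowSpec(w=4))
        assert km2.median_k() == pytest.approx(km4.median_k(), rel=0.05)


class TestFullPipelineMap:
    def test_map_grid_is_35_by_cropped_air(self, diffuse_volume_2k):
        vol, _ = diffuse_volume_2k
        rec = ao.recover_volume(vol)
        km = ao.analyze_volume(rec, method="dpga")
        # 75 columns -> 37 windows -> 35 after edge crop; air rows shrink y
        assert km.k.shape[0] == 35
        assert km.k.shape[1] == (vol.air_rows.start // 2) - 2

    def test_amplitude_scaling_leaves_k_unchanged(self):
        from conftest import make_prong_volume

        vols = [make_prong_volume(2000.0, 2, amp_scale=s)[0] for s in (1.0, 2.0)]
        meds = [ao.analyze_volume(ao.recover_volume(v), method="dpga").median_k() for v in vols]
        assert abs(meds[1] / meds[0] - 1) < 0.02

    def test_analyze_requires_coherent_stage(self, diffuse_volume_2k):
        vol, _ = diffuse_volume_2k
        with pytest.raises(ValueError, match="coherent"):
            ao.analyze_volume(vol, method="dpga")
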