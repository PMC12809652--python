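"""Preprocessing-chain tests: MSC, CMR, SERDS differencing, smoothing, resampling."""

import numpy as np
import pytest
from scipy.signal import savgol_filter

from ramanuq import (
    PreprocessConfig,
    Spectrum,
    SyntheticConfig,
    average_grid,
    average_replicates,
    common_mode_rejection,
    generate_dataset,
    msc_correct,
    preprocess_sample,
    resample_uniform,
    savgol_smooth,
    serds_difference,
)
from ramanuq.preprocess import (
    DegenerateSpectrumError,
    PreprocessError,
    read_dataset_matrix,
    write_dataset_matrix,
)
from ramanuq.synthetic import fluorescence_background, soc_to_raman


@pytest.fixture()
def axis():
    return np.arange(350.0, 1374.0, 2.0)  # 512 channels


@pytest.fixture()
def wiggly(axis, rng):
    return Spectrum(axis, 10 + np.sin(axis / 40.0) + 0.1 * rng.normal(size=axis.size))


class TestMSC:
    def test_reference_maps_to_itself(self, wiggly):
        (out,) = msc_correct([wiggly], reference=wiggly)
        np.testing.assert_allclose(out.intensity, wiggly.intensity, atol=1e-10)

    def test_inverts_affine_distortion_to_machine_precision(self, wiggly):
        distorted = wiggly.with_intensity(2.0 * wiggly.intensity + 3.0)
        (out,) = msc_correct([distorted], reference=wiggly)
        np.testing.assert_allclose(out.intensity, wiggly.intensity, rtol=1e-12)

    def test_idempotent_against_fixed_reference(self, wiggly, rng):
        distorted = wiggly.with_intensity(1.7 * wiggly.intensity - 4.0
                                          + 0.01 * rng.normal(size=len(wiggly)))
        once = msc_correct([distorted], reference=wiggly)
        twice = msc_correct(once, reference=wiggly)
        np.testing.assert_allclose(twice[0].intensity, once[0].intensity, atol=1e-10)

    def test_constant_spectrum_raises_degenerate_error(self, axis, wiggly):
        flat = Spectrum(axis, np.full(axis.size, 5.0), {"sample_id": "flat-01"})
        with pytest.raises(DegenerateSpectrumError, match="flat-01"):
            msc_correct([flat], reference=wiggly)

    def test_mean_reference_needs_two_spectra(self, wiggly):
        with pytest.raises(PreprocessError, match="at least 2"):
            msc_correct([wiggly], reference="mean")


class TestAverageReplicates:
    def _sample_from(self, reps, t=0.2):
        from ramanuq.synthetic import RawSample

        reps = np.asarray(reps)
        meas = np.broadcast_to(reps[None, None], (1, 2, reps.shape[0], reps.shape[1])).copy()
        return RawSample("s", 3.0, meas, np.arange(reps.shape[1], dtype=float) + 350.0, t)

    def test_identical_replicates_normalized_by_integration_time(self, rng):
        r = 5 + rng.random(64)
        sample = self._sample_from([r, r], t=0.2)
        out = average_replicates(sample)
        np.testing.assert_allclose(out[(0, 1)].intensity, r / 0.2, rtol=1e-10)

    def test_scaled_replicates_average_to_mean_after_msc(self, rng):
        v = 1 + rng.random(64)
        sample = self._sample_from([v, 3 * v], t=1.0)
        out = average_replicates(sample)
        np.testing.assert_allclose(out[(0, 2)].intensity, 2 * v, rtol=1e-10)

    def test_zero_replicates_rejected(self):
        from ramanuq.synthetic import RawSample

        sample = RawSample("s", 3.0, np.zeros((1, 2, 0, 8)), np.arange(8.0), 0.2)
        with pytest.raises(PreprocessError, match="replicate"):
            average_replicates(sample)


class TestCommonModeRejection:
    cfg = PreprocessConfig(grid_start=350, grid_stop=1350, grid_step=2, cmr_levels=5)

    def _bg(self, axis):
        return 50 * (0.5 + 0.5 * np.exp(-(((axis - 900) / 300) ** 2)) + 2e-4 * (1400 - axis))

    def test_fully_shared_background_removed(self, axis):
        bg = self._bg(axis)
        o1, o2 = common_mode_rejection(
            Spectrum(axis, bg), Spectrum(axis, 1.3 * bg + 2.0), self.cfg
        )
        assert np.max(np.abs(o1.intensity)) < 1e-3 * bg.max()
        assert np.max(np.abs(o2.intensity)) < 1e-3 * bg.max()

    def test_narrow_peak_preserved_within_10_percent(self, axis):
        bg = self._bg(axis)
        peak = 3.0 * np.exp(-0.5 * ((axis - 800) / 8.0) ** 2)
        o1, _ = common_mode_rejection(
            Spectrum(axis, bg + peak), Spectrum(axis, bg), self.cfg
        )
        height = o1.intensity[np.argmin(np.abs(axis - 800))]
        assert abs(height - 3.0) / 3.0 < 0.10

    def test_zero_background_passes_signal_through(self, axis):
        peak = 3.0 * np.exp(-0.5 * ((axis - 800) / 8.0) ** 2)
        o1, _ = common_mode_rejection(
            Spectrum(axis, peak), Spectrum(axis, 0.5 * peak), self.cfg
        )
        assert np.max(np.abs(o1.intensity - peak)) < 0.2 * peak.max()

    def test_too_deep_decomposition_rejected(self, axis):
        deep = PreprocessConfig(grid_start=350, grid_stop=1350, grid_step=2, cmr_levels=12)
        s = Spectrum(axis, self._bg(axis))
        with pytest.raises(PreprocessError, match="cmr_levels"):
            common_mode_rejection(s, s, deep)

    def test_axis_mismatch_rejected(self, axis):
        s1 = Spectrum(axis, self._bg(axis))
        s2 = Spectrum(axis + 1.0, self._bg(axis))
        with pytest.raises(PreprocessError, match="axis"):
            common_mode_rejection(s1, s2, self.cfg)


class TestSERDSDifference:
    def test_identical_spectra_cancel(self, wiggly):
        out = serds_difference(wiggly, wiggly)
        np.testing.assert_array_equal(out.intensity, np.zeros(len(wiggly)))

    def test_elementwise_arithmetic(self):
        ax = np.array([1.0, 2.0, 3.0])
        out = serds_difference(Spectrum(ax, [1, 2, 3]), Spectrum(ax, [2, 2, 2]))
        np.testing.assert_array_equal(out.intensity, [1.0, 0.0, -1.0])

    def test_antisymmetric(self, wiggly, rng):
        other = wiggly.with_intensity(wiggly.intensity + rng.normal(size=len(wiggly)))
        fwd = serds_difference(wiggly, other)
        rev = serds_difference(other, wiggly)
        np.testing.assert_allclose(fwd.intensity, -rev.intensity, atol=1e-12)

    def test_shared_fluorescence_cancels_off_peak(self, axis):
        fluor = fluorescence_background(3.0, axis, 50.0)
        r1 = soc_to_raman(3.0, axis)
        r2 = soc_to_raman(3.0, axis - 10.0)
        out = serds_difference(Spectrum(axis, fluor + r1), Spectrum(axis, fluor + r2))
        off_peak = np.abs(axis - 800.0) < 30  # no band or shifted band nearby
        assert np.max(np.abs(out.intensity[off_peak])) < 1e-10 * fluor.max()


class TestAverageGrid:
    def test_opposite_signals_cancel(self, wiggly):
        neg = wiggly.with_intensity(-wiggly.intensity)
        out = average_grid([wiggly, neg])
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_pointwise_mean(self):
        ax = np.array([1.0, 2.0])
        out = average_grid([Spectrum(ax, [1, 1]), Spectrum(ax, [3, 5])])
        np.testing.assert_array_equal(out.intensity, [2.0, 3.0])

    def test_empty_list_rejected(self):
        with pytest.raises(PreprocessError, match="empty"):
            average_grid([])


class TestSavitzkyGolay:
    def test_reproduces_quadratics_exactly(self, axis):
        quad = Spectrum(axis, 2.0 + 0.3 * axis - 0.001 * axis**2)
        out = savgol_smooth(quad, window=11, polyorder=2)
        np.testing.assert_allclose(out.intensity, quad.intensity, rtol=1e-9)

    def test_constant_unchanged(self, axis):
        const = Spectrum(axis, np.full(axis.size, 7.0))
        out = savgol_smooth(const, 11, 2)
        np.testing.assert_allclose(out.intensity, 7.0, rtol=1e-12)

    def test_impulse_center_weight_matches_normal_equations(self):
        """Center tap equals the direct 11-point order-2 least-squares weight."""
        x = np.arange(-5.0, 6.0)
        A = np.vander(x, 3, increasing=True)  # [1, x, x^2]
        H = A @ np.linalg.solve(A.T @ A, A.T)
        oracle_center_weight = H[5, 5]
        impulse = np.zeros(31)
        impulse[15] = 1.0
        out = savgol_smooth(Spectrum(np.arange(31.0), impulse), 11, 2)
        assert out.intensity[15] == pytest.approx(oracle_center_weight, rel=1e-10)

    def test_invalid_window_rejected(self, wiggly):
        with pytest.raises(PreprocessError):
            savgol_smooth(wiggly, window=10, polyorder=2)
        with pytest.raises(PreprocessError):
            savgol_smooth(wiggly, window=3, polyorder=4)


class TestResample:
    def test_default_grid_has_1650_channels(self):
        cfg = PreprocessConfig()
        native = np.arange(330.0, 2031.0)
        out = resample_uniform(Spectrum(native, np.sin(native / 100)), cfg)
        assert len(out) == 1650
        assert out.axis[0] == 350.0
        assert out.axis[-1] == 1999.0

    def test_on_grid_input_unchanged(self):
        cfg = PreprocessConfig(grid_start=350, grid_stop=1350, grid_step=2)
        grid = cfg.target_grid()
        s = Spectrum(grid, np.cos(grid / 30))
        out = resample_uniform(s, cfg)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_linear_signal_interpolated_exactly(self):
        cfg = PreprocessConfig(grid_start=350, grid_stop=1350, grid_step=2)
        coarse = np.linspace(300.0, 1400.0, 23)
        out = resample_uniform(Spectrum(coarse, 2.0 * coarse), cfg)
        np.testing.assert_allclose(out.intensity, 2.0 * cfg.target_grid(), rtol=1e-12)

    def test_uncovered_range_rejected(self):
        cfg = PreprocessConfig()
        short = np.arange(400.0, 1000.0)
        with pytest.raises(PreprocessError, match="cover"):
            resample_uniform(Spectrum(short, np.ones(short.size)), cfg)


class TestFullChain:
    fast = PreprocessConfig(grid_start=350, grid_stop=1350, grid_step=2, cmr_levels=5)

    def _sample(self, **kw):
        base = dict(
            n_samples=1, grid_shape=(2, 1), n_replicates=2,
            axis_start=330.0, axis_stop=1420.0, axis_step=2.0, seed=9,
        )
        base.update(kw)
        return generate_dataset(SyntheticConfig(**base))[0]

    def test_deterministic(self):
        sample = self._sample()
        a = preprocess_sample(sample, self.fast)
        b = preprocess_sample(sample, self.fast)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_channel_count_invariant(self):
        out = preprocess_sample(self._sample(), self.fast)
        assert len(out) == int((1350 - 350) / 2)

    def test_noiseless_output_matches_raman_difference_signal(self):
        """Zero noise/fluorescence: the chain returns the smoothed, resampled
        SERDS difference of the pure Raman components."""
        sample = self._sample(
            fluorescence_amplitude_ratio=0.0, albedo_sd=0.0,
            replicate_noise_sd=0.0, offset_sd=0.0, heteroscedastic_coeffs=(1e-12, 0.0),
        )
        out = preprocess_sample(sample, self.fast)
        soc = sample.meta["soc_spectral"]
        t = sample.integration_time
        expected = (
            soc_to_raman(soc, sample.axis - 10.0) - soc_to_raman(soc, sample.axis)
        ) / t
        expected = np.interp(out.axis, sample.axis, savgol_filter(expected, 11, 2,
                                                                  mode="interp"))
        scale = np.max(np.abs(expected))
        # CMR baselines of narrow bands bias the chain slightly; shape must match
        assert np.corrcoef(out.intensity, expected)[0, 1] > 0.99
        assert np.max(np.abs(out.intensity - expected)) < 0.15 * scale

    def test_common_scaling_is_exactly_equivariant(self):
        sample = self._sample()
        scaled = self._sample()
        scaled.measurements = scaled.measurements * 3.0
        a = preprocess_sample(sample, self.fast)
        b = preprocess_sample(scaled, self.fast)
        np.testing.assert_allclose(b.intensity, 3.0 * a.intensity, rtol=1e-8)

    def test_per_replicate_affine_distortion_removed_by_msc(self):
        """Replicate-level gain/offset changes that keep the set mean fixed
        do not alter the output."""
        sample = self._sample(replicate_noise_sd=0.0, offset_sd=0.0)
        baseline = preprocess_sample(sample, self.fast)
        distorted = self._sample(replicate_noise_sd=0.0, offset_sd=0.0)
        m = distorted.measurements
        # swap replicate gains around the same mean: r0*(1+e), r1*(1-e') with
        # means preserved channelwise is hard analytically; instead distort one
        # replicate and rebuild the other so the set mean stays identical
        orig_mean = m[:, :, :, :].mean(axis=2, keepdims=True)
        m[:, :, 0, :] = m[:, :, 0, :] * 1.3 + 0.5
        m[:, :, 1, :] = 2 * orig_mean[:, :, 0, :] - m[:, :, 0, :]
        # note: mean preserved but individual replicates are affine-distorted
        out = preprocess_sample(distorted, self.fast)
        assert np.corrcoef(out.intensity, baseline.intensity)[0, 1] > 0.999

    def test_fluorescence_energy_reduced_tenfold(self):
        """CMR + differencing removes >= 10x the integrated fluorescence."""
        sample = self._sample(replicate_noise_sd=0.0, offset_sd=0.0)
        soc = sample.meta["soc_spectral"]
        albedo = sample.meta["albedo"]
        fluor_in = (
            albedo * fluorescence_background(soc, sample.axis, 50.0)
            / sample.integration_time
        )
        no_fluor = self._sample(
            replicate_noise_sd=0.0, offset_sd=0.0, fluorescence_amplitude_ratio=0.0
        )
        with_f = preprocess_sample(sample, self.fast)
        without_f = preprocess_sample(no_fluor, self.fast)
        residual_fluor = np.trapezoid(np.abs(with_f.intensity - without_f.intensity),
                                      with_f.axis)
        input_fluor = np.trapezoid(
            np.abs(np.interp(with_f.axis, sample.axis, fluor_in)), with_f.axis
        )
        assert input_fluor / residual_fluor >= 10.0

    def test_matrix_round_trip(self, tmp_path, tiny_dataset):
        from ramanuq.preprocess import preprocess_dataset

        X, y = preprocess_dataset(tiny_dataset[:3], self.fast)
        path = write_dataset_matrix(X, y, tmp_path / "m.csv")
        X2, y2 = read_dataset_matrix(path)
        np.testing.assert_allclose(X2, X, rtol=1e-6)
        np.testing.assert_allclose(y2, y, rtol=1e-6)
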