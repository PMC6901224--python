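import numpy as np
import pytest

from deepmaldi import FeatureDefinition, MzGrid
from deepmaldi.noise import noise_profile
from deepmaldi.preprocess import (
    AverageSpectrum,
    CalibrationSet,
    Excluded,
    align_raw_spectrum,
    average_spectra,
    detect_calibration_points,
    integrate_features,
    lower_hull_baseline,
    normalize,
    process_average,
    realign_average,
    subtract_background,
)
from deepmaldi.io import RawSpectrum
from deepmaldi.simulate import GroundTruth, simulate_raw_spectrum

from conftest import make_isolated_gaussian


def _flat_truth(centers, amps, widths, noise=0.0, jitter=0.0):
    return GroundTruth(np.asarray(centers, float), np.asarray(amps, float),
                       np.asarray(widths, float),
                       baseline=lambda mz: np.zeros_like(np.asarray(mz, float)),
                       noise_sigma=noise, jitter_scale=jitter)


@pytest.fixture(scope="module")
def five_peak_truth():
    return _flat_truth([4000, 5000, 6000, 7000, 8000],
                       [500, 800, 600, 900, 700], [4, 5, 6, 7, 8])


class TestCalibrationPoints:
    def test_noiseless_identical_spectra_yield_apex_positions(self, small_grid, five_peak_truth):
        pool = [simulate_raw_spectrum(five_peak_truth, small_grid, seed=i) for i in range(4)]
        calset = detect_calibration_points(pool)
        assert len(calset) == 5
        np.testing.assert_allclose(np.sort(calset.points), five_peak_truth.centers,
                                   atol=small_grid.step)

    def test_minority_peak_excluded_by_presence_rule(self, small_grid):
        with_extra = _flat_truth([4000, 5000, 6000, 6500], [500, 800, 600, 700],
                                 [4, 5, 6, 6])
        without = _flat_truth([4000, 5000, 6000], [500, 800, 600], [4, 5, 6])
        # extra peak present in 2 of 5 spectra (40%) at presence_fraction 0.5
        pool = [simulate_raw_spectrum(with_extra, small_grid, seed=i) for i in range(2)]
        pool += [simulate_raw_spectrum(without, small_grid, seed=i) for i in range(3)]
        calset = detect_calibration_points(pool, presence_fraction=0.5)
        assert len(calset) == 3
        assert not np.any(np.abs(calset.points - 6500) < 10)

    def test_low_snr_peak_excluded_at_threshold(self, small_grid):
        # peak of SNR ~2 in every spectrum, threshold 3: measured noise ~1
        truth = _flat_truth([4000, 5000, 6000], [500, 800, 2.0], [4, 5, 6], noise=1.0)
        pool = [simulate_raw_spectrum(truth, small_grid, seed=i) for i in range(6)]
        calset = detect_calibration_points(pool, snr_threshold=3.0)
        assert not np.any(np.abs(calset.points - 6000) < 10)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_calibration_points([])

    def test_calibration_set_needs_two_points(self):
        with pytest.raises(ValueError, match="2 points"):
            CalibrationSet(np.array([5000.0]))


class TestAlignment:
    def test_zero_jitter_gives_identity_level_correction(self, small_grid, five_peak_truth):
        raw = simulate_raw_spectrum(five_peak_truth, small_grid, seed=1)
        calset = CalibrationSet(five_peak_truth.centers.copy())
        out = align_raw_spectrum(raw, calset)
        assert isinstance(out, RawSpectrum)
        assert out.aligned
        # identity correction: intensities essentially unchanged
        np.testing.assert_allclose(out.intensities, raw.intensities, atol=1e-6)

    def test_known_affine_warp_is_inverted(self, small_grid, five_peak_truth):
        # apply a = 1.0005, b = 2 Da by evaluating the clean signal at a*x+b
        a, b = 1.0005, 2.0
        warped = five_peak_truth.signal(a * small_grid.mz + b)
        raw = RawSpectrum(grid=small_grid, intensities=warped)
        calset = CalibrationSet(five_peak_truth.centers.copy())
        # this warp shifts apexes by ~4-6 Da; widen the matching tolerance
        out = align_raw_spectrum(raw, calset, match_tol=lambda mz: max(2.0, 1.5e-3 * mz))
        assert isinstance(out, RawSpectrum)
        for center, amp in zip(five_peak_truth.centers, five_peak_truth.amplitudes):
            window = slice(*[np.searchsorted(small_grid.mz, center + d) for d in (-30, 30)])
            apex = small_grid.mz[window][np.argmax(out.intensities[window])]
            assert abs(apex - center) <= 0.5 * small_grid.step + 1e-9

    def test_unmatchable_spectrum_flagged_excluded(self, small_grid, five_peak_truth):
        raw = simulate_raw_spectrum(five_peak_truth, small_grid, seed=1)
        calset = CalibrationSet(np.array([4300.0, 5300.0, 6300.0, 7300.0]))
        out = align_raw_spectrum(raw, calset, min_match_fraction=0.6)
        assert isinstance(out, Excluded)
        assert "0/4" in out.reason

    def test_degenerate_fit_rejected(self, small_grid):
        # both calibration points match the same single observed peak
        truth = _flat_truth([5000], [900], [5])
        raw = simulate_raw_spectrum(truth, small_grid, seed=1)
        calset = CalibrationSet(np.array([4999.6, 5000.4]))
        with pytest.raises(ValueError, match="degenerate"):
            align_raw_spectrum(raw, calset, min_match_fraction=0.5)


class TestAveraging:
    def test_thousand_raw_spectra_give_800k_shots(self, small_grid):
        base = RawSpectrum(grid=small_grid, intensities=np.zeros(len(small_grid)),
                           aligned=True)
        pool = [base.copy() for _ in range(1000)]
        avg = average_spectra(pool, 1000, seed=0)
        assert avg.n_shots == 800_000
        assert avg.n_raw == 1000

    def test_averaging_copies_of_one_spectrum_returns_it_exactly(self, small_grid):
        rng = np.random.default_rng(4)
        y = rng.uniform(0, 100, len(small_grid))
        pool = [RawSpectrum(grid=small_grid, intensities=y.copy(), aligned=True)
                for _ in range(7)]
        avg = average_spectra(pool, 7, seed=0)
        # identical up to one rounding of the mean (sum/n float arithmetic)
        np.testing.assert_allclose(avg.intensities, y, rtol=5e-15, atol=0)

    def test_noise_of_mean_of_100_is_sigma_over_10(self, small_grid):
        rng = np.random.default_rng(5)
        sigma = 2.0
        pool = [RawSpectrum(grid=small_grid,
                            intensities=sigma * rng.standard_normal(len(small_grid)),
                            aligned=True) for _ in range(100)]
        avg = average_spectra(pool, 100, seed=1)
        assert abs(avg.intensities.std(ddof=1) - sigma / 10) < 0.1 * (sigma / 10)

    def test_selection_is_deterministic_and_without_replacement(self, aligned_pool):
        a1 = average_spectra(aligned_pool, 10, seed=42)
        a2 = average_spectra(aligned_pool, 10, seed=42)
        np.testing.assert_array_equal(a1.intensities, a2.intensities)
        assert len(set(a1.provenance)) == 10

    def test_unaligned_member_rejected(self, small_grid, five_peak_truth):
        raw = simulate_raw_spectrum(five_peak_truth, small_grid, seed=1)
        raw.aligned = False
        with pytest.raises(ValueError, match="not aligned"):
            average_spectra([raw], 1, seed=0)

    def test_oversized_request_rejected(self, aligned_pool):
        with pytest.raises(ValueError, match="exceeds"):
            average_spectra(aligned_pool, len(aligned_pool) + 1, seed=0)


class TestConvexHullBackground:
    def test_affine_spectrum_has_zero_residual(self, small_grid):
        y = 3.0 * small_grid.mz + 17.0
        base = lower_hull_baseline(small_grid.mz, y)
        np.testing.assert_array_equal(base, y)

    def test_convex_profile_has_zero_residual(self, small_grid):
        y = (small_grid.mz - 6000.0) ** 2 / 1000.0 + 5.0
        avg = AverageSpectrum(grid=small_grid, intensities=y)
        out = subtract_background(avg)
        assert np.max(np.abs(out.intensities)) < 1e-9 * np.max(y)

    def test_gaussian_peak_on_linear_baseline_recovered(self, small_grid):
        amp, center, sig = 250.0, 6000.0, 5.0
        y = 0.01 * small_grid.mz + 30.0 + make_isolated_gaussian(small_grid, center, amp, sig)
        avg = AverageSpectrum(grid=small_grid, intensities=y)
        out = subtract_background(avg)
        apex = out.intensities[np.searchsorted(small_grid.mz, center)]
        assert abs(apex - amp) / amp < 0.02
        assert np.all(out.intensities >= 0)

    def test_double_subtraction_rejected(self, small_grid):
        avg = AverageSpectrum(grid=small_grid, intensities=np.ones(len(small_grid)))
        out = subtract_background(avg)
        with pytest.raises(ValueError, match="already"):
            subtract_background(out)

    def test_hull_subtraction_idempotent_in_effect(self, small_grid):
        rng = np.random.default_rng(8)
        y = rng.uniform(10, 100, len(small_grid))
        first = np.maximum(y - lower_hull_baseline(small_grid.mz, y), 0.0)
        second_hull = lower_hull_baseline(small_grid.mz, first)
        assert second_hull.sum() <= 1e-12 * max(first.sum(), 1.0)


class TestNormalization:
    def _windows(self):
        return ((6100.0, 7500.0), (8500.0, 10700.0), (13300.0, 16400.0))

    def test_window_union_sum_becomes_one(self):
        grid = MzGrid.uniform(3000.0, 30000.0, 1.0)
        rng = np.random.default_rng(9)
        avg = AverageSpectrum(grid=grid, intensities=rng.uniform(0.1, 5, len(grid)),
                              background_subtracted=True)
        out = normalize(avg)
        mask = np.zeros(len(grid), dtype=bool)
        for lo, hi in self._windows():
            mask[grid.window_slice(lo, hi)] = True
        assert out.normalized
        assert abs(out.intensities[mask].sum() - 1.0) < 1e-12

    def test_scale_invariance(self):
        grid = MzGrid.uniform(3000.0, 30000.0, 2.0)
        rng = np.random.default_rng(10)
        y = rng.uniform(0.1, 5, len(grid))
        a = normalize(AverageSpectrum(grid=grid, intensities=y, background_subtracted=True))
        b = normalize(AverageSpectrum(grid=grid, intensities=7.3 * y, background_subtracted=True))
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-12)

    def test_indicator_spectrum_matches_grid_point_count(self):
        # inclusive boundaries on a 1 Da grid: 1401 + 2201 + 3101 = 6703 points
        grid = MzGrid.uniform(3000.0, 30000.0, 1.0)
        mask = np.zeros(len(grid), dtype=bool)
        for lo, hi in self._windows():
            mask[grid.window_slice(lo, hi)] = True
        assert mask.sum() == 6703
        avg = AverageSpectrum(grid=grid, intensities=mask.astype(float),
                              background_subtracted=True)
        out = normalize(avg)
        np.testing.assert_allclose(out.intensities[mask], 1.0 / 6703, rtol=1e-12)

    def test_requires_background_subtraction(self, small_grid):
        avg = AverageSpectrum(grid=small_grid, intensities=np.ones(len(small_grid)))
        with pytest.raises(ValueError, match="background"):
            normalize(avg, windows=((4000.0, 5000.0),))

    def test_zero_normalization_constant_rejected(self, small_grid):
        avg = AverageSpectrum(grid=small_grid, intensities=np.zeros(len(small_grid)),
                              background_subtracted=True)
        with pytest.raises(ValueError, match="not positive"):
            normalize(avg, windows=((4000.0, 5000.0),))


class TestFeatureIntegration:
    def test_zero_spectrum_gives_zero_values(self, small_grid):
        avg = AverageSpectrum(grid=small_grid, intensities=np.zeros(len(small_grid)))
        defs = [FeatureDefinition("F0", 4000, 4100), FeatureDefinition("F1", 5000, 5100)]
        values = integrate_features(avg, defs)
        assert (values == 0).all()

    def test_unit_gaussian_integral_matches_closed_form(self, small_grid):
        # unit height, sigma 5 Da, 1 Da grid: sum ~ 5 * sqrt(2*pi) ~ 12.533
        y = make_isolated_gaussian(small_grid, 6000.0, 1.0, 5.0)
        avg = AverageSpectrum(grid=small_grid, intensities=y)
        values = integrate_features(avg, [FeatureDefinition("F0", 5900, 6100)])
        assert abs(values["F0"] - 5.0 * np.sqrt(2 * np.pi)) / values["F0"] < 0.01

    def test_additivity(self, small_grid):
        rng = np.random.default_rng(11)
        y1, y2 = rng.uniform(0, 3, (2, len(small_grid)))
        defs = [FeatureDefinition("F0", 4000, 4500), FeatureDefinition("F1", 4400, 4800)]
        v1 = integrate_features(AverageSpectrum(grid=small_grid, intensities=y1), defs)
        v2 = integrate_features(AverageSpectrum(grid=small_grid, intensities=y2), defs)
        v12 = integrate_features(AverageSpectrum(grid=small_grid, intensities=y1 + y2), defs)
        np.testing.assert_allclose(v12, v1 + v2, rtol=1e-12)

    def test_empty_interval_error_names_feature(self):
        grid = MzGrid.uniform(3000.0, 9000.0, 10.0)
        avg = AverageSpectrum(grid=grid, intensities=np.zeros(len(grid)))
        with pytest.raises(ValueError, match="F9"):
            integrate_features(avg, [FeatureDefinition("F9", 4001.0, 4009.0)])

    def test_shared_boundary_point_counts_in_both_features(self, small_grid):
        y = np.ones(len(small_grid))
        defs = [FeatureDefinition("L", 4000, 4100), FeatureDefinition("R", 4100, 4200)]
        values = integrate_features(AverageSpectrum(grid=small_grid, intensities=y), defs)
        assert values["L"] == 101 and values["R"] == 101  # 4100 in both


class TestFullPipeline:
    def test_pipeline_is_deterministic(self, aligned_pool, small_truth):
        defs = [FeatureDefinition(f"F{i}", c - 15, c + 15)
                for i, c in enumerate(small_truth.centers[:10])]
        windows = ((4000.0, 8000.0),)
        outs = []
        for _ in range(2):
            avg = average_spectra(aligned_pool, 16, seed=5)
            _, values = process_average(avg, defs, windows=windows)
            outs.append(values)
        assert (outs[0] == outs[1]).all()

    def test_realign_average_reuses_affine_code_path(self, small_grid, five_peak_truth):
        a, b = 1.0004, 1.5
        warped = five_peak_truth.signal(a * small_grid.mz + b)
        avg = AverageSpectrum(grid=small_grid, intensities=warped,
                              background_subtracted=True)
        calset = CalibrationSet(five_peak_truth.centers.copy())
        out = realign_average(avg, calset, match_tol=lambda mz: max(2.0, 1.5e-3 * mz))
        assert isinstance(out, AverageSpectrum)
        apex = small_grid.mz[np.argmax(out.intensities)]
        strongest = five_peak_truth.centers[np.argmax(five_peak_truth.amplitudes)]
        assert abs(apex - strongest) <= small_grid.step

    def test_noise_of_averages_follows_inverse_sqrt_law(self, aligned_pool):
        from deepmaldi.metrics import fit_power_law
        eval_points = np.linspace(3500, 8500, 6)
        shots, sigmas = [], []
        for n in [1, 4, 16, 64]:
            avg = average_spectra(aligned_pool, n, seed=n)
            sub = subtract_background(avg)
            prof = noise_profile(sub, eval_points)
            shots.append(avg.n_shots)
            sigmas.append(float(np.median(prof.sigma)))
        slope, _ = fit_power_law(shots, sigmas)
        assert abs(slope + 0.5) < 0.05
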