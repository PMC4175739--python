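"""Kinetic readouts: ROI curves, rates, spreading, mechanism calls."""
import numpy as np
import pytest

from pcmfrap.exceptions import PcmFrapError
from pcmfrap.kinetics import (ModeThresholds, RecoveryCurve, RoiSpec,
                              acceleration_index, classify_mode,
                              double_bleach_compare, fwhm_series, initial_rate,
                              recovery_profiles, rescale_peripheral, roi_curve,
                              shape_deviation, spread_index)
from pcmfrap.profiling import ProfileSet, RadialProfile, RingGrid

GRID = RingGrid(spacing=0.028, span=1.54)


def gaussian_profile(amplitude, sigma, normalized=False):
    values = amplitude * np.exp(-GRID.radii**2 / (2 * sigma**2))
    return RadialProfile(radii=GRID.radii, values=values,
                         n_subpixels=np.full(GRID.n_rings, 25),
                         spacing=GRID.spacing, background_subtracted=True,
                         normalized=normalized)


def make_pset(amplitudes, sigmas, times=None):
    """Prebleach at t=-10, baseline (zero) at t=0, then Gaussian recoveries."""
    n = len(amplitudes)
    times = np.array([-10.0, 0.0] + list(10.0 * np.arange(1, n + 1))
                     if times is None else times)
    profiles = [gaussian_profile(1.0, 0.4, normalized=True),
                gaussian_profile(0.0, 0.4)]
    profiles += [gaussian_profile(a, s) for a, s in zip(amplitudes, sigmas)]
    return ProfileSet(times=times, profiles=profiles, n_centrosomes=10,
                      bleach_times=np.array([0.0]), prebleach_index=0)


class TestRoi:
    def test_default_bands_select_five_rings_each(self):
        prof = gaussian_profile(1.0, 0.4)
        roi = RoiSpec()
        assert RoiSpec.rings_in_band(prof, roi.central).sum() == 5
        assert RoiSpec.rings_in_band(prof, roi.peripheral).sum() == 5

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            RoiSpec(central=(0.0, 0.5), peripheral=(0.4, 0.8))

    def test_roi_curve_is_band_mean(self):
        pset = make_pset([1.0], [0.4])
        flat = [RadialProfile(radii=GRID.radii, values=np.full(GRID.n_rings, 3.0),
                              n_subpixels=np.full(GRID.n_rings, 1),
                              spacing=GRID.spacing) for _ in range(3)]
        pset = ProfileSet(times=np.array([-1.0, 0.0, 1.0]), profiles=flat,
                          n_centrosomes=10, bleach_times=np.array([0.0]),
                          prebleach_index=0)
        curve = roi_curve(pset, (0.028, 0.14))
        assert np.allclose(curve.values, 3.0)


class TestRates:
    def test_exact_linear_slope(self):
        curve = RecoveryCurve(times=np.arange(-10.0, 61.0, 10.0),
                              values=np.concatenate([[5.0], 0.02 * np.arange(0, 61, 10)]),
                              bleach_times=[0.0])
        est = initial_rate(curve, window=60.0)
        assert np.isclose(est.slope, 0.02)
        assert est.n_points == 7
        assert np.isclose(est.stderr, 0.0, atol=1e-12)

    def test_rate_invariant_to_baseline_shift(self):
        t = np.arange(-10.0, 61.0, 10.0)
        v = np.where(t < 0, 5.0, 0.01 * t)
        a = initial_rate(RecoveryCurve(t, v, [0.0]))
        b = initial_rate(RecoveryCurve(t, v + 2.5, [0.0]))
        assert np.isclose(a.slope, b.slope)

    def test_rate_scales_with_values(self):
        t = np.arange(-10.0, 61.0, 10.0)
        v = np.where(t < 0, 5.0, 0.01 * t)
        a = initial_rate(RecoveryCurve(t, v, [0.0]))
        b = initial_rate(RecoveryCurve(t, 3.0 * v, [0.0]))
        assert np.isclose(b.slope, 3.0 * a.slope)

    def test_too_few_samples_rejected(self):
        curve = RecoveryCurve(times=[-1.0, 0.0, 100.0], values=[1.0, 0.0, 0.5],
                              bleach_times=[0.0])
        with pytest.raises(PcmFrapError):
            initial_rate(curve, window=60.0)

    def test_rescale_peripheral_matches_prebleach_means(self):
        t = np.array([-10.0, -5.0, 0.0, 10.0])
        central = RecoveryCurve(t, [4.0, 4.0, 0.0, 1.0], [0.0])
        peripheral = RecoveryCurve(t, [1.0, 1.0, 0.0, 0.25], [0.0])
        scaled = rescale_peripheral(peripheral, central)
        assert np.isclose(scaled.prebleach_mean(), central.prebleach_mean())
        assert np.allclose(scaled.values, 4.0 * peripheral.values)


class TestAcceleration:
    def test_quadratic_coefficient_recovered(self):
        t = np.arange(-10.0, 121.0, 10.0)
        v = np.where(t < 0, 1.0, 3e-5 * t**2)
        assert np.isclose(acceleration_index(RecoveryCurve(t, v, [0.0])), 3e-5)

    def test_saturating_recovery_scores_negative(self):
        t = np.arange(-10.0, 121.0, 10.0)
        v = np.where(t < 0, 1.0, 1.0 - np.exp(-t / 40.0))
        assert acceleration_index(RecoveryCurve(t, v, [0.0])) < 0


class TestDoubleBleach:
    def test_rates_and_ratio_on_synthetic_two_phase_data(self):
        t = np.arange(-10.0, 301.0, 10.0)
        v = np.where(t < 0, 5.0,
                     np.where(t < 180.0, 0.02 * t, 0.01 * (t - 180.0)))
        curve = RecoveryCurve(t, v, [0.0, 180.0])
        r1, r2, ratio = double_bleach_compare(curve)
        assert np.isclose(r1.slope, 0.02)
        assert np.isclose(r2.slope, 0.01)
        assert np.isclose(ratio, 0.5)

    def test_requires_exactly_two_bleaches(self):
        t = np.arange(-10.0, 61.0, 10.0)
        curve = RecoveryCurve(t, np.abs(t), [0.0])
        with pytest.raises(PcmFrapError):
            double_bleach_compare(curve)


class TestRecoveryBaseline:
    def test_baseline_frame_subtracted_and_excluded(self):
        pset = make_pset([0.3, 0.6], [0.4, 0.4])
        # add residual 0.1 * prebleach into baseline and all post frames
        for p in pset.profiles[1:]:
            p.values = p.values + 0.1 * pset.prebleach.values
        ts, recs = recovery_profiles(pset)
        assert np.allclose(ts, [10.0, 20.0])
        assert np.allclose(recs[0].values,
                           0.3 * np.exp(-GRID.radii**2 / (2 * 0.4**2)))

    def test_missing_post_bleach_frame_rejected(self):
        pset = make_pset([0.5], [0.4])
        pset.bleach_times = np.array([999.0])
        with pytest.raises(PcmFrapError):
            recovery_profiles(pset)


class TestSpreadAndShape:
    def test_widening_recovery_has_positive_significant_slope(self):
        sigmas = [0.15, 0.2, 0.25, 0.3, 0.35]
        pset = make_pset([0.2, 0.4, 0.6, 0.8, 0.9], sigmas)
        ts, ws, pre = fwhm_series(pset)
        factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
        assert np.allclose(ws, factor * np.array(sigmas), rtol=0.02)
        assert np.isclose(pre, factor * 0.4, rtol=0.02)
        est = spread_index(pset)
        assert est.slope > 0
        assert est.t_stat > 10

    def test_constant_shape_recovery_has_flat_width_and_zero_deviation(self):
        pset = make_pset([0.2, 0.5, 0.8], [0.4, 0.4, 0.4])
        _, ws, pre = fwhm_series(pset)
        assert np.allclose(ws, pre, rtol=1e-6)
        _, devs = shape_deviation(pset)
        assert np.all(devs < 1e-9)

    def test_narrow_recovery_has_large_deviation(self):
        pset = make_pset([0.3], [0.15])
        _, devs = shape_deviation(pset)
        assert devs[0] > 0.1


class TestClassify:
    def test_flux_like_series_called_inside_out(self):
        pset = make_pset([0.2, 0.4, 0.6, 0.8, 0.9],
                         [0.15, 0.2, 0.25, 0.3, 0.35])
        call = classify_mode(pset)
        assert call.call == "inside_out"
        assert call.evidence["early_fwhm_ratio"] < 0.8

    def test_even_series_called_distributed(self):
        pset = make_pset([0.2, 0.5, 0.7, 0.85, 0.95],
                         [0.4, 0.4, 0.4, 0.4, 0.4])
        call = classify_mode(pset)
        assert call.call == "distributed"
        assert call.evidence["shape_deviation_max"] < 0.05

    def test_signal_free_series_is_indeterminate(self):
        # post-bleach frames with no recovered signal (noise below background):
        # widths are unmeasurable and the shape matches nothing
        rng = np.random.default_rng(5)
        profiles = [gaussian_profile(1.0, 0.4, normalized=True)]
        for _ in range(5):
            p = gaussian_profile(0.0, 0.4)
            p.values = rng.normal(-0.3, 0.05, size=GRID.n_rings)
            profiles.append(p)
        pset = ProfileSet(times=np.array([-10.0, 0.0, 10.0, 20.0, 30.0, 40.0]),
                          profiles=profiles, n_centrosomes=10,
                          bleach_times=np.array([0.0]), prebleach_index=0)
        assert classify_mode(pset).call == "indeterminate"

    def test_too_few_time_points_rejected(self):
        pset = make_pset([0.5], [0.4])
        with pytest.raises(PcmFrapError):
            classify_mode(pset)

    def test_thresholds_are_respected(self):
        pset = make_pset([0.2, 0.5, 0.7, 0.85, 0.95],
                         [0.4, 0.4, 0.4, 0.4, 0.4])
        strict = ModeThresholds(shape_dev_max=0.0)
        assert classify_mode(pset, strict).call == "indeterminate"
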