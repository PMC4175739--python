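"""Radial profiler: upsampling, centring, ring averages, widths."""
import numpy as np
import pytest

from pcmfrap.exceptions import (GridMismatchError, NormalizationError,
                                NoSignalError, PcmFrapError, UnboundedWidthError)
from pcmfrap.images import ImageStack
from pcmfrap.profiling import (ProfileSet, RadialProfile, RingGrid,
                               average_profiles, compare_to_reference,
                               estimate_cytosol_background, find_center,
                               normalize_and_mirror, normalize_to_prebleach_peak,
                               profile_fwhm, radial_profile, subtract_background,
                               upsample_image)


def make_profile(values, spacing=0.1, **flags):
    values = np.asarray(values, dtype=float)
    radii = (np.arange(values.size) + 0.5) * spacing
    return RadialProfile(radii=radii, values=values,
                         n_subpixels=np.ones(values.size, dtype=int),
                         spacing=spacing, **flags)


class TestGrid:
    def test_default_grid_has_107_rings(self):
        g = RingGrid()
        assert g.n_rings == 107
        assert np.isclose(g.radii[0], 0.014)
        assert np.isclose(g.radii[-1], (107 - 0.5) * 0.028)

    def test_partial_ring_is_discarded(self):
        assert RingGrid(spacing=0.3, span=1.0).n_rings == 3

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            RingGrid(spacing=0.0, span=1.0)
        with pytest.raises(ValueError):
            RingGrid(spacing=0.5, span=0.2)


class TestUpsample:
    def test_single_pixel_becomes_uniform_block(self):
        img = ImageStack(np.array([[4.0]]), pixel_size=0.14)
        up = upsample_image(img, 5)
        assert up.pixels.shape == (5, 5)
        assert np.all(up.pixels == 4.0)
        assert np.isclose(up.pixel_size, 0.028)

    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        img = ImageStack(rng.uniform(size=(6, 7)), pixel_size=0.14)
        up = upsample_image(img, 3)
        assert np.isclose(up.pixels.mean(), img.pixels.mean())

    def test_factor_one_is_identity(self):
        img = ImageStack(np.arange(4.0).reshape(2, 2), pixel_size=1.0)
        up = upsample_image(img, 1)
        assert np.array_equal(up.pixels, img.pixels)

    def test_bad_factor_rejected(self):
        img = ImageStack(np.ones((2, 2)), pixel_size=1.0)
        with pytest.raises(ValueError):
            upsample_image(img, 0)


class TestFindCenter:
    def test_single_bright_pixel(self):
        img = ImageStack(np.array([[0.0, 0.0], [0.0, 8.0]]), pixel_size=1.0)
        assert np.allclose(find_center(img), (1.5, 1.5))

    def test_weighted_centroid(self):
        px = np.zeros((5, 5))
        px[2, 1] = 3.0
        px[2, 3] = 1.0
        img = ImageStack(px, pixel_size=2.0)
        x, y = find_center(img, threshold_frac=0.1)
        assert np.isclose(y, 5.0)
        assert np.isclose(x, 2.0 * (1.5 * 3 + 3.5 * 1) / 4)

    def test_flat_image_raises(self):
        with pytest.raises(NoSignalError):
            find_center(ImageStack(np.ones((4, 4)), pixel_size=1.0))

    def test_zstack_uses_brightest_plane(self):
        stack = np.zeros((3, 5, 5))
        stack[1, 2, 2] = 10.0
        x, y = find_center(ImageStack(stack, pixel_size=1.0))
        assert np.allclose((x, y), (2.5, 2.5))


class TestRadialProfile:
    def test_uniform_image_gives_flat_profile(self):
        img = ImageStack(np.full((41, 41), 3.0), pixel_size=0.1)
        prof = radial_profile(img, center=(2.05, 2.05), grid=RingGrid(0.1, 1.0))
        assert np.allclose(prof.values[prof.valid], 3.0)

    def test_rings_beyond_field_are_nan(self):
        img = ImageStack(np.ones((11, 11)), pixel_size=0.1)
        prof = radial_profile(img, center=(0.55, 0.55), grid=RingGrid(0.1, 1.0))
        # centre sits 0.55 um from every edge: rings past 0.55 um are invalid
        assert np.all(np.isfinite(prof.values[:5]))
        assert np.all(np.isnan(prof.values[5:]))

    def test_center_outside_field_rejected(self):
        img = ImageStack(np.ones((5, 5)), pixel_size=0.1)
        with pytest.raises(PcmFrapError):
            radial_profile(img, center=(2.0, 0.2))

    def test_ring_membership_is_half_open(self):
        # a pixel at distance exactly one spacing belongs to ring 1, not ring 0
        img = ImageStack(np.ones((5, 5)), pixel_size=1.0)
        prof = radial_profile(img, center=(2.5, 2.5), grid=RingGrid(1.0, 2.0))
        assert prof.n_subpixels[0] == 1           # the central pixel only
        assert prof.n_subpixels[1] == 8           # d = 1 (4 px) and d = sqrt(2) (4 px)


class TestBackground:
    def test_background_is_annulus_median(self):
        px = np.zeros((31, 31))
        img = ImageStack(px + 7.0, pixel_size=0.1)
        bg = estimate_cytosol_background(img, center=(1.55, 1.55),
                                         inner_r=0.5, outer_r=1.0)
        assert bg == 7.0

    def test_double_subtraction_rejected(self):
        prof = make_profile([1.0, 2.0])
        sub = subtract_background(prof, 0.5)
        assert np.allclose(sub.values, [0.5, 1.5])
        with pytest.raises(PcmFrapError):
            subtract_background(sub, 0.1)


class TestNormalizeMirror:
    def test_peak_is_one_and_symmetric(self):
        prof = make_profile([2.0, 4.0, 1.0], background_subtracted=True)
        nm = normalize_and_mirror(prof)
        assert nm.mirrored and nm.normalized
        assert np.isclose(nm.values.max(), 1.0)
        assert np.allclose(nm.values, nm.values[::-1])
        assert np.allclose(nm.radii, -nm.radii[::-1])

    def test_requires_background_subtraction(self):
        with pytest.raises(NormalizationError):
            normalize_and_mirror(make_profile([1.0, 2.0]))

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_and_mirror(make_profile([-1.0, -2.0],
                                              background_subtracted=True))

    def test_idempotent_on_mirrored_input(self):
        prof = make_profile([2.0, 4.0, 1.0], background_subtracted=True)
        nm = normalize_and_mirror(prof)
        again = normalize_and_mirror(nm)
        assert np.allclose(again.values, nm.values)


class TestAveraging:
    def test_mean_and_min_n(self):
        profs = [make_profile([float(i), 2.0]) for i in range(10)]
        avg = average_profiles(profs, min_n=10)
        assert np.allclose(avg.values, [4.5, 2.0])
        with pytest.raises(PcmFrapError):
            average_profiles(profs[:9], min_n=10)

    def test_grid_mismatch_rejected(self):
        a = make_profile([1.0, 2.0], spacing=0.1)
        b = make_profile([1.0, 2.0], spacing=0.2)
        with pytest.raises(GridMismatchError):
            average_profiles([a, b], min_n=2)

    def test_nan_rings_propagate(self):
        a = make_profile([1.0, np.nan])
        b = make_profile([3.0, 2.0])
        avg = average_profiles([a, b], min_n=2)
        assert avg.values[0] == 2.0 and np.isnan(avg.values[1])


class TestWidths:
    def test_triangular_profile_width(self):
        # mirrored triangle peaking at 1, reaching 0 at |r| = 1: FWHM = 1
        r = np.linspace(-1.0, 1.0, 81)
        prof = RadialProfile(radii=r, values=1.0 - np.abs(r),
                             n_subpixels=np.ones_like(r, dtype=int), spacing=0.025,
                             background_subtracted=True, normalized=True,
                             mirrored=True)
        assert np.isclose(profile_fwhm(prof), 1.0)

    def test_gaussian_profile_width(self):
        sigma = 0.2
        prof = make_profile(np.exp(-((np.arange(60) + 0.5) * 0.01)**2 / (2 * sigma**2)),
                            spacing=0.01, background_subtracted=True)
        w = profile_fwhm(normalize_and_mirror(prof))
        assert abs(w - 2.0 * np.sqrt(2 * np.log(2)) * sigma) < 0.01

    def test_unbounded_profile_raises(self):
        prof = make_profile([1.0, 0.9, 0.8], background_subtracted=True)
        with pytest.raises(UnboundedWidthError):
            profile_fwhm(normalize_and_mirror(prof))

    def test_width_ratio_to_reference(self):
        r = (np.arange(40) + 0.5) * 0.1
        wide = make_profile(np.exp(-r**2 / (2 * 1.0**2)),
                            background_subtracted=True)
        narrow = make_profile(np.exp(-r**2 / (2 * 0.5**2)),
                              background_subtracted=True)
        ratio = compare_to_reference(normalize_and_mirror(wide),
                                     normalize_and_mirror(narrow))
        assert np.isclose(ratio, 2.0, rtol=0.02)


class TestPeakMatching:
    def test_scaling_to_prebleach_peak(self):
        pre = make_profile([2.0, 8.0, 2.0], background_subtracted=True)
        rec = make_profile([0.5, 2.0, 0.5], background_subtracted=True)
        scaled = normalize_to_prebleach_peak(rec, pre)
        assert np.allclose(scaled.values, [2.0, 8.0, 2.0])

    def test_grid_mismatch_and_zero_peak(self):
        pre = make_profile([1.0, 2.0], background_subtracted=True)
        with pytest.raises(GridMismatchError):
            normalize_to_prebleach_peak(make_profile([1.0, 2.0], spacing=0.2,
                                                     background_subtracted=True), pre)
        with pytest.raises(NormalizationError):
            normalize_to_prebleach_peak(make_profile([0.0, 0.0],
                                                     background_subtracted=True), pre)
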