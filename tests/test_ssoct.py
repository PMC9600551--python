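"""SS-OCT pipeline: stage contracts, phantom oracles, densitometry invariants."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculens import phantom, ssoct
from oculens.imgio import BScan
from oculens.phantom import PhantomParams
from oculens.ssoct import (
    DEFAULT_CONFIG,
    SegmentationError,
    SsoctConfig,
    fit_quartic_with_correction,
)


def make_scan(pixels, **kw):
    return BScan(pixels=np.asarray(pixels, dtype=float), **kw)


class TestPreprocess:
    FULL_RANGE = SsoctConfig(clip_percentiles=(0.0, 100.0))

    def test_full_span_image_unchanged_without_clipping(self):
        px = np.linspace(0, 255, 100).reshape(10, 10)
        out = ssoct.preprocess(make_scan(px), self.FULL_RANGE)
        assert np.allclose(out.pixels, px)

    def test_constant_image_warns_and_passes_through(self):
        scan = make_scan(np.full((8, 8), 42.0))
        with pytest.warns(UserWarning, match="constant"):
            out = ssoct.preprocess(scan)
        assert np.array_equal(out.pixels, scan.pixels)

    def test_stretch_hits_full_range(self):
        px = np.linspace(40, 90, 64).reshape(8, 8)
        out = ssoct.preprocess(make_scan(px), self.FULL_RANGE)
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 255.0

    def test_idempotent_under_full_range_stretch(self):
        px = np.linspace(40, 90, 64).reshape(8, 8)
        once = ssoct.preprocess(make_scan(px), self.FULL_RANGE)
        twice = ssoct.preprocess(once, self.FULL_RANGE)
        assert np.allclose(once.pixels, twice.pixels)


class TestBinarize:
    def test_bimodal_image_isolates_bright_level(self):
        px = np.full((20, 20), 20.0)
        px[5:15, 5:15] = 200.0
        mask = ssoct.binarize(px)
        assert np.array_equal(mask, px == 200.0)

    def test_inverted_image_inverts_mask(self):
        px = np.full((20, 20), 20.0)
        px[5:15, 5:15] = 200.0
        mask = ssoct.binarize(px)
        inv_mask = ssoct.binarize(255.0 - px)
        assert np.array_equal(inv_mask, ~mask)

    def test_phantom_foreground_covers_lens_not_chamber(self, noise_free_phantom):
        scan, truth = noise_free_phantom
        # Absolute threshold between chamber (20) and cortex (100).
        mask = ssoct.binarize(scan.pixels, SsoctConfig(threshold_override=60.0))
        assert mask[truth.lens_mask].all()
        assert not mask[truth.chamber_mask].any()


class TestCleanMask:
    def test_specks_removed_blob_intact(self):
        mask = np.zeros((200, 200), bool)
        mask[50:150, 50:150] = True  # 10^4 px blob
        mask[5, 5:8] = True  # 3-px speck
        mask[190, 10:13] = True
        out = ssoct.clean_mask(mask, SsoctConfig(min_object_px=50, closing_radius_px=0))
        assert out[50:150, 50:150].all()
        assert out.sum() == 100 * 100

    def test_idempotent_on_clean_rectangle(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        out = ssoct.clean_mask(mask)
        assert np.array_equal(out, mask)

    def test_small_interior_hole_closed(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        mask[30, 30:32] = False  # 2-px hole
        out = ssoct.clean_mask(mask, SsoctConfig(closing_radius_px=3))
        assert out[30, 30:32].all()

    def test_empty_after_cleaning_raises(self):
        mask = np.zeros((50, 50), bool)
        mask[10, 10:13] = True  # below min size
        with pytest.raises(SegmentationError, match="no lens candidate"):
            ssoct.clean_mask(mask)


class TestExtractSurfaces:
    def test_filled_band_yields_flat_surfaces(self):
        mask = np.zeros((400, 50), bool)
        mask[100:301, :] = True
        anterior, posterior = ssoct.extract_surfaces(mask)
        assert np.all(anterior[:, 1] == 100)
        assert np.all(posterior[:, 1] == 300)

    def test_narrow_component_underdetermined(self):
        mask = np.zeros((50, 50), bool)
        mask[10:40, 20:24] = True  # 4 columns
        with pytest.raises(SegmentationError, match="5"):
            ssoct.extract_surfaces(mask)

    def test_phantom_surfaces_on_true_quartic(self, noise_free_phantom):
        scan, truth = noise_free_phantom
        mask = ssoct.clean_mask(ssoct.binarize(ssoct.preprocess(scan)))
        anterior, _ = ssoct.extract_surfaces(mask)
        true_y = np.polynomial.polynomial.polyval(anterior[:, 0], truth.anterior_curve)
        assert np.max(np.abs(anterior[:, 1] - true_y)) <= 1.5


class TestQuarticFit:
    X = np.linspace(0, 100, 60)

    def test_exact_polynomial_recovered(self):
        y = 2 + 0.001 * self.X**2
        curve, n_corr = fit_quartic_with_correction(np.column_stack([self.X, y]))
        assert n_corr == 0
        assert np.allclose(curve.coef, [2, 0, 0.001, 0, 0], atol=1e-9)

    def test_displaced_point_corrected_to_clean_fit(self):
        y = 2 + 0.001 * self.X**2
        clean, _ = fit_quartic_with_correction(np.column_stack([self.X, y]))
        y_bad = y.copy()
        y_bad[30] += 50.0
        curve, n_corr = fit_quartic_with_correction(
            np.column_stack([self.X, y_bad]), deviation_threshold_px=10.0
        )
        assert n_corr == 1
        assert np.allclose(curve.coef, clean.coef, atol=1e-6)

    def test_too_few_points_rejected(self):
        pts = np.column_stack([np.arange(4), np.arange(4)])
        with pytest.raises(ValueError, match="5"):
            fit_quartic_with_correction(pts)


class TestSegmentLens:
    def test_noise_free_iou(self, noise_free_phantom, noise_free_segmentation):
        _, truth = noise_free_phantom
        seg = noise_free_segmentation
        inter = (seg.mask & truth.lens_mask).sum()
        union = (seg.mask | truth.lens_mask).sum()
        assert inter / union >= 0.95

    def test_speckle_surface_rmse(self, speckle_phantom):
        scan, truth = speckle_phantom
        seg = ssoct.segment_lens(scan)
        xs = np.arange(seg.lateral_extent[0], seg.lateral_extent[1] + 1)
        for fitted, true_coef in [
            (seg.anterior, truth.anterior_curve),
            (seg.posterior, truth.posterior_curve),
        ]:
            true_y = np.polynomial.polynomial.polyval(xs, true_coef)
            rmse = np.sqrt(np.mean((fitted(xs) - true_y) ** 2))
            assert rmse <= 3.0

    def test_blank_image_reports_no_lens(self):
        scan = make_scan(np.random.default_rng(0).uniform(10, 12, (100, 100)))
        with pytest.raises(SegmentationError, match="no lens candidate"):
            ssoct.segment_lens(scan)


class TestSegmentChamber:
    def test_noise_free_chamber_mean_exact(self, noise_free_phantom, noise_free_segmentation):
        scan, _ = noise_free_phantom
        seg = noise_free_segmentation
        roi = ssoct.segment_chamber(scan, seg.anterior, lateral_extent=seg.lateral_extent)
        assert scan.pixels[roi.mask].mean() == 20.0

    def test_roi_disjoint_from_lens(self, noise_free_phantom, noise_free_segmentation):
        scan, _ = noise_free_phantom
        seg = noise_free_segmentation
        roi = ssoct.segment_chamber(scan, seg.anterior, lateral_extent=seg.lateral_extent)
        assert not (roi.mask & seg.mask).any()

    def test_speckle_chamber_mean_within_one_piu(self, speckle_phantom):
        scan, _ = speckle_phantom
        seg = ssoct.segment_lens(scan)
        roi = ssoct.segment_chamber(scan, seg.anterior, lateral_extent=seg.lateral_extent)
        assert scan.pixels[roi.mask].mean() == pytest.approx(20.0, abs=1.0)

    def test_no_cornea_edge_raises(self, noise_free_segmentation):
        seg = noise_free_segmentation
        scan = make_scan(np.full((768, 1024), 30.0))
        with pytest.raises((SegmentationError, Warning)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ssoct.segment_chamber(scan, seg.anterior, lateral_extent=seg.lateral_extent)


class TestDensitometry:
    def test_uniform_lens_region(self, noise_free_segmentation):
        seg = noise_free_segmentation
        scan = make_scan(np.full(seg.mask.shape, 100.0))
        assert ssoct.lens_density(scan, seg) == 100.0

    def test_phantom_lens_density_area_weighted(self, noise_free_phantom, noise_free_segmentation):
        scan, _ = noise_free_phantom
        # 14% nucleus at 140 inside cortex at 100.
        expected = 0.14 * 140 + 0.86 * 100
        assert ssoct.lens_density(scan, noise_free_segmentation) == pytest.approx(
            expected, abs=0.5
        )

    def test_corrected_density_identities(self):
        assert ssoct.corrected_density(44.78, 0.0) == 44.78
        assert ssoct.corrected_density(120.0, 20.0) == 100.0

    def test_negative_corrected_density_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            assert ssoct.corrected_density(10.0, 20.0) == -10.0

    def test_shift_invariance(self, noise_free_phantom, noise_free_segmentation):
        scan, _ = noise_free_phantom
        seg = noise_free_segmentation
        roi = ssoct.segment_chamber(scan, seg.anterior, lateral_extent=seg.lateral_extent)
        shifted = make_scan(scan.pixels + 7.0)
        base = ssoct.corrected_density(
            ssoct.lens_density(scan, seg), ssoct.chamber_density(scan, roi)
        )
        moved = ssoct.corrected_density(
            ssoct.lens_density(shifted, seg), ssoct.chamber_density(shifted, roi)
        )
        assert moved == pytest.approx(base, abs=1e-9)

    def test_monotonicity_in_lens_intensity(self, noise_free_phantom, noise_free_segmentation):
        scan, truth = noise_free_phantom
        seg = noise_free_segmentation
        roi = ssoct.segment_chamber(scan, seg.anterior, lateral_extent=seg.lateral_extent)
        brighter = scan.pixels.copy()
        brighter[truth.lens_mask] += 10.0
        bright_scan = make_scan(brighter)
        assert ssoct.lens_density(bright_scan, seg) > ssoct.lens_density(scan, seg)
        assert ssoct.chamber_density(bright_scan, roi) == ssoct.chamber_density(scan, roi)

    @given(st.floats(0, 235), st.floats(0, 20))
    @settings(max_examples=30, deadline=None)
    def test_corrected_density_is_difference(self, lens_mean, chamber_mean):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = ssoct.corrected_density(lens_mean, chamber_mean)
        assert value == pytest.approx(lens_mean - chamber_mean)


class TestNucleusROI:
    def test_default_fraction_within_one_percent(self, noise_free_segmentation):
        seg = noise_free_segmentation
        roi = ssoct.nucleus_roi(seg)
        area = np.pi * roi.semi_axis_lateral * roi.semi_axis_axial
        assert area / seg.mask.sum() == pytest.approx(0.14, rel=0.01)

    def test_tiny_fraction_strictly_inside(self, noise_free_segmentation):
        seg = noise_free_segmentation
        roi = ssoct.nucleus_roi(seg, area_fraction=0.01)
        pm = roi.pixel_mask(seg.mask.shape)
        assert pm.any()
        assert not (pm & ~seg.mask).any()

    def test_center_at_mask_centroid(self, noise_free_segmentation):
        seg = noise_free_segmentation
        roi = ssoct.nucleus_roi(seg)
        ys, xs = np.nonzero(seg.mask)
        assert roi.center[0] == pytest.approx(xs.mean(), abs=1.0)
        assert roi.center[1] == pytest.approx(ys.mean(), abs=1.0)

    def test_fraction_out_of_range_rejected(self, noise_free_segmentation):
        with pytest.raises(ValueError):
            ssoct.nucleus_roi(noise_free_segmentation, area_fraction=0.7)


class TestNucleusDensity:
    def test_phantom_nucleus_minus_chamber(self, noise_free_phantom, noise_free_segmentation):
        scan, _ = noise_free_phantom
        roi = ssoct.nucleus_roi(noise_free_segmentation)
        assert ssoct.nucleus_density(scan, roi, 20.0) == pytest.approx(120.0, abs=0.5)

    def test_uniform_image_zero(self, noise_free_segmentation):
        roi = ssoct.nucleus_roi(noise_free_segmentation)
        scan = make_scan(np.full(noise_free_segmentation.mask.shape, 55.0))
        assert ssoct.nucleus_density(scan, roi, 55.0) == 0.0


class TestSeriesDensity:
    def test_mean_of_values(self):
        assert ssoct.series_density([10, 20, 30]) == 20.0

    def test_single_value(self):
        assert ssoct.series_density([44.78]) == 44.78

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ssoct.series_density([])

    def test_series_mean_reduces_noise(self):
        """Std of the 15-scan mean is close to per-scan std / sqrt(15)."""
        per_scan_stds, series_stds = [], []
        lens_means = []
        for seed in range(8):
            params = PhantomParams(speckle_sd=0.1, seed=seed)
            series = phantom.generate_radial_series(params)
            means = [
                scan.pixels[truth.lens_mask].mean() for scan, truth in series
            ]
            lens_means.append(means)
        lens_means = np.asarray(lens_means)
        per_scan_sd = lens_means.std()
        series_sd = lens_means.mean(axis=1).std()
        assert series_sd == pytest.approx(per_scan_sd / np.sqrt(15), rel=0.8)


class TestAScanAnalysis:
    def test_detected_capsules_near_truth(self):
        params = PhantomParams(speckle_sd=0.0)
        profile, interfaces = phantom.generate_ascan(params, noise_sd=0.0)
        i_ant, i_post = ssoct.detect_lens_range(profile)
        step = profile.depth_mm[1] - profile.depth_mm[0]
        assert abs(profile.depth_mm[i_ant] - interfaces[2]) <= 2 * step
        assert abs(profile.depth_mm[i_post] - interfaces[3]) <= 2 * step
        assert i_ant < i_post

    def test_three_peak_profile_rejected(self):
        depth = np.arange(0.01, 10, 0.01)
        prof = 0.05 + sum(
            0.5 * np.exp(-0.5 * ((depth - d) / 0.05) ** 2) for d in (1.0, 4.0, 8.0)
        )
        from oculens.imgio import AScanProfile

        with pytest.raises(SegmentationError, match="capsule"):
            ssoct.detect_lens_range(AScanProfile(depth, np.clip(prof, 0, 1)))

    def test_constructed_plateau_returned_exactly(self):
        params = PhantomParams(speckle_sd=0.0, ascan_lens_plateau_au=0.10)
        profile, _ = phantom.generate_ascan(params, noise_sd=0.0)
        assert ssoct.linear_density(profile) == pytest.approx(0.10, abs=1e-3)

    def test_noisy_plateau_within_device_tolerance(self):
        params = PhantomParams(speckle_sd=0.0, seed=21)
        profile, _ = phantom.generate_ascan(params, noise_sd=0.005)
        assert ssoct.linear_density(profile) == pytest.approx(0.102, abs=0.002)

    def test_result_in_unit_range(self):
        profile, _ = phantom.generate_ascan(PhantomParams(speckle_sd=0.0), noise_sd=0.0)
        assert 0 <= ssoct.linear_density(profile) <= 1


class TestAnalyzeSeries:
    def test_full_series_on_noise_free_phantom(self):
        params = PhantomParams(speckle_sd=0.0, n_scans=2)
        series = [s for s, _ in phantom.generate_radial_series(params)]
        profile, _ = phantom.generate_ascan(params, noise_sd=0.0)
        result = ssoct.analyze_series(series, profile=profile)
        assert result.n_scans == 2
        assert result.lens_corrected == pytest.approx(105.6 - 20.0, abs=1.0)
        assert result.nucleus_corrected == pytest.approx(120.0, abs=1.0)
        assert result.linear_au == pytest.approx(0.102, abs=0.002)
        assert all(0 <= v <= 255 for v in result.per_scan_lens_mean)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ssoct.analyze_series([])
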