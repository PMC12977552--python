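"""Soma-counting pipeline: per-stage oracle checks and end-to-end counts."""
import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

from retquant import synthetic
from retquant.counting import (
    Candidates,
    CountingConfig,
    RegionMask,
    binarize,
    count_cells,
    count_in_regions,
    declump,
    filter_detections,
    locate_centers,
    suppress_background,
)
from retquant.geometry import SquareROI
from retquant.image import Image2D

from oracles import (
    brute_edt_maxima,
    brute_greedy_suppression,
    brute_opening,
)


def _blob(shape, cx, cy, sigma, peak):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return peak * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestSuppressBackground:
    def test_constant_image_cancels_exactly(self):
        cfg = replace(CountingConfig(), absolute_background=80.0)
        img = Image2D(np.full((64, 64), 80.0))
        out = suppress_background(img, cfg)
        assert (out.pixels == 0).all()

    def test_large_blob_survives_with_small_attenuation(self):
        """Oracle: direct brute-force morphology on a 50x50 toy grid."""
        cfg = CountingConfig(
            opening_radius_px=2, background_kernel_radius_px=20, min_area_px=1, max_area_px=9e9
        )
        px = _blob((50, 50), 25, 25, sigma=8.0, peak=1000.0)
        out = suppress_background(Image2D(px.copy()), cfg)
        opened = brute_opening(px.copy(), 2)
        tophat = np.clip(opened - brute_opening(opened.copy(), 20), 0, None)
        np.testing.assert_allclose(out.pixels, tophat, atol=1e-9)
        assert out.pixels.max() > 0.95 * opened.max()

    def test_single_pixel_impulses_removed(self):
        cfg = CountingConfig()
        px = np.zeros((80, 80))
        px[10, 10] = px[40, 60] = px[70, 20] = 500.0
        out = suppress_background(Image2D(px), cfg)
        assert (out.pixels == 0).all()

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            suppress_background(Image2D(np.zeros((20, 20))), CountingConfig())

    def test_output_non_negative(self):
        rng = np.random.default_rng(0)
        img = Image2D(rng.uniform(0, 100, size=(64, 64)))
        cfg = replace(CountingConfig(), absolute_background=50.0)
        assert (suppress_background(img, cfg).pixels >= 0).all()


class TestDeclump:
    def test_zero_iterations_identity(self):
        rng = np.random.default_rng(1)
        px = rng.uniform(0, 10, size=(32, 32))
        cfg = replace(CountingConfig(), declump_iterations=0)
        np.testing.assert_array_equal(declump(Image2D(px), cfg).pixels, px)

    def test_touching_pair_splits_into_two_components(self):
        """Two blobs one soma diameter apart: one component at threshold
        before declumping, two after."""
        sigma = 6.0
        px = _blob((64, 64), 22, 32, sigma, 1000.0) + _blob((64, 64), 42, 32, sigma, 1000.0)
        thr = 450.0
        n_before = ndimage.label(px > thr)[1]
        out = declump(Image2D(px), CountingConfig())
        n_after = ndimage.label(out.pixels > thr)[1]
        assert n_before == 1
        assert n_after == 2

    def test_isolated_blob_stays_single(self):
        px = _blob((64, 64), 32, 32, 6.0, 1000.0)
        cfg = CountingConfig()
        out = declump(Image2D(px), cfg)
        thr = 0.3 * out.pixels.max()
        assert ndimage.label(out.pixels > thr)[1] == 1


class TestBinarize:
    def test_constant_image_all_background(self):
        mask = binarize(Image2D(np.full((64, 64), 123.0)), CountingConfig())
        assert not mask.any()

    def test_blob_on_steep_gradient_still_segmented(self):
        """Gradient amplitude 2x the blob height: a global threshold fails
        but the local adaptive threshold does not."""
        h = w = 128
        ramp = np.linspace(0, 2000, w)[None, :].repeat(h, axis=0)
        blob = _blob((h, w), 30, 64, 5.0, 1000.0)
        img = Image2D(ramp + blob)
        cfg = replace(CountingConfig(), adaptive_offset=300.0)
        mask = binarize(img, cfg)
        # any global threshold catching the blob also floods the bright edge
        blob_peak_total = ramp[64, 30] + 1000.0
        assert (img.pixels > blob_peak_total * 0.8).sum() > 500
        lab, n = ndimage.label(mask)
        sizes = np.bincount(lab.ravel())[1:]
        main = np.argmax(sizes) + 1
        ys, xs = np.nonzero(lab == main)
        assert abs(xs.mean() - 30) < 3 and abs(ys.mean() - 64) < 3

    def test_checkerboard_bright_squares_foreground(self):
        tile = np.kron(np.indices((8, 8)).sum(axis=0) % 2, np.ones((8, 8)))
        img = Image2D(tile * 1000.0)
        cfg = replace(CountingConfig(), adaptive_offset=100.0)
        mask = binarize(img, cfg)
        assert mask[tile == 1].mean() > 0.5
        assert not mask[tile == 0].any()

    def test_block_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="block"):
            binarize(Image2D(np.zeros((32, 32))), CountingConfig())


class TestLocateCenters:
    def test_filled_disc_gives_single_central_candidate(self):
        mask = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[0:40, 0:40]
        mask[(xx - 20) ** 2 + (yy - 19) ** 2 <= 100] = True
        cand = locate_centers(mask, CountingConfig())
        assert len(cand) == 1
        assert abs(cand.x_px[0] - 20) <= 1 and abs(cand.y_px[0] - 19) <= 1

    def test_empty_mask_gives_no_candidates(self):
        cand = locate_centers(np.zeros((30, 30), dtype=bool), CountingConfig())
        assert len(cand) == 0

    def test_dumbbell_matches_exhaustive_edt_maxima(self):
        """Oracle: exhaustive distance-map maxima on a 40x40 toy mask."""
        mask = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[0:40, 0:40]
        mask[(xx - 13) ** 2 + (yy - 20) ** 2 <= 64] = True
        mask[(xx - 27) ** 2 + (yy - 20) ** 2 <= 64] = True
        cfg = replace(CountingConfig(), min_peak_distance_px=6.0)
        cand = locate_centers(mask, cfg)
        oracle = brute_edt_maxima(mask, 6.0)
        assert len(cand) == 2
        got = sorted(zip(cand.x_px, cand.y_px))
        exp = sorted(oracle)
        for (gx, gy), (ex, ey) in zip(got, exp):
            assert abs(gx - ex) <= 1.5 and abs(gy - ey) <= 1.5

    def test_candidate_carries_component_area(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:20, 10:20] = True
        cand = locate_centers(mask, CountingConfig())
        assert cand.area_px[0] == 100


class TestFilterDetections:
    def _cand(self, rows):
        rows = np.asarray(rows, dtype=float)
        return Candidates(rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3])

    def test_separated_midsized_all_retained(self):
        cand = self._cand([[10, 10, 5, 300], [40, 10, 5, 300], [10, 40, 5, 300]])
        det = filter_detections(cand, CountingConfig())
        assert det.count == 3

    def test_close_pair_suppressed_to_one(self):
        cfg = CountingConfig()
        d = 0.5 * cfg.min_center_distance_px
        cand = self._cand([[10, 10, 6, 300], [10 + d, 10, 5, 300]])
        det = filter_detections(cand, cfg)
        assert det.count == 1
        assert det.centers_px[0, 0] == 10  # higher distance-map value wins

    def test_size_bounds_applied(self):
        cfg = CountingConfig()
        cand = self._cand(
            [
                [10, 10, 5, cfg.min_area_px - 1],   # undersized
                [40, 10, 5, cfg.max_area_px + 1],   # oversized
                [70, 10, 5, 300],                   # in-spec
            ]
        )
        assert filter_detections(cand, cfg).count == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_greedy_rule(self, seed):
        """Oracle: literal simulation of the suppression order on <=10
        candidates, including ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        x = rng.uniform(0, 60, n).round(0)
        y = rng.uniform(0, 60, n).round(0)
        v = rng.choice([3.0, 5.0, 8.0], n)  # ties likely
        a = rng.choice([200.0, 300.0], n)
        cfg = replace(CountingConfig(), min_center_distance_px=20.0)
        det = filter_detections(Candidates(x, y, v, a), cfg)
        rows = list(zip(x, y, v, a))
        accepted = brute_greedy_suppression(rows, 20.0)
        exp = sorted((x[i], y[i]) for i in accepted)
        got = sorted(map(tuple, det.centers_px))
        assert got == pytest.approx(exp)


class TestCountCells:
    def test_blank_image_counts_zero(self):
        img = Image2D(np.full((256, 256), 100.0), 0.5)
        assert count_cells(img).count == 0

    def test_isolated_noise_free_cells_counted_exactly(self):
        spec = synthetic.FlatMountSpec(
            width_px=640,
            height_px=640,
            n_cells=100,
            clump_fraction=0.0,
            noise_sd=0.0,
            gradient_amplitude=0.0,
            min_separation_um=18.0,
            seed=21,
        )
        img, truth = synthetic.generate_flatmount(spec)
        assert count_cells(img).count == truth.true_count == 100

    def test_adding_one_isolated_cell_increments_count(self, clean_scene):
        spec, img, truth = clean_scene
        base = count_cells(img).count
        extra = img.copy()
        # render one extra in-spec soma in a clear corner
        yy, xx = np.mgrid[0 : img.height_px, 0 : img.width_px]
        sigma_px = (spec.soma_radius_um_mean / 2) / spec.microns_per_px
        d2 = (xx - 30.0) ** 2 + (yy - 30.0) ** 2
        blob = spec.peak_intensity_mean * np.exp(-d2 / (2 * sigma_px**2))
        blob[d2 > (3 * sigma_px) ** 2] = 0.0
        extra.pixels += blob
        assert count_cells(extra).count == base + 1

    def test_translation_invariance(self, clean_scene):
        _, img, _ = clean_scene
        rolled = Image2D(np.roll(img.pixels, (7, 13), axis=(0, 1)), img.microns_per_px)
        assert count_cells(rolled).count == count_cells(img).count

    def test_masked_count_not_larger_than_unmasked(self, default_tile):
        _, img, _ = default_tile
        full = count_cells(img).count
        mask = RegionMask.from_square_roi(img, SquareROI(32.0, 32.0, 128.0))
        assert count_cells(img, mask=mask).count <= full

    def test_mismatched_mask_rejected(self, default_tile):
        _, img, _ = default_tile
        with pytest.raises(ValueError, match="mask shape"):
            count_cells(img, mask=RegionMask(np.ones((10, 10), dtype=bool)))


class TestCountInRegions:
    def test_uniform_density_recovered_in_roi(self):
        spec = synthetic.FlatMountSpec(
            width_px=1024,
            height_px=1024,
            density_per_mm2=1000.0,
            clump_fraction=0.0,
            noise_sd=0.0,
            gradient_amplitude=0.0,
            seed=33,
        )
        img, truth = synthetic.generate_flatmount(spec)
        table = count_in_regions(img, rois=[SquareROI(66.0, 66.0, 380.0)])
        expected = 1000.0 * 0.1444  # density x ROI area in mm^2
        assert abs(table["count"][0] - expected) < 3.0 * np.sqrt(expected)
        assert table.density_per_mm2[0] == pytest.approx(table["count"][0] / 0.1444)

    def test_empty_roi_zero_density(self):
        img = Image2D(np.full((512, 512), 50.0), 0.5)
        table = count_in_regions(img, rois=[SquareROI(10.0, 10.0, 100.0)])
        assert table["count"][0] == 0 and table.density_per_mm2[0] == 0.0

    def test_roi_outside_image_rejected(self):
        img = Image2D(np.zeros((128, 128)), 0.5)
        with pytest.raises(ValueError, match="ROI"):
            count_in_regions(img, rois=[SquareROI(0.0, 0.0, 100.0)])

    def test_full_roi_equals_whole_mask_count(self, default_tile):
        spec, img, _ = default_tile
        side = img.width_px * img.microns_per_px
        table = count_in_regions(img, rois=[SquareROI(0.0, 0.0, side)])
        mask = RegionMask(np.ones(img.shape, dtype=bool))
        assert table["count"][0] == count_cells(img, mask=mask).count

    def test_disjoint_tiling_not_more_than_whole(self, default_tile):
        _, img, _ = default_tile
        side = img.width_px * img.microns_per_px
        half = side / 2
        rois = [
            SquareROI(0.0, 0.0, half),
            SquareROI(half, 0.0, half),
            SquareROI(0.0, half, half),
            SquareROI(half, half, half),
        ]
        table = count_in_regions(img, rois=rois)
        assert table["count"].sum() <= count_cells(img).count


class TestDegradation:
    def test_error_grows_with_clumping_and_noise(self):
        """Counting error is non-decreasing along 3-point clump-fraction and
        noise sweeps (trend over 10 seeds, 256 px tiles)."""

        def mean_err(**kw):
            errs = []
            for seed in range(10):
                spec = synthetic.FlatMountSpec(
                    width_px=256, height_px=256, seed=seed + 50, **kw
                )
                img, truth = synthetic.generate_flatmount(spec)
                det = count_cells(img)
                errs.append(abs(det.count - truth.true_count) / truth.true_count)
            return float(np.mean(errs))

        clump = [mean_err(clump_fraction=c, noise_sd=0.0) for c in (0.0, 0.25, 0.5)]
        noise = [mean_err(noise_sd=s, clump_fraction=0.0) for s in (0.0, 1000.0, 1500.0)]
        slack = 0.002  # one cell in a 256 px tile, Monte-Carlo jitter
        assert clump[0] <= clump[1] + slack <= clump[2] + 2 * slack
        assert noise[0] <= noise[1] + slack <= noise[2] + 2 * slack
        assert clump[2] >= clump[0] and noise[2] >= noise[0]
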