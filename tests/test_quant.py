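import numpy as np
import pandas as pd
import pytest

from telofish.quant import (extract_spots, quantify_cells, quantify_image,
                            rolling_ball, segment_spots, sharpen,
                            subtract_background)


def brute_force_ball_opening(img, radius):
    """Independent O(n^2 k^2) grayscale opening with a spherical-cap
    structuring function, ignoring out-of-bounds pixels."""
    h, w = img.shape
    r = int(np.floor(radius))
    offsets = [(a, b, np.sqrt(radius ** 2 - a * a - b * b))
               for a in range(-r, r + 1) for b in range(-r, r + 1)
               if a * a + b * b <= radius ** 2]
    eroded = np.empty_like(img, dtype=float)
    for i in range(h):
        for j in range(w):
            eroded[i, j] = min(img[i + a, j + b] - s for a, b, s in offsets
                               if 0 <= i + a < h and 0 <= j + b < w)
    opened = np.empty_like(img, dtype=float)
    for i in range(h):
        for j in range(w):
            opened[i, j] = max(eroded[i + a, j + b] + s for a, b, s in offsets
                               if 0 <= i + a < h and 0 <= j + b < w)
    return opened


class TestSubtractBackground:
    def test_constant_estimator_cancels_flat_field(self):
        img = np.full((4, 4), 50.0)
        assert np.all(subtract_background(img, "constant", 50.0) == 0)

    def test_zero_subtraction_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(
            subtract_background(img, "constant", 0.0), img)

    def test_percentile_estimator_clamps_at_zero(self):
        img = np.array([[10.0, 20.0, 110.0]])
        # 5th percentile of {10, 20, 110} by linear interpolation is 11
        expected = np.array([[0.0, 9.0, 99.0]])
        np.testing.assert_allclose(
            subtract_background(img, "percentile", 5.0), expected)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.empty((0, 0)), "constant", 1.0)


class TestSharpen:
    def test_zero_amount_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 10, (6, 6))
        np.testing.assert_array_equal(sharpen(img, 0.0), img)

    def test_flat_field_unchanged(self):
        img = np.full((5, 5), 7.0)
        np.testing.assert_allclose(sharpen(img, 2.5), img)

    def test_bright_pixel_hand_applied_kernel(self):
        """A lone bright pixel: center gains 4*amount*value, the four
        neighbors would go negative and are clamped at zero."""
        img = np.zeros((5, 5))
        img[2, 2] = 100.0
        out = sharpen(img, 1.0)
        assert out[2, 2] == 500.0
        assert out[1, 2] == out[3, 2] == out[2, 1] == out[2, 3] == 0.0


class TestRollingBall:
    def test_flat_field_maps_to_zero(self):
        img = np.full((16, 16), 42.0)
        np.testing.assert_allclose(rolling_ball(img, 3), 0.0)

    def test_output_never_exceeds_input(self):
        img = np.random.default_rng(1).uniform(0, 100, (20, 20))
        out = rolling_ball(img, 4)
        assert np.all(out <= img + 1e-9)
        assert np.all(out >= 0)

    def test_spike_on_dome_keeps_spike_removes_dome(self):
        """A broad smooth dome with one sharp spike: the ball rolls under the
        dome (removed) but not under the spike (kept)."""
        y, x = np.mgrid[0:16, 0:16]
        dome = 50.0 * np.exp(-((x - 8) ** 2 + (y - 8) ** 2) / (2 * 8.0 ** 2))
        img = dome.copy()
        img[4, 4] += 40.0
        out = rolling_ball(img, 5)
        assert out[4, 4] > 35.0                      # spike survives
        assert out[12, 12] < 5.0                     # dome removed
        np.testing.assert_allclose(
            out, img - brute_force_ball_opening(img, 5), atol=1e-9)

    def test_oversized_radius_falls_back_to_global_minimum(self):
        img = np.random.default_rng(2).uniform(5, 10, (16, 16))
        with pytest.warns(RuntimeWarning):
            out = rolling_ball(img, 100)
        np.testing.assert_allclose(out, img - img.min())


class TestSegmentSpots:
    def test_blank_image_gives_empty_mask(self):
        assert not segment_spots(np.zeros((8, 8))).any()

    def test_fixed_threshold_counts_two_blobs(self):
        img = np.zeros((10, 10))
        img[1:3, 1:3] = 100.0
        img[6:8, 6:8] = 100.0
        mask = segment_spots(img, "fixed", 50.0, min_area=2, max_area=50)
        from skimage.measure import label
        assert label(mask, connectivity=2).max() == 2

    def test_min_area_filter_removes_single_pixels(self):
        img = np.zeros((8, 8))
        img[4, 4] = 100.0
        mask = segment_spots(img, "fixed", 50.0, min_area=2, max_area=50)
        assert not mask.any()

    def test_max_area_filter_removes_large_components(self):
        img = np.zeros((12, 12))
        img[2:10, 2:10] = 100.0  # area 64
        mask = segment_spots(img, "fixed", 50.0, min_area=2, max_area=10)
        assert not mask.any()

    def test_otsu_on_constant_image_is_empty(self):
        assert not segment_spots(np.full((8, 8), 3.0), "otsu").any()

    def test_connectivity_4_vs_8_on_diagonal_pair(self):
        img = np.zeros((6, 6))
        img[2, 2] = img[3, 3] = 100.0
        # 8-connectivity: one 2-px component survives min_area=2
        assert segment_spots(img, "fixed", 50.0, connectivity=8).sum() == 2
        # 4-connectivity: two 1-px components, both removed
        assert not segment_spots(img, "fixed", 50.0, connectivity=4).any()


class TestExtractSpots:
    def test_mean_times_area_arithmetic(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        raw = np.full((6, 6), 10.0)
        rois = np.ones((6, 6), dtype=int)
        spots = extract_spots(mask, raw, rois)
        assert len(spots) == 1
        assert spots.loc[0, "area"] == 4
        assert spots.loc[0, "mean_intensity"] == 10.0
        assert spots.loc[0, "spot_value"] == 40.0
        assert spots.loc[0, "cell_label"] == 1

    def test_centroid_assigns_cell_label(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[5:7, 5:7] = True
        rois = np.zeros((8, 8), dtype=int)
        rois[4:8, 4:8] = 3
        spots = extract_spots(mask, np.ones((8, 8)), rois)
        assert spots.loc[0, "cell_label"] == 3

    def test_straddling_spot_assigned_by_centroid_only(self):
        """A spot lying across two ROIs goes entirely to the ROI under its
        centroid; total spot value is conserved, not split."""
        rois = np.zeros((8, 8), dtype=int)
        rois[:, :4] = 2
        rois[:, 4:] = 3
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 1:6] = True  # centroid at column 3 -> ROI 2
        raw = np.full((8, 8), 7.0)
        spots = extract_spots(mask, raw, rois)
        assert len(spots) == 1
        assert spots.loc[0, "cell_label"] == 2
        assert spots.loc[0, "spot_value"] == pytest.approx(5 * 7.0)

    def test_background_centroid_gets_label_zero(self):
        rois = np.zeros((8, 8), dtype=int)
        mask = np.zeros((8, 8), dtype=bool)
        mask[0:2, 0:2] = True
        spots = extract_spots(mask, np.ones((8, 8)), rois)
        assert spots.loc[0, "cell_label"] == 0


class TestQuantifyCells:
    def test_tfi_arithmetic(self):
        spots = pd.DataFrame([dict(spot_id=1, cell_label=1, area=4,
                                   mean_intensity=5.0, spot_value=20.0,
                                   centroid_y=1.0, centroid_x=1.0)])
        dapi = np.zeros((6, 6))
        rois = np.zeros((6, 6), dtype=int)
        rois[0:2, 0:2] = 1
        dapi[0:2, 0:2] = 25.0  # D = 100
        cells = quantify_cells(spots, dapi, rois)
        assert cells.loc[0, "tfi"] == pytest.approx(0.2)

    def test_spotless_cell_retained_with_zero_tfi(self):
        dapi = np.ones((4, 4))
        rois = np.ones((4, 4), dtype=int)
        cells = quantify_cells(pd.DataFrame(columns=["cell_label", "spot_value"]),
                               dapi, rois)
        assert len(cells) == 1
        assert cells.loc[0, "n_spots"] == 0
        assert cells.loc[0, "tfi"] == 0.0

    def test_zero_dapi_cell_excluded_with_warning(self):
        dapi = np.zeros((4, 4))
        rois = np.ones((4, 4), dtype=int)
        with pytest.warns(RuntimeWarning, match="DAPI"):
            cells = quantify_cells(pd.DataFrame(columns=["cell_label",
                                                         "spot_value"]),
                                   dapi, rois)
        assert cells.empty

    def test_background_spots_excluded_from_totals(self):
        spots = pd.DataFrame([
            dict(cell_label=0, spot_value=999.0),
            dict(cell_label=1, spot_value=10.0),
        ])
        dapi = np.ones((4, 4))
        rois = np.ones((4, 4), dtype=int)
        cells = quantify_cells(spots, dapi, rois)
        assert cells.loc[0, "total_spot_value"] == 10.0


class TestEndToEnd:
    def test_noiseless_specimen_recovers_truth_exactly(self, clean_specimen):
        """On a blur-free, noise-free specimen the measured TFI equals
        T_true/D_true per cell to better than 1% relative error."""
        _, cy3, dapi, labels, truth = clean_specimen
        # sharpening off: its clamp-at-zero deliberately discards sub-zero
        # flank pixels, so exact flux capture is defined for the plain chain
        _, cells = quantify_image(cy3, dapi, labels, sharpen_amount=0.0)
        merged = cells.merge(truth, on="cell_label")
        expected = merged["T_true"] / merged["D_true"]
        ok = expected > 0
        rel = np.abs(merged.loc[ok, "tfi"] - expected[ok]) / expected[ok]
        assert rel.max() < 0.01

    def test_tfi_scales_linearly_with_cy3_gain(self, noisy_specimen):
        """Scaling the Cy3 channel by c > 0 scales every TFI by c when the
        segmentation footprint is held fixed (measurement is linear); the
        full adaptive chain re-derives a nearly identical mask, so the
        end-to-end TFI is scale-stable to well under a percent."""
        from telofish.quant import (rolling_ball, segment_spots, sharpen,
                                    subtract_background)
        _, cy3, dapi, labels, _ = noisy_specimen
        norm = subtract_background(cy3)
        mask = segment_spots(rolling_ball(sharpen(norm, 0.5), 5))
        dapi_norm = subtract_background(dapi)
        base = quantify_cells(extract_spots(mask, norm, labels), dapi_norm, labels)
        for c in (2.0, 0.5):
            scaled = quantify_cells(
                extract_spots(mask, subtract_background(c * cy3), labels),
                dapi_norm, labels)
            np.testing.assert_allclose(scaled["tfi"], c * base["tfi"],
                                       rtol=1e-12)
        # the adaptive chain (threshold re-estimated on the scaled image)
        _, cells1 = quantify_image(cy3, dapi, labels)
        _, cells2 = quantify_image(2.0 * cy3, dapi, labels)
        np.testing.assert_allclose(cells2["tfi"], 2.0 * cells1["tfi"],
                                   rtol=5e-3)

    def test_spot_count_conservation(self, noisy_specimen):
        """Cell-assigned plus background-assigned spots equal the number of
        connected components in the mask."""
        from skimage.measure import label as cc_label
        from telofish.quant import (rolling_ball, segment_spots, sharpen,
                                    subtract_background)
        _, cy3, dapi, labels, _ = noisy_specimen
        norm = subtract_background(cy3)
        enhanced = rolling_ball(sharpen(norm, 0.5), 5)
        mask = segment_spots(enhanced)
        spots = extract_spots(mask, norm, labels)
        cells = quantify_cells(spots, subtract_background(dapi), labels)
        n_components = cc_label(mask, connectivity=2).max()
        n_bg = (spots["cell_label"] == 0).sum()
        assert cells["n_spots"].sum() + n_bg == n_components == len(spots)

    def test_default_noise_compartment_recovery_within_ten_percent(
            self, noisy_specimen):
        """With default noise the per-compartment mean measured TFI tracks
        the truth-table mean T_true/D_true within 10%."""
        _, cy3, dapi, labels, truth = noisy_specimen
        _, cells = quantify_image(cy3, dapi, labels)
        merged = cells.merge(truth, on="cell_label")
        for _, grp in merged.groupby("compartment"):
            true_mean = (grp["T_true"] / grp["D_true"]).mean()
            assert grp["tfi"].mean() == pytest.approx(true_mean, rel=0.10)
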