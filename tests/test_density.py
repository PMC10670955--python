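"""Band/nucleus segmentation, area filtering, band length, sensitivity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uroquant import density, phantom
from uroquant.density import FilterParams, Micrograph, NucleusRecord


def _record(area, in_band=True, label=1):
    return NucleusRecord(label=label, area_um2=area, centroid=(0.0, 0.0),
                         in_band=in_band)


def _records(areas, in_band=True):
    return [_record(a, in_band, i + 1) for i, a in enumerate(areas)]


class TestSegmentBand:
    def test_iou_against_ground_truth(self, clean_straight):
        micro, truth = clean_straight
        band = density.segment_band(micro)
        inter = (band.mask & truth.band_mask).sum()
        union = (band.mask | truth.band_mask).sum()
        assert inter / union >= 0.95

    def test_idempotent_on_binary_input(self):
        mask = np.zeros((40, 80), dtype=np.uint8)
        mask[10:30, 5:75] = 1
        micro = Micrograph(np.stack([mask, np.zeros_like(mask)]), pixel_size_um=1.0)
        band = density.segment_band(micro, smoothing_sigma_um=0.0,
                                    closing_radius_um=0.0)
        np.testing.assert_array_equal(band.mask, mask.astype(bool))

    def test_constant_channel_raises(self):
        zeros = np.zeros((32, 32), dtype=np.uint8)
        micro = Micrograph(np.stack([zeros, zeros]), pixel_size_um=1.0)
        with pytest.raises(ValueError, match="no foreground"):
            density.segment_band(micro)


class TestTrainableSegmentation:
    def test_matches_threshold_route_on_clean_phantom(self, phantom_factory):
        micro, truth = phantom_factory(
            "straight", seed=6, image_height_px=96, image_width_px=192
        )
        labels = np.zeros(micro.band_channel.shape, dtype=int)
        labels[truth.band_mask] = 2
        labels[~truth.band_mask] = 1
        band = density.segment_band_trainable(micro, labels)
        inter = (band.mask & truth.band_mask).sum()
        union = (band.mask | truth.band_mask).sum()
        assert inter / union >= 0.95

    def test_single_class_labels_rejected(self, phantom_factory):
        micro, _ = phantom_factory(
            "straight", seed=6, image_height_px=96, image_width_px=192
        )
        with pytest.raises(ValueError, match="both classes"):
            density.segment_band_trainable(
                micro, np.ones(micro.band_channel.shape, dtype=int)
            )


class TestSegmentNuclei:
    def test_count_matches_ground_truth(self, clean_straight):
        micro, truth = clean_straight
        band = density.segment_band(micro)
        records = density.segment_nuclei(micro, band)
        assert sum(r.in_band for r in records) == truth.in_band_nucleus_count

    def test_empty_channel_gives_empty_list(self):
        band_ch = np.zeros((32, 32), dtype=np.uint8)
        band_ch[10:20, :] = 200
        micro = Micrograph(np.stack([band_ch, np.zeros_like(band_ch)]),
                           pixel_size_um=1.0)
        band = density.segment_band(micro, 0.0, 0.0)
        assert density.segment_nuclei(micro, band) == []

    def test_watershed_splits_overlapping_discs(self):
        # two discs, centres farther apart than one radius: expect 2 records
        h, w, r0 = 40, 60, 8
        yy, xx = np.mgrid[0:h, 0:w]
        disc1 = (yy - 20) ** 2 + (xx - 24) ** 2 <= r0 ** 2
        disc2 = (yy - 20) ** 2 + (xx - 36) ** 2 <= r0 ** 2
        nuclei = np.where(disc1 | disc2, 220, 10).astype(np.uint8)
        band_ch = np.full((h, w), 200, dtype=np.uint8)
        band_ch[0, 0] = 0  # keep the channel non-constant
        micro = Micrograph(np.stack([band_ch, nuclei]), pixel_size_um=1.0)
        band = density.segment_band(micro, 0.0, 0.0)
        records = density.segment_nuclei(micro, band, min_seed_distance_um=6.0)
        assert len(records) == 2

    def test_shape_mismatch_raises(self, clean_straight):
        micro, _ = clean_straight
        other = density.BandMask(np.ones((8, 8), dtype=bool), 0.5)
        with pytest.raises(ValueError, match="shape"):
            density.segment_nuclei(micro, other)


class TestFilterNuclei:
    @pytest.mark.parametrize(
        "areas, a_min, factor, expect_kept, expect_med",
        [
            ([10, 12, 14], 2.5, 4.0, 3, 12.0),
            ([0.5, 10, 12, 14], 2.5, 4.0, 3, 12.0),   # debris out before median
            ([10, 12, 14, 100], 2.5, 4.0, 3, 13.0),   # oversized object excluded
        ],
    )
    def test_stated_examples(self, areas, a_min, factor, expect_kept, expect_med):
        kept, a_med = density.filter_nuclei(
            _records(areas), FilterParams(a_min_um2=a_min, a_max_factor=factor)
        )
        assert len(kept) == expect_kept
        assert a_med == pytest.approx(expect_med)

    def test_out_of_band_records_ignored(self):
        records = _records([10, 12]) + _records([11], in_band=False)
        kept, _ = density.filter_nuclei(records, FilterParams())
        assert len(kept) == 2

    def test_no_survivor_raises_undefined_median(self):
        with pytest.raises(ValueError, match="median"):
            density.filter_nuclei(_records([0.5, 0.7]), FilterParams())

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            FilterParams(a_min_um2=6.0)
        with pytest.raises(ValueError):
            FilterParams(a_max_factor=5.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        areas=st.lists(st.floats(0.1, 60.0), min_size=1, max_size=30),
        a_min_pair=st.tuples(st.floats(0, 5), st.floats(0, 5)),
        factor_pair=st.tuples(st.floats(3.01, 4.99), st.floats(3.01, 4.99)),
    )
    def test_kept_count_monotone_in_thresholds(self, areas, a_min_pair, factor_pair):
        """Kept count never grows with a_min, never shrinks with a_max_factor."""
        records = _records(areas)

        def kept(a_min, factor):
            try:
                return len(density.filter_nuclei(
                    records, FilterParams(a_min, factor))[0])
            except ValueError:
                return 0

        lo_min, hi_min = sorted(a_min_pair)
        assert kept(hi_min, 4.0) <= kept(lo_min, 4.0)
        lo_f, hi_f = sorted(factor_pair)
        assert kept(2.5, lo_f) <= kept(2.5, hi_f)


class TestBandLength:
    def test_rectangle_oracle(self, rectangle_band):
        band, expected = rectangle_band
        assert density.estimate_band_length(band) == pytest.approx(expected, rel=0.05)

    def test_half_circle_oracle(self, half_circle_band):
        band, expected = half_circle_band
        assert density.estimate_band_length(band) == pytest.approx(expected, rel=0.05)

    def test_single_pixel_line_exact(self):
        mask = np.zeros((9, 50), dtype=bool)
        mask[4, 5:46] = True
        band = density.BandMask(mask, pixel_size_um=1.0)
        assert density.estimate_band_length(band) == pytest.approx(40.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            density.BandMask(np.zeros((5, 5), dtype=bool), 1.0)

    def test_rotation_robustness(self, clean_straight):
        micro, _ = clean_straight
        band = density.segment_band(micro)
        rot = density.BandMask(np.rot90(band.mask).copy(), band.pixel_size_um)
        l0 = density.estimate_band_length(band)
        l1 = density.estimate_band_length(rot)
        assert abs(l1 - l0) / l0 < 0.01

    def test_scale_equivariance(self, phantom_factory):
        from skimage.transform import resize

        micro, _ = phantom_factory("sinusoid", seed=3)
        up = np.stack([
            resize(c.astype(float), (c.shape[0] * 2, c.shape[1] * 2),
                   order=1, preserve_range=True)
            for c in micro.channels
        ])
        micro2 = Micrograph(up, pixel_size_um=micro.pixel_size_um / 2)
        r1 = density.run_density_pipeline(micro)
        r2 = density.run_density_pipeline(micro2)
        assert abs(r2.band_length_um - r1.band_length_um) / r1.band_length_um < 0.05
        assert abs(r2.density_per_um - r1.density_per_um) / r1.density_per_um < 0.05


class TestComputeDensity:
    def test_arithmetic(self):
        res = density.compute_density(50, 100.0)
        assert res.density_per_um == pytest.approx(0.5)
        assert density.compute_density(0, 37.0).density_per_um == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            density.compute_density(10, 0.0)


class TestSensitivity:
    def test_clean_phantom_negligible_deviation(self, clean_straight):
        micro, _ = clean_straight
        res = density.run_sensitivity(micro)
        assert len(res.entries) == 20
        assert res.max_rel_deviation <= 0.02

    def test_single_grid_point_zero_deviation(self, clean_straight):
        micro, _ = clean_straight
        res = density.run_sensitivity(micro, a_min_grid=[2.5], factor_grid=[4.0])
        assert res.max_rel_deviation == 0.0

    def test_debris_monotone_in_a_min(self, phantom_factory):
        micro, _ = phantom_factory("straight", seed=8, debris_count=30)
        band = density.segment_band(micro)
        records = density.segment_nuclei(micro, band)
        counts = [
            len(density.filter_nuclei(records, FilterParams(a, 4.0))[0])
            for a in density.DEFAULT_A_MIN_GRID
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # debris visible at a_min = 0

    def test_empty_grid_rejected(self, clean_straight):
        micro, _ = clean_straight
        with pytest.raises(ValueError):
            density.run_sensitivity(micro, a_min_grid=[], factor_grid=[4.0])


class TestCountingOracle:
    def _brute_force_components(self, raster: np.ndarray) -> int:
        """Flood-fill enumeration of 8-connected foreground components."""
        seen = np.zeros_like(raster, dtype=bool)
        h, w = raster.shape
        count = 0
        for r0 in range(h):
            for c0 in range(w):
                if not raster[r0, c0] or seen[r0, c0]:
                    continue
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and raster[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
        return count

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_counts_match_flood_fill_on_64px_fixture(self, seed):
        params = phantom.TissuePhantomParams(
            image_height_px=64, image_width_px=64, pixel_size_um=1.0,
            band_thickness_um=20.0, target_density_per_um=0.08,
            nucleus_major_um=2.5, nucleus_minor_um=2.0, seed=seed,
        )
        micro, _ = phantom.generate_tissue_phantom(params)
        band = density.segment_band(micro, 0.0, 0.0)
        records = density.segment_nuclei(micro, band)
        raster = micro.nuclei_channel > 100
        assert len(records) == self._brute_force_components(raster)


class TestManualComparison:
    def test_identical_vectors(self):
        cmp = density.compare_with_manual([10, 12, 14], [10, 12, 14])
        assert cmp.mean_signed_diff == 0.0
        assert cmp.mean_abs_diff == 0.0
        assert cmp.concordance == pytest.approx(1.0)

    def test_offsetting_differences(self):
        cmp = density.compare_with_manual([10, 12], [11, 11])
        assert cmp.mean_signed_diff == 0.0
        assert cmp.mean_abs_diff == 1.0

    def test_single_pair_concordance_undefined(self):
        cmp = density.compare_with_manual([10], [11])
        assert cmp.mean_signed_diff == -1.0
        assert math.isnan(cmp.concordance)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            density.compare_with_manual([1, 2], [1])
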