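"""The measurement pipeline: segmentation, coverage, colony areas, mixing,
attachment-event detection and probability normalisation."""

import math

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from colonyflow.errors import InvalidParameterError
from colonyflow.geometry import ChannelGeometry
from colonyflow.imaging import make_fixture
from colonyflow.quantify import (
    SegParams,
    attachment_probability,
    attachment_rate,
    colony_areas,
    colony_filter_cell_equivalent,
    cross_lineage_mixing,
    detect_attachment_events,
    mixing_from_tables,
    segment_channel,
    surface_coverage,
)


def raster_with_boxes(boxes, shape=(128, 128), amplitude=1000.0, bg=100.0):
    """Noise-free raster with rectangular objects (r0, c0, h, w)."""
    img = np.full(shape, bg)
    for r0, c0, h, w in boxes:
        img[r0 : r0 + h, c0 : c0 + w] += amplitude
    return img.astype(np.uint16)


def seg_from_mask(mask):
    """Wrap a known-good mask as a SegmentationResult via a clean raster."""
    img = np.where(mask, 1100, 100).astype(np.uint16)
    return segment_channel(img)


class TestSegmentation:
    def test_minimum_object_area_is_fifteen_pixels(self):
        """A 14-px object is discarded; a 15-px object survives intact."""
        img = raster_with_boxes([(20, 20, 7, 2), (60, 60, 5, 3)])
        res = segment_channel(img)
        assert res.n_objects == 1
        assert res.areas[0] == 15

    def test_blank_fixture_yields_no_objects(self):
        res = segment_channel(make_fixture("blank").channels[0])
        assert res.n_objects == 0

    def test_single_cell_recovered_within_thirty_percent(self):
        img = make_fixture("single_cell")
        res = segment_channel(img.channels[0])
        truth = img.truth_table()["area_px"].iloc[0]
        assert res.n_objects == 1
        assert abs(res.areas[0] - truth) <= 0.3 * truth

    def test_constant_raster_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            res = segment_channel(np.full((64, 64), 7, dtype=np.uint16))
        assert res.n_objects == 0

    def test_labels_are_contiguous_positive(self):
        img = raster_with_boxes([(10, 10, 6, 6), (50, 50, 6, 6), (90, 90, 6, 6)])
        res = segment_channel(img)
        assert sorted(np.unique(res.labels)) == [0, 1, 2, 3]

    def test_rendered_blank_false_positive_control(self):
        """Rendering nothing and quantifying yields < 0.5% coverage."""
        from colonyflow.imaging import render
        import pandas as pd

        img = render(pd.DataFrame({"x_um": [], "y_um": [], "color": []}),
                     (0, 0, 100, 100), seed=5)
        res_g = segment_channel(img.channels[0])
        res_m = segment_channel(img.channels[1])
        assert surface_coverage(res_g.mask, res_m.mask) < 0.005


class TestSurfaceCoverage:
    def test_degenerate_cases(self):
        empty = np.zeros((10, 10), bool)
        full = np.ones((10, 10), bool)
        assert surface_coverage(empty, empty) == 0.0
        assert surface_coverage(full, full) == 1.0

    def test_inclusion_exclusion(self):
        a = np.zeros((100, 100), bool)
        b = np.zeros((100, 100), bool)
        a[:, :50] = True  # left half
        b[:50, :] = True  # top half
        assert surface_coverage(a, b) == 0.75

    def test_symmetric_and_idempotent(self):
        rng = np.random.default_rng(0)
        a = rng.random((50, 50)) > 0.8
        b = rng.random((50, 50)) > 0.8
        assert surface_coverage(a, b) == surface_coverage(b, a)
        assert surface_coverage(a, a) == a.mean()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            surface_coverage(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestColonyAreas:
    PIXEL = 0.1791

    def test_small_object_removed_and_area_converted(self):
        """A 400-px square survives the 200-px filter (12.83 um^2); a 100-px
        square does not."""
        a = np.zeros((128, 128), bool)
        a[20:40, 20:40] = True  # 400 px
        a[80:90, 80:90] = True  # 100 px
        stats = colony_areas(a, np.zeros_like(a), self.PIXEL)
        assert stats.areas_um2.size == 1
        assert stats.median_um2 == pytest.approx(400 * self.PIXEL**2, rel=1e-9)
        assert stats.median_um2 == pytest.approx(12.83, abs=0.01)

    @pytest.mark.parametrize(
        "fixture, expected", [("two_squares_gap6", 1), ("two_squares_gap20", 2)]
    )
    def test_disk_closing_bridges_small_gaps(self, fixture, expected):
        """Closing with a radius-5 disk merges 6-px gaps but not 20-px gaps;
        cross-checked against an independent morphology implementation."""
        img = make_fixture(fixture)
        res = segment_channel(img.channels[0])
        stats = colony_areas(res.mask, np.zeros_like(res.mask), img.pixel_um)
        assert stats.areas_um2.size == expected
        # independent oracle: scipy.ndimage closing on the ground-truth mask
        truth = img.truth[0] > 0
        padded = np.pad(truth, 5)
        closed = ndimage.binary_closing(padded, structure=morphology.disk(5))[5:-5, 5:-5]
        n_oracle = ndimage.label(closed, structure=np.ones((3, 3)))[1]
        assert n_oracle == expected

    def test_coverage_gate_excludes_saturated_images(self):
        img = make_fixture("near_saturated")
        stats = colony_areas(img.truth[0] > 0, img.truth[1] > 0, self.PIXEL)
        assert stats.excluded
        assert stats.areas_um2.size == 0 and math.isnan(stats.median_um2)

    def test_filter_close_order_flag(self):
        """Two sub-threshold squares bridged by closing survive only in the
        close-before-filter ordering."""
        a = np.zeros((128, 128), bool)
        a[50:60, 30:45] = True  # 150 px
        a[50:60, 51:66] = True  # 150 px, 6-px gap
        first = colony_areas(a, np.zeros_like(a), 1.0, filter_before_close=True)
        second = colony_areas(a, np.zeros_like(a), 1.0, filter_before_close=False)
        assert first.areas_um2.size == 0
        assert second.areas_um2.size == 1


class TestCrossLineageMixing:
    def test_three_four_five_triangle(self):
        """Centroids at (10,10) and (13,14) with 1 um pixels: both directions 5 um."""
        a = np.zeros((30, 30), bool)
        b = np.zeros((30, 30), bool)
        a[8:13, 8:13] = True  # 5x5, centroid (10, 10)
        b[11:16, 12:17] = True  # 5x5, centroid (13, 14)
        mix = cross_lineage_mixing(seg_from_mask(a), seg_from_mask(b), 1.0,
                                   closing_radius=1)
        assert mix.defined and mix.n == 2
        np.testing.assert_allclose(mix.distances_um, [5.0, 5.0])
        assert mix.mean_um == pytest.approx(5.0)

    def test_checkerboard_mean_equals_grid_spacing(self):
        img = make_fixture("checkerboard_mixed")
        res_g = segment_channel(img.channels[0])
        res_m = segment_channel(img.channels[1])
        mix = cross_lineage_mixing(res_g, res_m, img.pixel_um)
        assert mix.mean_um == pytest.approx(30.0, rel=1e-6)
        assert mix.n == 16

    def test_segregated_halves_mean_exceeds_gap(self):
        img = make_fixture("segregated_halves")
        mix = cross_lineage_mixing(
            segment_channel(img.channels[0]), segment_channel(img.channels[1]),
            img.pixel_um)
        assert mix.mean_um >= 60.0  # the constructed inter-block gap

    def test_empty_channel_is_undefined_not_zero(self):
        a = np.zeros((30, 30), bool)
        a[10:15, 10:15] = True
        mix = cross_lineage_mixing(seg_from_mask(a),
                                   seg_from_mask(np.zeros((30, 30), bool)), 1.0)
        assert not mix.defined and math.isnan(mix.mean_um)

    def test_table_and_mask_routes_agree(self):
        pts_a = np.array([[10.0, 10.0]])
        pts_b = np.array([[13.0, 14.0]])
        assert mixing_from_tables(pts_a, pts_b).mean_um == pytest.approx(5.0)


class TestJointImageInvariances:
    def _stats(self, mask_a, mask_b):
        areas = colony_areas(mask_a, mask_b, 1.0, min_colony_px=50)
        mix = cross_lineage_mixing(seg_from_mask(mask_a), seg_from_mask(mask_b), 1.0)
        return sorted(areas.areas_um2), mix.mean_um

    def test_translation_and_rotation_invariance(self):
        img = make_fixture("checkerboard_mixed")
        a, b = img.truth[0] > 0, img.truth[1] > 0
        base = self._stats(a, b)
        shifted = self._stats(np.roll(a, (7, 11), (0, 1)), np.roll(b, (7, 11), (0, 1)))
        rotated = self._stats(np.rot90(a), np.rot90(b))
        for other in (shifted, rotated):
            np.testing.assert_allclose(other[0], base[0])
            assert other[1] == pytest.approx(base[1], rel=1e-9)


class TestAttachmentEvents:
    def frames_with_track(self, present, pos=(10.0, 10.0), n_frames=12):
        return [
            np.array([pos]) if k in present else np.empty((0, 2))
            for k in range(n_frames)
        ], np.arange(n_frames, dtype=float)

    def test_two_frame_appearance_not_counted(self):
        frames, times = self.frames_with_track({5, 6})
        assert detect_attachment_events(frames, times).size == 0

    def test_three_frame_persistence_counted_at_first_frame(self):
        frames, times = self.frames_with_track({5, 6, 7})
        events = detect_attachment_events(frames, times)
        np.testing.assert_array_equal(events, [5.0])

    def test_drifting_object_fails_same_location_rule(self):
        frames = [np.array([[10.0 + 5 * k, 10.0]]) for k in range(5)]
        events = detect_attachment_events(frames, np.arange(5.0), epsilon_px=3.0)
        assert events.size == 0

    def test_jitter_within_tolerance_is_same_location(self):
        frames = [np.array([[10.0 + 0.5 * k, 10.0]]) for k in range(5)]
        events = detect_attachment_events(frames, np.arange(5.0), epsilon_px=3.0)
        np.testing.assert_array_equal(events, [0.0])

    def test_nonuniform_timestamps_rejected(self):
        frames, _ = self.frames_with_track({0, 1, 2}, n_frames=4)
        with pytest.raises(InvalidParameterError):
            detect_attachment_events(frames, [0.0, 1.0, 2.0, 4.0])

    def test_two_simultaneous_tracks_two_events(self):
        frames = [np.array([[10.0, 10.0], [50.0, 50.0]])] * 4
        events = detect_attachment_events(frames, np.arange(4.0))
        assert events.size == 2


class TestAttachmentRate:
    def test_two_events_per_frame_gives_rate_two(self):
        times = np.arange(1.0, 61.0)
        events = np.repeat(times, 2)
        res = attachment_rate(events, times)
        assert res.rate == pytest.approx(2.0, rel=1e-12)

    def test_zero_events_flagged(self):
        res = attachment_rate([], np.arange(0.0, 60.0))
        assert res.rate == 0.0 and math.isinf(res.stderr)

    def test_poisson_events_recover_intensity(self):
        rng = np.random.default_rng(4)
        lam, span = 0.5, 600.0
        n = rng.poisson(lam * span)
        events = np.sort(rng.uniform(0, span, n))
        res = attachment_rate(events, np.arange(0.0, span + 1.0))
        assert res.rate == pytest.approx(lam, abs=3 * math.sqrt(lam / span))


class TestAttachmentProbability:
    def test_reference_value(self):
        """r = 9 cells/s, Q = 1 ul/s, C = 4.5e4 cells/ul -> p = 2e-4."""
        est = attachment_probability(9.0, 1e-9, 4.5e4 * 1e9)
        assert est.p_att == pytest.approx(2.0e-4, rel=1e-12)

    def test_inverse_in_concentration(self):
        a = attachment_probability(1.0, 1e-9, 1e13).p_att
        b = attachment_probability(1.0, 1e-9, 2e13).p_att
        assert a == pytest.approx(2 * b, rel=1e-12)

    def test_zero_rate(self):
        assert attachment_probability(0.0, 1e-9, 1e13).p_att == 0.0

    def test_flux_reported_with_geometry(self):
        g = ChannelGeometry.from_lab_units(1.0, 500.0, 90.0)
        est = attachment_probability(9.0, 1e-9, 4.5e13, geometry=g)
        assert est.flux == pytest.approx(1e-9 * 4.5e13 / g.area, rel=1e-12)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            attachment_probability(1e6, 1e-9, 1e9)


def test_colony_filter_equivalence_is_five_cells():
    """200 px divided by the 40.2-px mean cell area rounds to five cells."""
    assert colony_filter_cell_equivalent() == 5
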