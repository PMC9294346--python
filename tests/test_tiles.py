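"""Tiling lattice, coordinate maps, and point-mark -> box label synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoquant import (
    PointMark,
    WellImage,
    assign_labels,
    box_side_from_width,
    extract_segment,
    grid_dims,
    to_global,
    to_local,
)


class TestGridDims:
    @pytest.mark.parametrize(
        "w,h,size,overlap,cols,rows",
        [
            (10248, 9122, 416, 0.5, 50, 44),   # full-scale well, 50% overlap
            (8320, 7760, 416, 0.5, 40, 38),    # smaller-well dataset
            (10248, 9122, 416, 0.0, 25, 22),   # counting grid, no overlap
            (416, 416, 416, 0.0, 1, 1),        # image equals one segment
            (416, 416, 416, 0.5, 2, 2),        # ceil rule applies per axis
        ],
    )
    def test_printed_segment_counts(self, w, h, size, overlap, cols, rows):
        g = grid_dims(w, h, size, overlap)
        assert (g.n_cols, g.n_rows) == (cols, rows)
        assert g.n_segments == cols * rows

    def test_overlap_quadruples_segments_when_dims_exceed_two_strides(self):
        g_half = grid_dims(10248, 9122, 416, 0.5)
        g_none = grid_dims(10248, 9122, 416, 0.0)
        assert g_half.n_segments == 4 * g_none.n_segments == 2200

    def test_non_integer_stride_rejected(self):
        with pytest.raises(ValueError, match="0.3"):
            grid_dims(1000, 1000, 416, 0.3)

    @pytest.mark.parametrize("w,h", [(0, 100), (100, 0), (-5, 100)])
    def test_degenerate_dimensions_rejected(self, w, h):
        with pytest.raises(ValueError):
            grid_dims(w, h, 416, 0.5)

    @given(
        w=st.integers(1, 5000),
        h=st.integers(1, 5000),
        size=st.integers(1, 600),
        inv_frac=st.sampled_from([1, 2, 4, 8]),
    )
    @settings(max_examples=60, deadline=None)
    def test_every_pixel_covered_by_some_window(self, w, h, size, inv_frac):
        overlap = 1.0 - 1.0 / inv_frac
        if (size * (1.0 - overlap)) % 1:
            return
        g = grid_dims(w, h, size, overlap)
        # the last window must reach the far edge in both axes
        assert (g.n_cols - 1) * g.stride_px + size >= w
        assert (g.n_rows - 1) * g.stride_px + size >= h
        # and every pixel belongs to at least one window
        assert g.refs_containing(w - 0.5, h - 0.5)
        assert g.refs_containing(0.0, 0.0)


class TestExtractSegment:
    def test_interior_segment_of_constant_image_is_constant(self):
        well = WellImage(np.full((1000, 1000), 7, dtype=np.uint8))
        g = grid_dims(1000, 1000, 416, 0.5)
        seg = extract_segment(well, g.ref(1, 1))
        assert seg.shape == (416, 416)
        assert (seg == 7).all()

    def test_bottom_right_segment_pads_beyond_image(self):
        # full-scale grid: last column origin 49*208 = 10,192 leaves 56 image
        # columns and 360 pad columns
        well = WellImage(np.full((9122, 10248), 9, dtype=np.uint8))
        g = grid_dims(10248, 9122, 416, 0.5)
        ref = g.ref(g.n_rows - 1, g.n_cols - 1)
        assert ref.origin_x == 10192
        seg = extract_segment(well, ref)
        n_rows_img = 9122 - ref.origin_y  # image rows before the bottom pad
        assert (seg[:n_rows_img, :56] == 9).all()
        assert (seg[:, 56:] == 0).all()
        assert (seg[n_rows_img:, :] == 0).all()
        assert seg[:, 56:].shape[1] == ref.origin_x + 416 - 10248 == 360

    def test_nonoverlap_tiling_partitions_image_exactly(self, rng):
        pixels = rng.integers(0, 255, size=(832, 1040), dtype=np.uint8)
        well = WellImage(pixels)
        g = grid_dims(1040, 832, 416, 0.0)
        rebuilt = np.zeros((g.n_rows * 416, g.n_cols * 416), dtype=np.uint8)
        for ref in g.refs():
            rebuilt[ref.origin_y:ref.origin_y + 416,
                    ref.origin_x:ref.origin_x + 416] = extract_segment(well, ref)
        assert (rebuilt[:832, :1040] == pixels).all()

    def test_ref_outside_grid_rejected(self):
        g = grid_dims(1000, 1000, 416, 0.5)
        with pytest.raises(ValueError):
            g.ref(g.n_rows, 0)


class TestCoordinateMaps:
    def test_origin_maps_to_segment_origin(self):
        g = grid_dims(2000, 2000, 416, 0.5)
        ref = g.ref(1, 1)
        assert to_global(ref, 0.0, 0.0) == (208, 208)

    def test_local_is_global_shifted_by_origin(self):
        g = grid_dims(2000, 2000, 416, 0.5)
        assert to_local(g.ref(1, 2), 500.0, 300.0) == (84.0, 92.0)

    def test_round_trip_identity_on_random_points(self, rng):
        g = grid_dims(3000, 2500, 416, 0.5)
        refs = list(g.refs())
        for _ in range(1000):
            ref = refs[rng.integers(len(refs))]
            x, y = rng.uniform(0, 416, size=2)
            gx, gy = to_global(ref, x, y)
            assert to_local(ref, gx, gy) == pytest.approx((x, y), abs=1e-12)


class TestBoxSide:
    @pytest.mark.parametrize("width,side", [(10248, 100), (8320, 81), (1025, 10)])
    def test_fixed_fraction_side_matches_printed_values(self, width, side):
        assert box_side_from_width(width) == side

    def test_rounding_is_half_away_from_zero(self):
        # 0.5 exactly must round up, not to even
        assert box_side_from_width(1000, fraction=0.0125) == 13  # 12.5 -> 13

    def test_degenerate_side_rejected(self):
        with pytest.raises(ValueError, match="degenerates"):
            box_side_from_width(10)


class TestAssignLabels:
    def test_mark_in_center_of_nonoverlap_grid_appears_once(self):
        g = grid_dims(832, 832, 416, 0.0)
        labels = assign_labels([PointMark(416.0, 416.0)], g, 100)
        boxed = {k: v for k, v in labels.items() if v}
        assert list(boxed) == [(1, 1)]

    def test_interior_mark_appears_in_four_overlapping_segments(self):
        g = grid_dims(2000, 2000, 416, 0.5)
        labels = assign_labels([PointMark(210.0, 210.0)], g, 100)
        boxed = sorted(k for k, v in labels.items() if v)
        assert boxed == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_box_near_segment_edge_is_clipped_not_shifted(self):
        g = grid_dims(416, 416, 416, 0.0)
        labels = assign_labels([PointMark(10.0, 200.0)], g, 100)
        (box,) = labels[(0, 0)]
        assert box.w == pytest.approx(60.0)  # 10 px inside + 50 px half-box
        assert box.h == pytest.approx(100.0)
        assert box.x0 == pytest.approx(0.0)

    def test_mark_outside_well_rejected(self):
        g = grid_dims(416, 416, 416, 0.0)
        with pytest.raises(ValueError, match="outside"):
            assign_labels([PointMark(500.0, 10.0)], g, 100)

    def test_label_conservation_on_nonoverlap_grid(self, rng):
        g = grid_dims(2080, 1664, 416, 0.0)
        marks = [PointMark(rng.uniform(0, 2080), rng.uniform(0, 1664))
                 for _ in range(200)]
        labels = assign_labels(marks, g, 100)
        assert sum(len(v) for v in labels.values()) == 200

    def test_clipped_boxes_stay_inside_segment(self, rng):
        g = grid_dims(2080, 1664, 416, 0.5)
        marks = [PointMark(rng.uniform(0, 2080), rng.uniform(0, 1664))
                 for _ in range(300)]
        for boxes in assign_labels(marks, g, 100).values():
            for b in boxes:
                assert -1e-9 <= b.x0 and b.x1 <= 416 + 1e-9
                assert -1e-9 <= b.y0 and b.y1 <= 416 + 1e-9
                assert b.w > 0 and b.h > 0
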