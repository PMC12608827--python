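"""Path length, tortuosity, total lengths, segment statistics, area fractions."""

from __future__ import annotations

import math

import numpy as np
import pytest

from duravasc.image_io import LabelMask, VesselClass
from duravasc.morphometry import (
    chord_length,
    path_length,
    segment_statistics,
    segment_table,
    summarize_image,
    tortuosity,
    total_vessel_length,
    vessel_area_fraction,
)
from duravasc.skeleton_graph import VesselSegment, build_graph, extract_graph

from conftest import mask_from_ascii, skeleton_from_ascii


def _seg(polyline, cls=VesselClass.ARTERIOLE, complete=True):
    return VesselSegment(
        id=0, vessel_class=cls, polyline=list(polyline), end_nodes=(0, 1),
        complete=complete,
    )


class TestPathLength:
    def test_collinear_horizontal_pixels(self):
        assert path_length([(0, c) for c in range(11)]) == pytest.approx(10.0)

    def test_main_diagonal(self):
        assert path_length([(i, i) for i in range(6)]) == pytest.approx(5 * math.sqrt(2))

    def test_pixel_size_scales_linearly(self):
        poly = [(i, i) for i in range(6)]
        assert path_length(poly, 0.5) == pytest.approx(0.5 * path_length(poly))

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            path_length([(0, 0)])

    def test_non_adjacent_pixels_rejected(self):
        with pytest.raises(ValueError, match="8-neighbours"):
            path_length([(0, 0), (0, 3)])


class TestTortuosity:
    def test_straight_path_is_exactly_one(self):
        seg = _seg([(0, c) for c in range(11)])
        assert tortuosity(seg) == 1.0

    def test_l_path_is_sqrt2(self):
        poly = [(0, c) for c in range(6)] + [(r, 5) for r in range(1, 6)]
        assert tortuosity(_seg(poly)) == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_rasterized_semicircle_near_half_pi(self):
        # digitize a semicircular arc of radius 40 px and follow the
        # extracted centerline of its width-3 rasterization
        size, r, cen = 120, 40, (60, 60)
        grid = np.zeros((size, size), dtype=np.uint8)
        for t in np.linspace(0, math.pi, 3000):
            pr, pc = cen[0] - r * math.sin(t), cen[1] + r * math.cos(t)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    grid[int(round(pr)) + dr, int(round(pc)) + dc] = 1
        graph = extract_graph(LabelMask(grid=grid), min_spur_length=5)
        assert len(graph.segments) == 1
        ratio = tortuosity(graph.segments[0])
        assert ratio == pytest.approx(math.pi / 2, abs=0.03)

    def test_zero_chord_loop_excluded_not_crash(self):
        poly = [(0, 0), (0, 1), (1, 1), (1, 0), (0, 0)]
        assert tortuosity(_seg(poly)) is None

    def test_isometry_invariance_under_grid_rotations_and_flips(self):
        rng = np.random.default_rng(7)
        # random 8-connected staircase path
        poly = [(0, 0)]
        for _ in range(40):
            dr, dc = rng.choice([(0, 1), (1, 0), (1, 1)])
            poly.append((poly[-1][0] + dr, poly[-1][1] + dc))
        base = tortuosity(_seg(poly))
        transforms = [
            lambda p: (p[1], -p[0]),     # rot90
            lambda p: (-p[0], -p[1]),    # rot180
            lambda p: (-p[1], p[0]),     # rot270
            lambda p: (p[0], -p[1]),     # flip
            lambda p: (p[1], p[0]),      # transpose
        ]
        for tf in transforms:
            assert tortuosity(_seg([tf(p) for p in poly])) == pytest.approx(base, abs=1e-6)


class TestTotalLength:
    def test_empty_graph_gives_zeros(self):
        skel, classes = skeleton_from_ascii(".")
        graph = build_graph(skel, classes)
        totals = total_vessel_length(graph)
        assert totals["total"] == 0.0
        assert totals["arteriole_length"] == 0.0

    def test_h_geometry_total_is_sum_of_segments(self):
        skel, classes = skeleton_from_ascii(
            """
            A.....A
            A.....A
            A.....A
            A.....A
            AAAAAAA
            A.....A
            A.....A
            A.....A
            A.....A
            """
        )
        graph = build_graph(skel, classes)
        totals = total_vessel_length(graph)
        by_hand = sum(path_length(s.polyline) for s in graph.segments)
        assert totals["total"] == pytest.approx(by_hand)
        assert totals["arteriole_length"] == pytest.approx(by_hand)

    def test_additive_over_disjoint_subgraphs(self):
        a, ca = skeleton_from_ascii("AAAAAA")
        combined, cc = skeleton_from_ascii(
            """
            AAAAAA
            ......
            VVVV..
            """
        )
        b, cb = skeleton_from_ascii("VVVV")
        ga, gb = build_graph(a, ca), build_graph(b, cb)
        gc = build_graph(combined, cc)
        assert total_vessel_length(gc)["total"] == pytest.approx(
            total_vessel_length(ga)["total"] + total_vessel_length(gb)["total"]
        )

    def test_includes_incomplete_and_undetermined(self):
        skel, classes = skeleton_from_ascii("AAAUUUU")
        graph = build_graph(skel, classes)
        totals = total_vessel_length(graph)
        assert totals["undetermined_length"] > 0
        assert totals["total"] == pytest.approx(
            totals["total_determined"] + totals["undetermined_length"]
        )


class TestSegmentStatistics:
    def test_single_complete_segment_mean_is_its_length(self):
        skel, classes = skeleton_from_ascii(
            """
            A...........A
            .AAAAAAAAAAA.
            A...........A
            """
        )
        graph = build_graph(skel, classes)
        stats = segment_statistics(graph)
        complete = [s for s in graph.segments if s.complete]
        assert len(complete) == 1
        assert stats["overall"]["segment_length"]["n"] == 1
        assert stats["overall"]["segment_length"]["mean"] == pytest.approx(
            path_length(complete[0].polyline)
        )

    def test_y_graph_without_complete_segments_flags_missing(self):
        skel, classes = skeleton_from_ascii(
            """
            A...A
            .A.A.
            ..A..
            ..A..
            ..A..
            ..A..
            """
        )
        stats = segment_statistics(build_graph(skel, classes))
        assert stats["overall"]["segment_length"]["n"] == 0
        assert stats["overall"]["segment_length"]["mean"] is None
        assert stats["overall"]["tortuosity"]["mean"] is None

    def test_means_match_recomputation_from_segment_table(self, rng):
        from conftest import random_label_mask

        for _ in range(10):
            mask = random_label_mask(rng, size=24, p_fg=0.35)
            graph = extract_graph(mask, min_spur_length=0)
            stats = segment_statistics(graph)
            table = segment_table(graph)
            comp = table[table.complete]
            if len(comp):
                assert stats["overall"]["segment_length"]["mean"] == pytest.approx(
                    comp.length.mean()
                )
                torts = comp.tortuosity.dropna()
                if len(torts):
                    assert stats["overall"]["tortuosity"]["mean"] == pytest.approx(
                        torts.mean()
                    )
            else:
                assert stats["overall"]["segment_length"]["n"] == 0


class TestAreaFraction:
    def test_all_background_is_zero(self):
        mask = LabelMask(grid=np.zeros((10, 10), dtype=np.uint8))
        assert vessel_area_fraction(mask)["vessel_area_fraction"] == 0.0

    def test_counted_fraction(self):
        grid = np.zeros((100, 100), dtype=np.uint8)
        grid.flat[:1000] = 1
        mask = LabelMask(grid=grid)
        assert vessel_area_fraction(mask)["vessel_area_fraction"] == pytest.approx(0.1)

    def test_all_vessel_is_one(self):
        mask = LabelMask(grid=np.ones((5, 5), dtype=np.uint8))
        assert vessel_area_fraction(mask)["vessel_area_fraction"] == 1.0

    def test_invariant_under_rotation_and_reflection(self, rng):
        from conftest import random_label_mask

        mask = random_label_mask(rng, size=16)
        base = vessel_area_fraction(mask)
        for tf in (np.rot90, np.fliplr, np.flipud):
            out = vessel_area_fraction(LabelMask(grid=tf(mask.grid).copy()))
            assert out == base


class TestSummarizeImage:
    def test_empty_mask_gives_zero_record(self):
        mask = LabelMask(grid=np.zeros((8, 8), dtype=np.uint8), image_id="e")
        graph = extract_graph(mask)
        rec = summarize_image(graph, mask)
        assert rec.total_length == 0.0
        assert rec.n_complete_segments == 0
        assert rec.vessel_area_fraction == 0.0

    def test_single_straight_arteriole(self):
        mask = mask_from_ascii(
            """
            ..........
            AAAAAAAAAA
            ..........
            """
        )
        graph = extract_graph(mask, min_spur_length=0)
        rec = summarize_image(graph, mask)
        assert rec.arteriole_length == pytest.approx(rec.total_length)
        assert rec.venule_length == 0.0

    def test_id_mismatch_rejected(self):
        m1 = LabelMask(grid=np.zeros((4, 4), dtype=np.uint8), image_id="a")
        m2 = LabelMask(grid=np.zeros((4, 4), dtype=np.uint8), image_id="b")
        graph = extract_graph(m1)
        with pytest.raises(ValueError, match="graph is from"):
            summarize_image(graph, m2)

    def test_fields_match_recomputation_from_parts(self, rng):
        from conftest import random_label_mask

        mask = random_label_mask(rng, size=24, p_fg=0.35)
        graph = extract_graph(mask, min_spur_length=3)
        rec = summarize_image(graph, mask)
        totals = total_vessel_length(graph)
        stats = segment_statistics(graph)
        areas = vessel_area_fraction(mask)
        assert rec.total_length == totals["total"]
        assert rec.arteriole_length == totals["arteriole_length"]
        assert rec.mean_segment_length == stats["overall"]["segment_length"]["mean"]
        assert rec.vessel_area_fraction == areas["vessel_area_fraction"]
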