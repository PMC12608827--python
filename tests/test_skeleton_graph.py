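"""Thinning, spur pruning, pixel classification and graph extraction."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.measure import label as cc_label

from duravasc.image_io import LabelMask, VesselClass
from duravasc.skeleton_graph import (
    NodeKind,
    build_graph,
    classify_skeleton_pixels,
    extract_graph,
    prune_spurs,
    skeletonize_mask,
)
from duravasc.validation import brute_force_graph_summary, graph_summary

from conftest import mask_from_ascii, random_label_mask, skeleton_from_ascii


class TestSkeletonize:
    def test_wide_bar_thins_to_single_path(self):
        grid = np.zeros((9, 24), dtype=np.uint8)
        grid[3:6, 2:22] = 1
        skel = skeletonize_mask(LabelMask(grid=grid))
        # one pixel wide: no 2x2 all-skeleton block
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        assert not blocks.any()
        assert cc_label(skel, connectivity=2).max() == 1
        assert skel.sum() >= 15  # spans most of the bar

    def test_empty_mask_gives_empty_skeleton(self):
        skel = skeletonize_mask(LabelMask(grid=np.zeros((8, 8), dtype=np.uint8)))
        assert not skel.any()

    def test_component_count_preserved_on_random_blobs(self, rng):
        for _ in range(20):
            mask = random_label_mask(rng, size=24, p_fg=0.3)
            skel = skeletonize_mask(mask)
            n_fg = cc_label(mask.foreground(), connectivity=2).max()
            n_sk = cc_label(skel, connectivity=2).max()
            assert n_sk == n_fg


class TestPruneSpurs:
    def test_short_side_spur_removed_path_intact(self):
        # diagonal main path with a 2-pixel perpendicular spur off (6,6);
        # both main arms are longer than the threshold
        skel, _ = skeleton_from_ascii(
            """
            A............
            .A...........
            ..A..........
            ...A.........
            ....A...A....
            .....A.A.....
            ......A......
            .......A.....
            ........A....
            .........A...
            ..........A..
            ...........A.
            ............A
            """
        )
        out = prune_spurs(skel, 5)
        assert out.sum() == 13
        assert all(out[i, i] for i in range(13))

    def test_threshold_zero_is_identity(self):
        skel, _ = skeleton_from_ascii(
            """
            ..A.....
            AAAAAAAA
            """
        )
        assert np.array_equal(prune_spurs(skel, 0), skel)

    def test_isolated_short_path_kept(self):
        skel, _ = skeleton_from_ascii("AAA")
        assert np.array_equal(prune_spurs(skel, 5), skel)

    def test_idempotent_on_random_skeletons(self, rng):
        for _ in range(15):
            mask = random_label_mask(rng, size=20, p_fg=0.35)
            skel = skeletonize_mask(mask)
            once = prune_spurs(skel, 4)
            twice = prune_spurs(once, 4)
            assert np.array_equal(once, twice)


class TestClassify:
    def test_pixel_takes_mask_label(self):
        mask = mask_from_ascii(
            """
            AAAAVVVV
            """
        )
        skel = np.ones((1, 8), dtype=bool)
        classes = classify_skeleton_pixels(skel, mask)
        assert classes[(0, 0)] == VesselClass.ARTERIOLE
        assert classes[(0, 7)] == VesselClass.VENULE

    def test_equals_exhaustive_lookup(self, rng):
        mask = random_label_mask(rng, size=16)
        skel = skeletonize_mask(mask)
        classes = classify_skeleton_pixels(skel, mask)
        for (r, c), cls in classes.items():
            assert cls == VesselClass(int(mask.grid[r, c]))
        assert len(classes) == int(skel.sum())

    def test_skeleton_over_background_is_error(self):
        mask = mask_from_ascii("A.")
        skel = np.array([[True, True]])
        with pytest.raises(ValueError, match="background"):
            classify_skeleton_pixels(skel, mask)


class TestBuildGraph:
    def test_y_shape_one_branch_three_endpoints_no_complete(self):
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
        graph = build_graph(skel, classes)
        counts = graph.node_counts()
        assert counts[NodeKind.BRANCHING] == 1
        assert counts[NodeKind.ENDPOINT] == 3
        assert len(graph.segments) == 3
        assert sum(s.complete for s in graph.segments) == 0

    def test_h_shape_five_segments_crossbar_complete(self):
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
        counts = graph.node_counts()
        assert counts[NodeKind.BRANCHING] == 2
        assert counts[NodeKind.ENDPOINT] == 4
        assert len(graph.segments) == 5
        complete = [s for s in graph.segments if s.complete]
        assert len(complete) == 1
        # the crossbar runs between the two junction clusters
        rows = {p[0] for p in complete[0].polyline}
        assert rows == {4}

    def test_bare_transition_path_two_incomplete_segments(self):
        skel, classes = skeleton_from_ascii("AAAAAVVVVV")
        graph = build_graph(skel, classes)
        counts = graph.node_counts()
        assert counts[NodeKind.TRANSITION] == 1
        assert counts[NodeKind.ENDPOINT] == 2
        assert len(graph.segments) == 2
        assert all(not s.complete for s in graph.segments)
        # transition node sits at the first pixel of the new class
        trans = [n for n in graph.nodes if n.kind is NodeKind.TRANSITION][0]
        assert trans.position == (0, 5)
        assert {s.vessel_class for s in graph.segments} == {
            VesselClass.ARTERIOLE,
            VesselClass.VENULE,
        }

    def test_transition_path_between_junctions_both_complete(self):
        skel, classes = skeleton_from_ascii(
            """
            A..........V
            .AAAAAVVVVV.
            A..........V
            """
        )
        graph = build_graph(skel, classes)
        counts = graph.node_counts()
        assert counts[NodeKind.BRANCHING] == 2
        assert counts[NodeKind.TRANSITION] == 1
        main = [s for s in graph.segments if s.n_pixels > 2]
        assert len(main) == 2
        assert all(s.complete for s in main)

    def test_pure_cycle_gets_anchor_and_zero_chord_segment(self):
        skel, classes = skeleton_from_ascii(
            """
            .AAA.
            A...A
            A...A
            .AAA.
            """
        )
        graph = build_graph(skel, classes)
        assert len(graph.segments) == 1
        seg = graph.segments[0]
        assert seg.polyline[0] == seg.polyline[-1]
        assert graph.nodes[0].kind is NodeKind.BRANCHING

    def test_pixel_conservation(self, rng):
        for _ in range(20):
            mask = random_label_mask(rng, size=20, p_fg=0.35)
            skel = skeletonize_mask(mask)
            classes = classify_skeleton_pixels(skel, mask)
            graph = build_graph(skel, classes)
            node_pixels = set()
            for n in graph.nodes:
                node_pixels |= set(n.pixels)
            interior = []
            for s in graph.segments:
                interior.extend(p for p in s.polyline if p not in node_pixels)
            # isolated single pixels are dropped by design
            deg = _degrees(skel)
            n_isolated = int(((deg == 0) & skel).sum())
            assert len(interior) == len(set(interior))  # edge-disjoint
            assert len(set(interior)) + len(node_pixels) + n_isolated == int(skel.sum())

    def test_node_degree_invariants(self, rng):
        for _ in range(20):
            mask = random_label_mask(rng, size=20, p_fg=0.35)
            graph = extract_graph(mask, min_spur_length=0)
            for node in graph.nodes:
                incident = _incidence(graph, node.id)
                if node.kind is NodeKind.ENDPOINT:
                    assert incident == 1
                elif node.kind is NodeKind.TRANSITION:
                    assert incident == 2
                    classes = {
                        s.vessel_class for s in graph.segments if node.id in s.end_nodes
                    }
                    assert len(classes) == 2
                else:
                    assert incident >= 2  # >=3 except the artificial cycle anchor
            for seg in graph.segments:
                steps = np.abs(np.diff(np.asarray(seg.polyline), axis=0))
                assert (steps.max(axis=1) == 1).all()  # consecutive 8-neighbours

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        n_checked = 0
        for _ in range(120):
            mask = random_label_mask(rng, size=12, p_fg=rng.uniform(0.25, 0.5))
            skel = skeletonize_mask(mask)
            if not skel.any():
                continue
            classes = classify_skeleton_pixels(skel, mask)
            ours = graph_summary(build_graph(skel, classes))
            ref = brute_force_graph_summary(skel, classes)
            assert ours == ref
            n_checked += 1
        assert n_checked >= 80

    def test_rasterized_tree_recovers_branch_count(self):
        # trunk with two well-separated side branches, width 3
        from scipy import ndimage as ndi
        from skimage.morphology import disk

        size = 96
        img = np.zeros((size, size), dtype=bool)

        def draw(p0, p1):
            n = 300
            t = np.linspace(0, 1, n)
            pts = np.round(
                np.stack(
                    [p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1])], axis=1
                )
            ).astype(int)
            img[pts[:, 0], pts[:, 1]] = True

        draw((48, 5), (48, 90))       # trunk
        draw((48, 25), (10, 45))      # branch 1
        draw((48, 60), (85, 80))      # branch 2
        wide = ndi.binary_dilation(img, structure=disk(1))
        mask = LabelMask(grid=np.where(wide, np.uint8(1), np.uint8(0)))
        graph = extract_graph(mask, min_spur_length=5)
        assert graph.node_counts()[NodeKind.BRANCHING] == 2


def _degrees(skel: np.ndarray) -> np.ndarray:
    padded = np.pad(skel.astype(np.uint8), 1)
    deg = np.zeros_like(padded)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr or dc:
                deg += np.roll(np.roll(padded, dr, 0), dc, 1)
    return deg[1:-1, 1:-1]


def _incidence(graph, node_id: int) -> int:
    n = 0
    for s in graph.segments:
        a, b = s.end_nodes
        if a == node_id:
            n += 1
        if b == node_id:
            n += 1
    return n
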