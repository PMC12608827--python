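"""Centerline graph extraction from class-labelled vessel masks.

The binary union of all vessel classes is thinned to a one-pixel-wide,
topology-preserving skeleton (8-connectivity). Skeleton pixels are typed
by their neighbour count: junction pixels (>=3 skeleton neighbours) are
merged — adjacent junction pixels form a single BRANCHING node, since
thinning routinely leaves 2-pixel junction clusters — endpoints (exactly
1 neighbour) become ENDPOINT nodes, and the remaining degree-2 corridors
become segment polylines. Where the vessel class changes between two
consecutive corridor pixels a TRANSITION node is inserted at the first
pixel of the new class; that pixel belongs to both flanking segments.

A segment is *complete* when both of its end nodes are BRANCHING or
TRANSITION nodes; segments ending at an image endpoint (including the
image border) are incomplete. Pure cycles carrying no node receive one
artificial BRANCHING-kind anchor at their lexicographically smallest
pixel; the resulting loop segment has zero chord and is excluded from
tortuosity downstream.

Short terminal branches are thinning artifacts of vessel-wall
irregularities; :func:`prune_spurs` removes terminal branches shorter
than a configurable threshold (default 5 px) before graph construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from .image_io import LabelMask, VesselClass

__all__ = [
    "NodeKind",
    "SkeletonNode",
    "VesselSegment",
    "SkeletonGraph",
    "DEFAULT_MIN_SPUR_LENGTH",
    "skeletonize_mask",
    "prune_spurs",
    "classify_skeleton_pixels",
    "build_graph",
    "graph_to_json_dict",
    "extract_graph",
]

Pixel = tuple[int, int]

#: Default minimum terminal-branch length (pixels) kept after pruning.
DEFAULT_MIN_SPUR_LENGTH = 5

# 8-neighbourhood offsets in fixed scan order (row-major) for determinism.
_OFFSETS: tuple[Pixel, ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


class NodeKind(str, Enum):
    BRANCHING = "branching"
    TRANSITION = "transition"
    ENDPOINT = "endpoint"


@dataclass(frozen=True)
class SkeletonNode:
    """A typed node of the centerline graph.

    ``pixels`` holds every skeleton pixel absorbed into the node (junction
    clusters may span several pixels); ``position`` is the representative
    pixel nearest the cluster centroid.
    """

    id: int
    position: Pixel
    kind: NodeKind
    pixels: frozenset = field(default_factory=frozenset)


@dataclass
class VesselSegment:
    """A maximal single-class centerline piece between two nodes."""

    id: int
    vessel_class: VesselClass
    polyline: list
    end_nodes: tuple
    complete: bool

    @property
    def n_pixels(self) -> int:
        return len(self.polyline)


@dataclass
class SkeletonGraph:
    nodes: list
    segments: list
    source_mask_id: str = ""
    pixel_size: float = 1.0
    min_spur_length: int = DEFAULT_MIN_SPUR_LENGTH

    def node_by_id(self, node_id: int) -> SkeletonNode:
        return self._node_index()[node_id]

    def _node_index(self) -> dict:
        return {n.id: n for n in self.nodes}

    def incident_segments(self, node_id: int) -> list:
        return [s for s in self.segments if node_id in s.end_nodes]

    def node_counts(self) -> dict:
        counts = {kind: 0 for kind in NodeKind}
        for n in self.nodes:
            counts[n.kind] += 1
        return counts


# ---------------------------------------------------------------------------
# skeletonization and pruning


def skeletonize_mask(mask: LabelMask | np.ndarray) -> np.ndarray:
    """Thin the union of all vessel classes to a unit-width skeleton.

    Uses a topology-preserving 2D thinning; the skeleton is a subset of the
    foreground and keeps its connected-component count. An empty mask gives
    an empty skeleton.
    """
    if isinstance(mask, LabelMask):
        fg = mask.foreground()
    else:
        fg = np.asarray(mask).astype(bool)
    if not fg.any():
        return np.zeros_like(fg, dtype=bool)
    return _skimage_skeletonize(fg)


def _neighbor_degrees(skel: np.ndarray) -> np.ndarray:
    """Number of skeleton pixels in each pixel's 8-neighbourhood."""
    padded = np.pad(skel.astype(np.uint8), 1)
    deg = np.zeros_like(padded, dtype=np.uint8)
    for dr, dc in _OFFSETS:
        deg += np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
    return deg[1:-1, 1:-1] * skel


def _neighbors(p: Pixel, skel_set: set) -> list:
    r, c = p
    return [(r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in skel_set]


def prune_spurs(skel: np.ndarray, min_spur_length: int = DEFAULT_MIN_SPUR_LENGTH) -> np.ndarray:
    """Delete terminal branches shorter than ``min_spur_length`` pixels.

    A terminal branch runs from an endpoint to the first junction pixel
    (exclusive); only branches anchored at a junction are removed, so
    pruning never disconnects the skeleton and never deletes isolated
    paths. Iterates to a fixed point, hence idempotent at fixed threshold.
    A threshold of 0 is the identity.
    """
    if min_spur_length <= 0:
        return skel.copy()
    out = skel.copy()
    changed = True
    while changed:
        changed = False
        skel_set = set(map(tuple, np.argwhere(out)))
        deg = {p: len(_neighbors(p, skel_set)) for p in skel_set}
        endpoints = sorted(p for p, d in deg.items() if d == 1)
        to_remove: set = set()
        for ep in endpoints:
            if ep in to_remove:
                continue
            chain = [ep]
            prev: Pixel | None = None
            cur = ep
            hit_junction = False
            while len(chain) <= min_spur_length:
                nxt = [q for q in _neighbors(cur, skel_set) if q != prev]
                # step away from endpoint; at a junction the branch ends
                if not nxt:
                    break  # isolated path: keep
                if len(nxt) > 1 or deg[nxt[0]] >= 3:
                    # reached (or touched) a junction: chain is the spur
                    hit_junction = True
                    break
                if deg[nxt[0]] == 1:
                    break  # whole component is a bare path: keep
                prev, cur = cur, nxt[0]
                chain.append(cur)
            if hit_junction and len(chain) < min_spur_length:
                to_remove.update(chain)
        if to_remove:
            changed = True
            for r, c in to_remove:
                out[r, c] = False
    return out


def classify_skeleton_pixels(skel: np.ndarray, mask: LabelMask) -> dict:
    """Assign each skeleton pixel the vessel class of the mask underneath.

    Raises on a skeleton pixel over background (internal inconsistency).
    """
    classes: dict = {}
    for r, c in map(tuple, np.argwhere(skel)):
        label = VesselClass(int(mask.grid[r, c]))
        if label == VesselClass.BACKGROUND:
            raise ValueError(f"skeleton pixel (row={r}, col={c}) lies over background")
        classes[(r, c)] = label
    return classes


# ---------------------------------------------------------------------------
# graph construction


def _cluster_representative(cluster: Sequence[Pixel]) -> Pixel:
    """Pixel of the cluster nearest its centroid; lexicographic tiebreak."""
    arr = np.asarray(sorted(cluster), dtype=float)
    centroid = arr.mean(axis=0)
    d2 = ((arr - centroid) ** 2).sum(axis=1)
    best = np.lexsort((arr[:, 1], arr[:, 0], d2))[0]
    r, c = arr[best]
    return (int(r), int(c))


def _junction_clusters(junction_pixels: set) -> list:
    """8-connected components of the junction-pixel set."""
    remaining = set(junction_pixels)
    clusters = []
    while remaining:
        seed = min(remaining)
        stack = [seed]
        comp = {seed}
        remaining.discard(seed)
        while stack:
            p = stack.pop()
            for q in _neighbors(p, remaining):
                remaining.discard(q)
                comp.add(q)
                stack.append(q)
        clusters.append(sorted(comp))
    return clusters


def _segment_class(polyline: Sequence[Pixel], classes: dict, node_pixels: set) -> VesselClass:
    """Class of a segment: the class of its first non-node pixel, falling
    back to the first pixel for node-to-node two-pixel segments."""
    for p in polyline:
        if p not in node_pixels:
            return classes[p]
    return classes[polyline[0]]


def build_graph(
    skel: np.ndarray,
    classes: dict,
    *,
    source_mask_id: str = "",
    pixel_size: float = 1.0,
    min_spur_length: int = DEFAULT_MIN_SPUR_LENGTH,
) -> SkeletonGraph:
    """Convert a classified, pruned skeleton into a typed centerline graph.

    Parameters
    ----------
    skel
        Boolean unit-width skeleton.
    classes
        Mapping pixel -> :class:`VesselClass`, as produced by
        :func:`classify_skeleton_pixels`.

    Notes
    -----
    Isolated single pixels carry no measurable geometry and are dropped.
    """
    skel_set = set(map(tuple, np.argwhere(skel)))
    if skel_set - set(classes):
        raise ValueError("every skeleton pixel needs a class")
    deg = {p: len(_neighbors(p, skel_set)) for p in skel_set}

    junction_pixels = {p for p, d in deg.items() if d >= 3}
    endpoint_pixels = sorted(p for p, d in deg.items() if d == 1)
    corridor_pixels = {p for p, d in deg.items() if d == 2} - junction_pixels

    nodes: list = []
    pixel_to_node: dict = {}

    def _add_node(position: Pixel, kind: NodeKind, pixels: Iterable[Pixel]) -> int:
        node_id = len(nodes)
        pix = frozenset(pixels)
        nodes.append(SkeletonNode(id=node_id, position=position, kind=kind, pixels=pix))
        for p in pix:
            pixel_to_node[p] = node_id
        return node_id

    for cluster in _junction_clusters(junction_pixels):
        _add_node(_cluster_representative(cluster), NodeKind.BRANCHING, cluster)
    for p in endpoint_pixels:
        _add_node(p, NodeKind.ENDPOINT, [p])

    # --- walk corridors between node pixels -------------------------------
    raw_polylines: list = []
    used: set = set()
    direct_seen: set = set()
    for p in sorted(pixel_to_node):
        for q in _neighbors(p, skel_set):
            if q in corridor_pixels and q not in used:
                poly = [p, q]
                used.add(q)
                prev, cur = p, q
                while cur in corridor_pixels:
                    nxt = [x for x in _neighbors(cur, skel_set) if x != prev]
                    if not nxt:  # dead corridor end (cannot occur on valid input)
                        break
                    step = nxt[0]
                    poly.append(step)
                    prev, cur = cur, step
                    if cur in corridor_pixels:
                        used.add(cur)
                raw_polylines.append(poly)
            elif q in pixel_to_node and pixel_to_node[q] != pixel_to_node[p]:
                key = (min(p, q), max(p, q))
                if key not in direct_seen:
                    direct_seen.add(key)
                    raw_polylines.append([p, q])

    # --- pure cycles with no nodes ----------------------------------------
    leftover = corridor_pixels - used
    while leftover:
        anchor = min(leftover)
        node_id = _add_node(anchor, NodeKind.BRANCHING, [anchor])
        nbrs = sorted(_neighbors(anchor, leftover))
        poly = [anchor]
        prev, cur = anchor, nbrs[0]
        leftover.discard(anchor)
        while cur != anchor:
            poly.append(cur)
            leftover.discard(cur)
            nxt = [x for x in _neighbors(cur, skel_set) if x != prev and (x in leftover or x == anchor)]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        poly.append(anchor)
        raw_polylines.append(poly)

    # --- split polylines at class transitions -----------------------------
    pieces: list = []  # (polyline, start_node_id_or_None, end_node_id_or_None)
    transition_nodes_at: dict = {}

    def _transition_node(pixel: Pixel) -> int:
        if pixel not in transition_nodes_at:
            node_id = _add_node(pixel, NodeKind.TRANSITION, [pixel])
            transition_nodes_at[pixel] = node_id
        return transition_nodes_at[pixel]

    for poly in raw_polylines:
        cuts = [
            i
            for i in range(1, len(poly) - 1)
            if classes[poly[i]] != classes[poly[i - 1]]
        ]
        bounds = [0] + cuts + [len(poly) - 1]
        for a, b in zip(bounds[:-1], bounds[1:]):
            piece = poly[a : b + 1]
            start_id = pixel_to_node.get(piece[0])
            if start_id is None:
                start_id = _transition_node(piece[0])
            end_id = pixel_to_node.get(piece[-1])
            if end_id is None:
                end_id = _transition_node(piece[-1])
            pieces.append((piece, start_id, end_id))

    # transition pixels are node pixels too: segment class is read from
    # non-node pixels (falling back to the first pixel for 2-pixel pieces)
    node_pixel_set = set(pixel_to_node)

    # --- demote/dissolve degenerate junction clusters ---------------------
    # Thinning can leave a junction cluster touched by only 2 segments.
    incident: dict = {n.id: [] for n in nodes}
    for idx, (piece, a, b) in enumerate(pieces):
        incident[a].append(idx)
        if b != a:
            incident[b].append(idx)
        elif len(piece) > 2:  # self-loop touches its node twice
            incident[a].append(idx)

    demoted: dict = {}
    for n in list(nodes):
        if n.kind is NodeKind.BRANCHING and len(incident[n.id]) == 2 and len(set(incident[n.id])) == 2:
            i1, i2 = incident[n.id]
            if pieces[i1] is None or pieces[i2] is None:
                continue
            p1, a1, b1 = pieces[i1]
            p2, a2, b2 = pieces[i2]
            cls1 = _segment_class(p1, classes, node_pixel_set)
            cls2 = _segment_class(p2, classes, node_pixel_set)
            if cls1 != cls2:
                demoted[n.id] = NodeKind.TRANSITION
            else:
                # splice the two pieces through the cluster into one
                q1 = p1 if b1 == n.id else p1[::-1]
                q2 = p2 if a2 == n.id else p2[::-1]
                far1 = a1 if b1 == n.id else b1
                far2 = b2 if a2 == n.id else a2
                if q1[-1] == q2[0]:
                    merged = q1 + q2[1:]
                else:
                    bridge = _bridge_through_cluster(q1[-1], q2[0], n.pixels, skel_set)
                    merged = q1 + bridge + q2
                pieces[i1] = (merged, far1, far2)
                pieces[i2] = None  # type: ignore[assignment]
                demoted[n.id] = None
    if demoted:
        pieces = [pc for pc in pieces if pc is not None]
        keep = []
        for n in nodes:
            if n.id in demoted:
                if demoted[n.id] is None:
                    continue
                n = SkeletonNode(id=n.id, position=n.position, kind=demoted[n.id], pixels=n.pixels)
            keep.append(n)
        nodes = keep

    node_kind = {n.id: n.kind for n in nodes}
    segments: list = []
    for piece, a, b in pieces:
        complete = (
            node_kind.get(a) in (NodeKind.BRANCHING, NodeKind.TRANSITION)
            and node_kind.get(b) in (NodeKind.BRANCHING, NodeKind.TRANSITION)
        )
        segments.append(
            VesselSegment(
                id=len(segments),
                vessel_class=_segment_class(piece, classes, node_pixel_set),
                polyline=list(piece),
                end_nodes=(a, b),
                complete=complete,
            )
        )

    return SkeletonGraph(
        nodes=nodes,
        segments=segments,
        source_mask_id=source_mask_id,
        pixel_size=pixel_size,
        min_spur_length=min_spur_length,
    )


def _bridge_through_cluster(
    start: Pixel, goal: Pixel, cluster: frozenset, skel_set: set
) -> list:
    """Shortest 8-connected pixel path across a junction cluster (exclusive
    of start/goal), used when dissolving a degenerate 2-incident cluster."""
    if goal in _set8(start):
        return []
    from collections import deque

    allowed = set(cluster)
    queue = deque([(start, [])])
    seen = {start}
    while queue:
        p, path = queue.popleft()
        for q in sorted(_set8(p)):
            if q == goal:
                return path + []
            if q in allowed and q not in seen:
                seen.add(q)
                queue.append((q, path + [q]))
    raise ValueError("cluster pixels do not connect the two segments")


def _set8(p: Pixel) -> set:
    r, c = p
    return {(r + dr, c + dc) for dr, dc in _OFFSETS}


def graph_to_json_dict(graph: SkeletonGraph) -> dict:
    """JSON-serialisable export: nodes and segments with polylines."""
    return {
        "source_mask_id": graph.source_mask_id,
        "pixel_size": graph.pixel_size,
        "min_spur_length": graph.min_spur_length,
        "nodes": [
            {
                "id": n.id,
                "position": [int(n.position[0]), int(n.position[1])],
                "kind": n.kind.value,
                "pixels": sorted([int(r), int(c)] for r, c in n.pixels),
            }
            for n in graph.nodes
        ],
        "segments": [
            {
                "id": s.id,
                "vessel_class": s.vessel_class.name,
                "complete": bool(s.complete),
                "end_nodes": [int(s.end_nodes[0]), int(s.end_nodes[1])],
                "polyline": [[int(r), int(c)] for r, c in s.polyline],
            }
            for s in graph.segments
        ],
    }


def extract_graph(
    mask: LabelMask, min_spur_length: int = DEFAULT_MIN_SPUR_LENGTH
) -> SkeletonGraph:
    """Full pipeline: thin, prune, classify and build the centerline graph."""
    skel = skeletonize_mask(mask)
    skel = prune_spurs(skel, min_spur_length)
    classes = classify_skeleton_pixels(skel, mask)
    return build_graph(
        skel,
        classes,
        source_mask_id=mask.image_id,
        pixel_size=mask.pixel_size,
        min_spur_length=min_spur_length,
    )
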