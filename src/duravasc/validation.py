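"""Independent brute-force reference computations for verification.

This module re-derives the centerline-graph decomposition by exhaustive
enumeration on the pixel grid, using networkx set/graph primitives
instead of the production corridor-walking code, so the two routes share
no implementation. Both routes implement the same documented
conventions (8-connectivity, junction-cluster merging at the
centroid-nearest pixel, transition placement at the first pixel of the
new class, offset-scan and row-major tie-breaks), which is what makes
their outputs comparable pixel for pixel.

Intended for tests and acceptance checking on small inputs; the
enumeration is quadratic-ish and not meant for full-size fields.
"""

from __future__ import annotations

from collections import deque
from typing import Mapping

import networkx as nx
import numpy as np

from .image_io import VesselClass
from .skeleton_graph import NodeKind, SkeletonGraph

__all__ = ["graph_summary", "brute_force_graph_summary"]

Pixel = tuple[int, int]

_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def _canon_poly(poly) -> tuple:
    fwd = tuple(poly)
    rev = tuple(reversed(poly))
    return min(fwd, rev)


def graph_summary(graph: SkeletonGraph) -> dict:
    """Canonical, id-free summary of a SkeletonGraph for comparison."""
    nodes = sorted((n.position, n.kind.value) for n in graph.nodes)
    segments = sorted(
        (s.vessel_class.name, _canon_poly(s.polyline), bool(s.complete))
        for s in graph.segments
    )
    return {"nodes": nodes, "segments": segments}


def _offset_order(p: Pixel, candidates) -> list:
    """Sort candidate neighbours of ``p`` by the fixed offset scan order."""
    rank = {(p[0] + dr, p[1] + dc): i for i, (dr, dc) in enumerate(_OFFSETS)}
    return sorted(candidates, key=lambda q: rank[q])


def brute_force_graph_summary(skel: np.ndarray, classes: Mapping) -> dict:
    """Exhaustively enumerate nodes and segments of a skeleton.

    Returns the same canonical summary structure as :func:`graph_summary`
    computed by an independent route: a networkx pixel-adjacency graph,
    component analysis for junction clusters and corridors, and path
    reconstruction by graph search.
    """
    pixels = sorted(map(tuple, np.argwhere(skel)))
    pixel_set = set(pixels)
    G = nx.Graph()
    G.add_nodes_from(pixels)
    for r, c in pixels:
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            q = (r + dr, c + dc)
            if q in pixel_set:
                G.add_edge((r, c), q)
    deg = dict(G.degree())

    junction = {p for p in pixels if deg[p] >= 3}
    endpoints = [p for p in pixels if deg[p] == 1]
    # isolated single pixels carry no geometry: dropped, as in production
    node_of: dict = {}
    node_info: list = []  # (rep_position, kind, set_of_pixels)

    def _register(rep: Pixel, kind: NodeKind, pix: set) -> int:
        idx = len(node_info)
        node_info.append([rep, kind, set(pix)])
        for p in pix:
            node_of[p] = idx
        return idx

    for comp in sorted(nx.connected_components(G.subgraph(junction)), key=min):
        arr = np.asarray(sorted(comp), dtype=float)
        centroid = arr.mean(axis=0)
        d2 = ((arr - centroid) ** 2).sum(axis=1)
        best = np.lexsort((arr[:, 1], arr[:, 0], d2))[0]
        rep = (int(arr[best][0]), int(arr[best][1]))
        _register(rep, NodeKind.BRANCHING, comp)
    for p in endpoints:
        _register(p, NodeKind.ENDPOINT, {p})

    node_pixels = set(node_of)
    corridor = pixel_set - node_pixels - {p for p in pixels if deg[p] == 0}

    # --- corridors: connected components of the graph minus node pixels ---
    polylines: list = []
    H = G.subgraph(corridor)
    for comp in sorted(nx.connected_components(H), key=min):
        comp = set(comp)
        sub = H.subgraph(comp)
        internal_ends = sorted(p for p in comp if sub.degree(p) <= 1)
        attachments = {
            p: sorted(q for q in G.neighbors(p) if q in node_pixels)
            for p in internal_ends
        }
        att_any = [q for ats in attachments.values() for q in ats]
        if not att_any:
            # pure cycle: artificial anchor at the smallest pixel
            anchor = min(comp)
            _register(anchor, NodeKind.BRANCHING, {anchor})
            ring = comp - {anchor}
            first = min(q for q in G.neighbors(anchor) if q in ring)
            order = [anchor, first]
            prev, cur = anchor, first
            while True:
                nxts = [q for q in G.neighbors(cur) if q != prev and (q in ring or q == anchor)]
                step = nxts[0]
                order.append(step)
                if step == anchor:
                    break
                prev, cur = cur, step
            polylines.append(order)
            continue
        if len(comp) == 1:
            q = internal_ends[0]
            atts = attachments[q]
            start = min(atts)
            others = [a for a in atts if a != start] or [start]
            end = _offset_order(q, others)[0] if len(atts) > 2 else others[0]
            polylines.append([start, q, end])
            continue
        e1, e2 = internal_ends[0], internal_ends[1]
        a1, a2 = attachments[e1][0], attachments[e2][0]
        body = nx.shortest_path(sub, e1, e2)
        if a1 == a2:
            # loop attached to one node pixel: enter by offset order at a1
            q_first = _offset_order(a1, [e1, e2])[0]
            if q_first == e2:
                body = body[::-1]
        elif a2 < a1:
            body, a1, a2 = body[::-1], a2, a1
        polylines.append([a1] + body + [a2])

    # --- direct node-to-node adjacencies ---
    for p, q in sorted(G.edges()):
        if p in node_pixels and q in node_pixels and node_of[p] != node_of[q]:
            polylines.append(sorted([p, q]))

    # --- split at class transitions ---
    node_pixel_set = set(node_of)
    transition_at: dict = {}

    def _trans(pixel: Pixel) -> int:
        if pixel not in transition_at:
            transition_at[pixel] = _register(pixel, NodeKind.TRANSITION, {pixel})
        return transition_at[pixel]

    pieces: list = []
    for poly in polylines:
        cuts = [i for i in range(1, len(poly) - 1) if classes[poly[i]] != classes[poly[i - 1]]]
        bounds = [0] + cuts + [len(poly) - 1]
        for a, b in zip(bounds[:-1], bounds[1:]):
            piece = poly[a : b + 1]
            sid = node_of.get(piece[0])
            if sid is None:
                sid = _trans(piece[0])
            eid = node_of.get(piece[-1])
            if eid is None:
                eid = _trans(piece[-1])
            pieces.append([piece, sid, eid])

    def _piece_class(piece) -> VesselClass:
        for p in piece:
            if p not in node_pixel_set and p not in transition_at:
                return classes[p]
        return classes[piece[0]]

    # --- demote / dissolve 2-incident junction clusters ---
    incident: dict = {i: [] for i in range(len(node_info))}
    for idx, (piece, a, b) in enumerate(pieces):
        incident[a].append(idx)
        if b != a:
            incident[b].append(idx)
        elif len(piece) > 2:
            incident[a].append(idx)

    removed_nodes: set = set()
    for nid, info in enumerate(node_info):
        rep, kind, pix = info
        if kind is not NodeKind.BRANCHING or len(incident[nid]) != 2:
            continue
        if len(set(incident[nid])) != 2:
            continue
        i1, i2 = incident[nid]
        if pieces[i1] is None or pieces[i2] is None:
            continue
        p1, a1, b1 = pieces[i1]
        p2, a2, b2 = pieces[i2]
        if _piece_class(p1) != _piece_class(p2):
            node_info[nid][1] = NodeKind.TRANSITION
            continue
        q1 = p1 if b1 == nid else p1[::-1]
        q2 = p2 if a2 == nid else p2[::-1]
        far1 = a1 if b1 == nid else b1
        far2 = b2 if a2 == nid else a2
        if q1[-1] == q2[0]:
            merged = q1 + q2[1:]
        else:
            merged = q1 + _bfs_bridge(q1[-1], q2[0], pix) + q2
        pieces[i1] = [merged, far1, far2]
        pieces[i2] = None
        removed_nodes.add(nid)
    pieces = [pc for pc in pieces if pc is not None]

    kind_of = {
        nid: info[1] for nid, info in enumerate(node_info) if nid not in removed_nodes
    }
    segments = []
    for piece, a, b in pieces:
        complete = kind_of.get(a) in (NodeKind.BRANCHING, NodeKind.TRANSITION) and kind_of.get(
            b
        ) in (NodeKind.BRANCHING, NodeKind.TRANSITION)
        segments.append((_piece_class(piece).name, _canon_poly(piece), complete))
    nodes = sorted(
        (node_info[nid][0], kind_of[nid].value) for nid in kind_of
    )
    return {"nodes": nodes, "segments": sorted(segments)}


def _bfs_bridge(start: Pixel, goal: Pixel, cluster: set) -> list:
    """Deterministic BFS (sorted expansion) across a junction cluster."""
    if goal in {(start[0] + dr, start[1] + dc) for dr, dc in _OFFSETS}:
        return []
    queue = deque([(start, [])])
    seen = {start}
    while queue:
        p, path = queue.popleft()
        for dr, dc in sorted(_OFFSETS):
            q = (p[0] + dr, p[1] + dc)
            if q == goal:
                return path
            if q in cluster and q not in seen:
                seen.add(q)
                queue.append((q, path + [q]))
    raise ValueError("cluster does not bridge the two segments")
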