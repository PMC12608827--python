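"""Optional QC figures (requires matplotlib, not a core dependency)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .image_io import BLOOD_PALETTE, LabelMask, labels_to_rgb
from .skeleton_graph import NodeKind, SkeletonGraph

__all__ = ["save_graph_overlay", "save_comparison_barplot"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def save_graph_overlay(mask: LabelMask, graph: SkeletonGraph, path: str | Path) -> Path:
    """Mask with centerline segments drawn as lines and nodes as dots."""
    plt = _mpl()
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(labels_to_rgb(mask.grid, BLOOD_PALETTE))
    for seg in graph.segments:
        poly = np.asarray(seg.polyline)
        style = "-" if seg.complete else ":"
        ax.plot(poly[:, 1], poly[:, 0], style, color="0.8", linewidth=1)
    for node in graph.nodes:
        colour = {"branching": "yellow", "transition": "cyan", "endpoint": "0.5"}[
            node.kind.value
        ]
        ax.plot(node.position[1], node.position[0], "o", color=colour, markersize=3)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def save_comparison_barplot(comparisons: Sequence, path: str | Path) -> Path:
    """Group means ± SEM per metric, annotated with p-values."""
    plt = _mpl()
    path = Path(path)
    n = len(comparisons)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(3 * max(n, 1), 3.2), squeeze=False)
    for ax, cmp in zip(axes[0], comparisons):
        ax.bar([0, 1], [cmp.mean_a, cmp.mean_b],
               yerr=[cmp.sem_a, cmp.sem_b], color=["0.6", "0.3"], capsize=4)
        ax.set_xticks([0, 1], [cmp.group_a, cmp.group_b])
        ax.set_title(f"{cmp.metric}\np = {cmp.p_value:.3g}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
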