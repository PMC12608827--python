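"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from duravasc.image_io import LabelMask, VesselClass

#: ascii -> label for compact mask/skeleton literals in tests
CHAR_TO_LABEL = {
    ".": VesselClass.BACKGROUND,
    "A": VesselClass.ARTERIOLE,
    "V": VesselClass.VENULE,
    "U": VesselClass.UNDETERMINED,
    "L": VesselClass.LYMPHATIC,
}


def mask_from_ascii(art: str, **kwargs) -> LabelMask:
    """Build a LabelMask from an ascii-art block (see CHAR_TO_LABEL)."""
    rows = [line.strip() for line in art.strip().splitlines()]
    grid = np.array(
        [[int(CHAR_TO_LABEL[ch]) for ch in row] for row in rows], dtype=np.uint8
    )
    return LabelMask(grid=grid, **kwargs)


def skeleton_from_ascii(art: str) -> tuple[np.ndarray, dict]:
    """Boolean skeleton + per-pixel class dict from ascii art.

    Non-'.' characters are skeleton pixels carrying the indicated class.
    """
    rows = [line.strip() for line in art.strip().splitlines()]
    h, w = len(rows), len(rows[0])
    skel = np.zeros((h, w), dtype=bool)
    classes: dict = {}
    for r, row in enumerate(rows):
        for c, ch in enumerate(row):
            if ch != ".":
                skel[r, c] = True
                classes[(r, c)] = CHAR_TO_LABEL[ch]
    return skel, classes


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_label_mask(rng: np.random.Generator, size: int = 12, p_fg: float = 0.35) -> LabelMask:
    """Random small label mask with arteriole/venule/undetermined blobs."""
    fg = rng.random((size, size)) < p_fg
    labels = rng.integers(1, 4, size=(size, size)).astype(np.uint8)
    return LabelMask(grid=np.where(fg, labels, 0).astype(np.uint8))
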