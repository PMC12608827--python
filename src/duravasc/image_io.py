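"""Reading, writing and projecting annotated vascular images.

The unit of annotation is a :class:`LabelMask`: a 2D grid in which every
pixel carries one vessel-class label (arteriole, venule, undetermined
region, or background; lymphatic masks use a single LYMPHATIC class).
Masks travel as RGB PNG files with a fixed exact-match palette
(red = arteriole, green = venule, blue = undetermined, black = background,
white = lymphatic) plus an optional JSON sidecar holding pixel size and
animal/group metadata.

Fluorescence data travels as multi-page TIFF (one page per channel, or
plane-major channel-interleaved pages for a z-stack) with a JSON sidecar
naming the channels. Z-stacks are fused to a single 2D field by per-pixel
maximum-intensity projection.

Conventions: 0-based (row, col) indexing, origin at the top-left,
row-major storage. Pixel size is micrometres per pixel and defaults to
1.0, in which case all downstream lengths are in pixel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "VesselClass",
    "BLOOD_PALETTE",
    "LYMPHATIC_PALETTE",
    "LabelMask",
    "MultiChannelImage",
    "ZStack",
    "OffPaletteError",
    "read_label_mask",
    "write_label_mask",
    "read_multichannel",
    "write_multichannel",
    "read_zstack",
    "write_zstack",
    "max_project",
]


class VesselClass(IntEnum):
    """Vessel-class labels used throughout the pipeline."""

    BACKGROUND = 0
    ARTERIOLE = 1
    VENULE = 2
    UNDETERMINED = 3
    LYMPHATIC = 4


#: Palette for blood-vessel masks: red arterioles, green venules, blue
#: undetermined regions on a black background.
BLOOD_PALETTE: dict[VesselClass, tuple[int, int, int]] = {
    VesselClass.BACKGROUND: (0, 0, 0),
    VesselClass.ARTERIOLE: (255, 0, 0),
    VesselClass.VENULE: (0, 255, 0),
    VesselClass.UNDETERMINED: (0, 0, 255),
}

#: Palette for lymphatic masks: white vessels on black.
LYMPHATIC_PALETTE: dict[VesselClass, tuple[int, int, int]] = {
    VesselClass.BACKGROUND: (0, 0, 0),
    VesselClass.LYMPHATIC: (255, 255, 255),
}

#: Channel names recognised in multi-channel fluorescence images.
CHANNEL_NAMES = ("vessel", "asma", "pdpl")


class OffPaletteError(ValueError):
    """A mask pixel's colour is not in the palette (reports where and what)."""


def _as_label_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError(f"label grid must be 2D, got shape {grid.shape}")
    if grid.shape[0] < 1 or grid.shape[1] < 1:
        raise ValueError("label grid must be at least 1x1")
    valid = np.isin(grid, [int(c) for c in VesselClass])
    if not bool(valid.all()):
        bad = np.argwhere(~valid)[0]
        raise ValueError(
            f"invalid label {grid[tuple(bad)]} at (row={bad[0]}, col={bad[1]})"
        )
    return grid.astype(np.uint8)


@dataclass
class LabelMask:
    """2D grid of vessel-class labels with pixel-size and cohort metadata.

    Parameters
    ----------
    grid
        2D uint8 array of :class:`VesselClass` values.
    pixel_size
        Micrometres per pixel; 1.0 means downstream metrics are in pixels.
    image_id, animal_id, group
        Free-form identifiers used for per-animal aggregation.
    """

    grid: np.ndarray
    pixel_size: float = 1.0
    image_id: str = ""
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.grid = _as_label_grid(self.grid)
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def height(self) -> int:
        return int(self.grid.shape[0])

    @property
    def width(self) -> int:
        return int(self.grid.shape[1])

    def foreground(self) -> np.ndarray:
        """Boolean mask of all non-background pixels."""
        return self.grid != VesselClass.BACKGROUND

    def class_mask(self, vessel_class: VesselClass) -> np.ndarray:
        return self.grid == vessel_class

    def copy(self) -> "LabelMask":
        return replace(self, grid=self.grid.copy())


@dataclass
class MultiChannelImage:
    """Named set of co-registered non-negative 2D intensity channels."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    image_id: str = ""
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        ref = next(iter(shapes.values()))
        if len(ref) != 2:
            raise ValueError(f"channels must be 2D, got shape {ref}")
        for name, shape in shapes.items():
            if shape != ref:
                raise ValueError(
                    f"channel {name!r} shape {shape} differs from {ref}"
                )
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=np.float64)
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)


@dataclass
class ZStack:
    """Ordered confocal planes sharing shape and channel names."""

    planes: list[MultiChannelImage]
    plane_spacing: float = 1.0

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise ValueError("a z-stack needs at least one plane")
        ref = self.planes[0]
        for i, plane in enumerate(self.planes):
            if plane.shape != ref.shape:
                raise ValueError(f"plane {i} shape {plane.shape} != {ref.shape}")
            if set(plane.channel_names) != set(ref.channel_names):
                raise ValueError(f"plane {i} channel names differ")
        if not self.plane_spacing > 0:
            raise ValueError("plane_spacing must be > 0")


def max_project(stack: ZStack) -> MultiChannelImage:
    """Fuse a z-stack into one 2D field by per-pixel maximum projection.

    Each output channel pixel is the maximum of that pixel over all planes.
    Metadata is inherited from the first plane.
    """
    first = stack.planes[0]
    projected = {
        name: np.maximum.reduce([p.channels[name] for p in stack.planes])
        for name in first.channel_names
    }
    return MultiChannelImage(
        channels=projected,
        pixel_size=first.pixel_size,
        image_id=first.image_id,
        animal_id=first.animal_id,
        group=first.group,
    )


# ---------------------------------------------------------------------------
# label-mask PNG I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def labels_to_rgb(
    grid: np.ndarray, palette: Mapping[VesselClass, tuple[int, int, int]]
) -> np.ndarray:
    """Render a label grid as an RGB uint8 image using an exact palette."""
    rgb = np.zeros(grid.shape + (3,), dtype=np.uint8)
    for label, colour in palette.items():
        rgb[grid == label] = colour
    return rgb


def rgb_to_labels(
    rgb: np.ndarray, palette: Mapping[VesselClass, tuple[int, int, int]]
) -> np.ndarray:
    """Map an RGB image to labels; any off-palette pixel is an error."""
    grid = np.full(rgb.shape[:2], -1, dtype=np.int16)
    for label, colour in palette.items():
        match = np.all(rgb == np.asarray(colour, dtype=rgb.dtype), axis=-1)
        grid[match] = int(label)
    unmatched = grid < 0
    if bool(unmatched.any()):
        r, c = np.argwhere(unmatched)[0]
        raise OffPaletteError(
            f"pixel (row={r}, col={c}) has colour {tuple(int(v) for v in rgb[r, c])}"
            " which is not in the palette"
        )
    return grid.astype(np.uint8)


def read_label_mask(
    path: str | Path,
    palette: Mapping[VesselClass, tuple[int, int, int]] = BLOOD_PALETTE,
) -> LabelMask:
    """Read an RGB PNG mask, mapping colours to labels by exact match.

    If ``<path>.json`` exists next to the image it supplies pixel_size and
    identifiers; otherwise defaults apply.
    """
    path = Path(path)
    rgb = iio.imread(path)
    if rgb.ndim == 3 and rgb.shape[-1] == 4:  # drop alpha if fully opaque
        rgb = rgb[..., :3]
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"{path} is not an RGB image (shape {rgb.shape})")
    grid = rgb_to_labels(rgb, palette)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return LabelMask(
        grid=grid,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        image_id=str(meta.get("image_id", path.stem)),
        animal_id=str(meta.get("animal_id", "")),
        group=str(meta.get("group", "")),
    )


def write_label_mask(
    mask: LabelMask,
    path: str | Path,
    palette: Mapping[VesselClass, tuple[int, int, int]] = BLOOD_PALETTE,
) -> Path:
    """Write a mask as an RGB PNG plus a JSON metadata sidecar.

    Round-trips bit-exactly: ``read_label_mask(write_label_mask(m))`` equals
    ``m`` in grid and metadata.
    """
    path = Path(path)
    present = set(np.unique(mask.grid))
    allowed = {int(label) for label in palette}
    missing = present - allowed
    if missing:
        raise ValueError(f"mask labels {sorted(missing)} not representable in palette")
    iio.imwrite(path, labels_to_rgb(mask.grid, palette))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "pixel_size": mask.pixel_size,
                "image_id": mask.image_id,
                "animal_id": mask.animal_id,
                "group": mask.group,
            },
            indent=2,
        )
    )
    return path


# ---------------------------------------------------------------------------
# multi-channel TIFF I/O


def write_multichannel(image: MultiChannelImage, path: str | Path) -> Path:
    """Write channels as a multi-page TIFF (one page per channel) + sidecar."""
    path = Path(path)
    names = list(image.channel_names)
    pages = np.stack([image.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, pages, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "channels": names,
                "pixel_size": image.pixel_size,
                "image_id": image.image_id,
                "animal_id": image.animal_id,
                "group": image.group,
            },
            indent=2,
        )
    )
    return path


def read_multichannel(path: str | Path) -> MultiChannelImage:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta = json.loads(_sidecar_path(path).read_text())
    names = meta["channels"]
    if len(names) != pages.shape[0]:
        raise ValueError(
            f"{path}: sidecar names {len(names)} channels, file has {pages.shape[0]} pages"
        )
    return MultiChannelImage(
        channels={n: pages[i].astype(np.float64) for i, n in enumerate(names)},
        pixel_size=float(meta.get("pixel_size", 1.0)),
        image_id=str(meta.get("image_id", path.stem)),
        animal_id=str(meta.get("animal_id", "")),
        group=str(meta.get("group", "")),
    )


def write_zstack(stack: ZStack, path: str | Path) -> Path:
    """Write a z-stack as channel-interleaved TIFF pages (plane-major)."""
    path = Path(path)
    first = stack.planes[0]
    names = list(first.channel_names)
    pages = np.stack(
        [p.channels[n].astype(np.float32) for p in stack.planes for n in names]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "channels": names,
                "n_planes": len(stack.planes),
                "plane_spacing": stack.plane_spacing,
                "pixel_size": first.pixel_size,
                "image_id": first.image_id,
                "animal_id": first.animal_id,
                "group": first.group,
            },
            indent=2,
        )
    )
    return path


def read_zstack(path: str | Path) -> ZStack:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta = json.loads(_sidecar_path(path).read_text())
    names = meta["channels"]
    n_planes = int(meta["n_planes"])
    if pages.shape[0] != n_planes * len(names):
        raise ValueError(
            f"{path}: expected {n_planes * len(names)} pages, found {pages.shape[0]}"
        )
    planes = []
    for i in range(n_planes):
        block = pages[i * len(names) : (i + 1) * len(names)]
        planes.append(
            MultiChannelImage(
                channels={n: block[j].astype(np.float64) for j, n in enumerate(names)},
                pixel_size=float(meta.get("pixel_size", 1.0)),
                image_id=str(meta.get("image_id", path.stem)),
                animal_id=str(meta.get("animal_id", "")),
                group=str(meta.get("group", "")),
            )
        )
    return ZStack(planes=planes, plane_spacing=float(meta.get("plane_spacing", 1.0)))
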