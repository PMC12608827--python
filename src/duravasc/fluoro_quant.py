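"""Fluorescence quantification: mural-cell coverage and lymphatic measures.

Vessel smooth-muscle investment is indexed by the alpha-smooth-muscle
actin (α-SMA) signal over the blood-vessel area: the coverage ratio is
summed α-SMA intensity inside the vessel mask divided by the vessel
pixel count. Stromal α-SMA is the remainder — total image signal minus
the vessel-associated signal — so vessel + stromal = total holds exactly
by construction.

Lymphatic remodeling near the coronal suture is measured as the fraction
of image area covered by podoplanin-positive (PDPL+) lymphatic vessels,
plus a count of PDPL+ cell puncta lying outside the lymphatic vessel
mask (candidate lymphatic endothelial progenitors). Cell detection is a
declared automated substitute: intensity threshold (Otsu by default),
connected components, an area gate, and exclusion of components that
touch the vessel mask.

Vessel segmentation from an intensity channel is a deterministic
classical pipeline (Gaussian smoothing, Otsu or fixed threshold, small
object removal); externally produced masks are accepted everywhere a
mask is an input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects

from .image_io import LabelMask, VesselClass
from .morphometry import segment_statistics
from .skeleton_graph import extract_graph

__all__ = [
    "FluoroQuantRecord",
    "segment_vessels_classical",
    "asma_coverage",
    "stromal_asma",
    "pdpl_vessel_fraction",
    "count_pdpl_cells",
    "lymphatic_morphometry",
    "quantify_image",
]

#: Default area gate (pixels) for PDPL+ cell puncta.
DEFAULT_CELL_AREA_RANGE = (10, 400)


@dataclass
class FluoroQuantRecord:
    """One image's fluorescence-derived measures."""

    image_id: str
    animal_id: str
    group: str
    vessel_area: int
    asma_vessel_signal: float
    asma_coverage_ratio: float | None
    asma_stromal_signal: float
    pdpl_vessel_fraction: float | None
    pdpl_cell_count: int | None
    lymphatic_mean_segment_length: float | None = None
    degenerate_segmentation: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def segment_vessels_classical(
    channel: np.ndarray,
    smoothing_scale: float = 2.0,
    threshold_rule: str | float = "otsu",
    min_object_px: int = 25,
) -> tuple[np.ndarray, bool]:
    """Threshold-based vessel segmentation of an intensity channel.

    Gaussian-smooths at ``smoothing_scale`` (px), thresholds (``"otsu"``
    maximises between-class variance; a float is a fixed cutoff on the
    smoothed image), and drops objects smaller than ``min_object_px``.
    Deterministic for fixed inputs.

    Returns
    -------
    mask, degenerate
        Boolean vessel mask and a flag set when auto-thresholding was
        impossible (constant image), in which case the mask is empty.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if np.any(channel < 0):
        raise ValueError("intensity channel must be non-negative")
    smoothed = gaussian(channel, sigma=smoothing_scale, preserve_range=True)
    if isinstance(threshold_rule, str):
        if threshold_rule != "otsu":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        if np.ptp(smoothed) == 0:
            return np.zeros(channel.shape, dtype=bool), True
        thresh = threshold_otsu(smoothed)
    else:
        thresh = float(threshold_rule)
    mask = smoothed > thresh
    if min_object_px > 1:
        # objects strictly smaller than min_object_px are removed
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return mask, False


def asma_coverage(
    asma_channel: np.ndarray,
    vessel_mask: np.ndarray,
    signal_mode: str = "sum",
    area_threshold: float | None = None,
) -> tuple[int, float, float | None]:
    """Vessel area, vessel-associated α-SMA signal, and coverage ratio.

    ``ratio = signal / area``; an empty vessel mask yields ``None`` for
    the ratio (flagged missing, not zero). The default ``signal_mode``
    ``"sum"`` reads "signal" as summed intensity, which keeps
    vessel + stromal = total exact; the ``"thresholded_area"`` variant
    instead counts vessel pixels whose intensity exceeds
    ``area_threshold`` (Otsu on the channel when ``None``).
    """
    asma_channel = np.asarray(asma_channel, dtype=np.float64)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if asma_channel.shape != vessel_mask.shape:
        raise ValueError(
            f"shape mismatch: channel {asma_channel.shape} vs mask {vessel_mask.shape}"
        )
    area = int(np.count_nonzero(vessel_mask))
    if signal_mode == "sum":
        signal = float(asma_channel[vessel_mask].sum())
    elif signal_mode == "thresholded_area":
        if area_threshold is None:
            if np.ptp(asma_channel) == 0:
                return area, 0.0, (0.0 if area else None)
            area_threshold = float(threshold_otsu(asma_channel))
        signal = float(np.count_nonzero(asma_channel[vessel_mask] > area_threshold))
    else:
        raise ValueError(f"unknown signal_mode {signal_mode!r}")
    ratio = signal / area if area > 0 else None
    return area, signal, ratio


def stromal_asma(asma_channel: np.ndarray, vessel_mask: np.ndarray) -> float:
    """Non-vessel α-SMA: total image signal minus vessel-associated signal."""
    asma_channel = np.asarray(asma_channel, dtype=np.float64)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if asma_channel.shape != vessel_mask.shape:
        raise ValueError(
            f"shape mismatch: channel {asma_channel.shape} vs mask {vessel_mask.shape}"
        )
    return float(asma_channel.sum() - asma_channel[vessel_mask].sum())


def pdpl_vessel_fraction(lymph_mask: LabelMask | np.ndarray) -> float:
    """Fraction of image area covered by PDPL+ lymphatic vessels."""
    if isinstance(lymph_mask, LabelMask):
        fg = lymph_mask.class_mask(VesselClass.LYMPHATIC)
        total = lymph_mask.grid.size
    else:
        fg = np.asarray(lymph_mask, dtype=bool)
        total = fg.size
    return float(np.count_nonzero(fg)) / total


def count_pdpl_cells(
    pdpl_channel: np.ndarray,
    lymph_mask: LabelMask | np.ndarray,
    intensity_threshold: float | None = None,
    area_range: tuple[int, int] = DEFAULT_CELL_AREA_RANGE,
) -> int:
    """Count PDPL+ cell puncta outside the lymphatic vessel mask.

    Components of the thresholded PDPL channel are counted when their
    area lies in ``area_range`` (inclusive) and they do not overlap the
    vessel mask — cells are vessel-external puncta. ``intensity_threshold``
    defaults to Otsu on the channel; a constant channel counts 0.
    """
    pdpl_channel = np.asarray(pdpl_channel, dtype=np.float64)
    if isinstance(lymph_mask, LabelMask):
        vessel = lymph_mask.class_mask(VesselClass.LYMPHATIC)
    else:
        vessel = np.asarray(lymph_mask, dtype=bool)
    if pdpl_channel.shape != vessel.shape:
        raise ValueError("channel and mask shapes differ")
    min_px, max_px = area_range
    if min_px > max_px:
        raise ValueError(f"area_range lower bound {min_px} exceeds upper {max_px}")
    if intensity_threshold is None:
        if np.ptp(pdpl_channel) == 0:
            return 0
        intensity_threshold = float(threshold_otsu(pdpl_channel))
    binary = pdpl_channel > intensity_threshold
    labels, n = cc_label(binary, connectivity=2, return_num=True)
    if n == 0:
        return 0
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    overlaps = ndi.sum_labels(vessel.astype(np.float64), labels, index=np.arange(1, n + 1))
    keep = (areas >= min_px) & (areas <= max_px) & (overlaps == 0)
    return int(np.count_nonzero(keep))


def lymphatic_morphometry(
    lymph_mask: LabelMask, min_spur_length: int = 5
) -> dict:
    """Centerline segment statistics of the lymphatic network.

    Reuses the skeleton-graph and morphometry machinery on the LYMPHATIC
    class; an empty mask yields flagged missing values.
    """
    graph = extract_graph(lymph_mask, min_spur_length=min_spur_length)
    stats = segment_statistics(graph)
    return {
        "mean_segment_length": stats["lymphatic"]["segment_length"]["mean"],
        "median_segment_length": stats["lymphatic"]["segment_length"]["median"],
        "n_complete_segments": stats["lymphatic"]["segment_length"]["n"],
        "mean_tortuosity": stats["lymphatic"]["tortuosity"]["mean"],
    }


def quantify_image(
    *,
    image_id: str = "",
    animal_id: str = "",
    group: str = "",
    asma_channel: np.ndarray | None = None,
    vessel_mask: np.ndarray | None = None,
    vessel_channel: np.ndarray | None = None,
    pdpl_channel: np.ndarray | None = None,
    lymph_mask: LabelMask | np.ndarray | None = None,
    smoothing_scale: float = 2.0,
    threshold_rule: str | float = "otsu",
    min_object_px: int = 25,
    cell_intensity_threshold: float | None = None,
    cell_area_range: tuple[int, int] = DEFAULT_CELL_AREA_RANGE,
    lymphatic_min_spur_length: int = 5,
) -> FluoroQuantRecord:
    """Assemble the fluorescence record for one field.

    The vessel mask may be supplied directly or segmented from
    ``vessel_channel``; PDPL measures require ``lymph_mask`` (and
    ``pdpl_channel`` for cell counting).
    """
    degenerate = False
    if vessel_mask is None:
        if vessel_channel is None:
            vessel_mask = np.zeros(
                np.asarray(asma_channel).shape if asma_channel is not None else (1, 1),
                dtype=bool,
            )
        else:
            vessel_mask, degenerate = segment_vessels_classical(
                vessel_channel, smoothing_scale, threshold_rule, min_object_px
            )
    vessel_mask = np.asarray(vessel_mask, dtype=bool)

    if asma_channel is not None:
        area, signal, ratio = asma_coverage(asma_channel, vessel_mask)
        stromal = stromal_asma(asma_channel, vessel_mask)
    else:
        area = int(np.count_nonzero(vessel_mask))
        signal, ratio, stromal = 0.0, None, 0.0

    pdpl_fraction = None
    cell_count = None
    lymph_len = None
    if lymph_mask is not None:
        pdpl_fraction = pdpl_vessel_fraction(lymph_mask)
        if pdpl_channel is not None:
            cell_count = count_pdpl_cells(
                pdpl_channel, lymph_mask, cell_intensity_threshold, cell_area_range
            )
        if isinstance(lymph_mask, LabelMask):
            lymph_len = lymphatic_morphometry(
                lymph_mask, min_spur_length=lymphatic_min_spur_length
            )["mean_segment_length"]

    return FluoroQuantRecord(
        image_id=image_id,
        animal_id=animal_id,
        group=group,
        vessel_area=area,
        asma_vessel_signal=signal,
        asma_coverage_ratio=ratio,
        asma_stromal_signal=stromal,
        pdpl_vessel_fraction=pdpl_fraction,
        pdpl_cell_count=cell_count,
        lymphatic_mean_segment_length=lymph_len,
        degenerate_segmentation=degenerate,
    )
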