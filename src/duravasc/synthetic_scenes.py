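"""Synthetic dural vascular and lymphatic scenes with exact ground truth.

Emulates 2D maximum-projection confocal fields (512x512 by default) of
the cranial dura mater: interdigitating arteriolar and venular trees
grown from border-anchored roots, a suture-band lymphatic network, an
α-SMA channel concentrated on blood vessels plus stromal patches, and a
podoplanin (PDPL) channel showing lymphatic vessels plus isolated
off-vessel cell puncta.

Centerlines are analytic curves — a chord plus a sinusoidal transverse
perturbation whose relative amplitude controls tortuosity — so each
segment's true path length, chord and tortuosity are exact by dense
quadrature, independent of the pipeline's discrete estimators. Group
effects (arteriolar shortening, raised arteriolar curvature, lymphatic
expansion, more PDPL+ cells, higher α-SMA gain) are injectable via
:class:`EffectSpec`, and :func:`make_cohort` builds reproducible
two-group animal cohorts with per-animal log-normal random effects so
that the per-animal averaging step is consequential.

All randomness derives from one master seed through
``numpy.random.SeedSequence`` spawning; a fixed seed reproduces every
scene bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as _disk

from .image_io import LabelMask, MultiChannelImage, VesselClass

__all__ = [
    "SceneParams",
    "EffectSpec",
    "TruthSegment",
    "SyntheticTruth",
    "Scene",
    "sample_network",
    "sample_lymph_network",
    "rasterize_network",
    "rasterize_lymph_network",
    "render_channels",
    "make_scene",
    "make_cohort",
]

#: Quadrature sampling density (points per pixel of chord) for truth lengths.
_QUAD_DENSITY = 4


@dataclass(frozen=True)
class SceneParams:
    """Geometry and signal parameters of one synthetic field.

    Lengths and widths are in pixels; intensities in arbitrary
    fluorescence units. Defaults describe a 512x512 field; use
    :meth:`for_size` to scale the geometry to a smaller frame.
    """

    size: int = 512
    margin: int = 12
    # blood-vessel trees
    n_trees_arteriole: int = 3
    n_trees_venule: int = 3
    branching_prob: float = 0.7
    extension_prob: float = 0.5
    max_depth: int = 3
    segment_length_median: float = 90.0
    segment_length_sigma: float = 0.30
    min_segment_length: float = 20.0
    curvature_amplitude: float = 0.06
    width_arteriole: int = 4
    width_venule: int = 5
    transition_rate: float = 0.12
    undetermined_rate: float = 0.03
    # alpha-SMA channel
    asma_vessel_intensity: float = 120.0
    stromal_patch_rate: float = 10.0
    stromal_patch_radius: tuple = (4.0, 10.0)
    stromal_patch_intensity: float = 60.0
    # lymphatics / PDPL channel
    n_lymph_vessels: int = 3
    lymph_band_fraction: float = 0.25
    lymph_width: int = 8
    lymph_amplitude: float = 0.05
    pdpl_vessel_intensity: float = 110.0
    pdpl_cell_rate: float = 8.0
    pdpl_cell_radius: int = 3
    pdpl_cell_intensity: float = 150.0
    # vessel-marker channel and noise
    vessel_marker_intensity: float = 100.0
    noise_sigma: float = 4.0
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        for name in ("branching_prob", "extension_prob", "transition_rate",
                     "undetermined_rate", "lymph_band_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("width_arteriole", "width_venule", "lymph_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if max(self.width_arteriole, self.width_venule, self.lymph_width) >= self.size:
            raise ValueError("vessel widths must be smaller than the image")
        if self.curvature_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("curvature_amplitude and noise_sigma must be >= 0")

    @classmethod
    def for_size(cls, size: int, **overrides) -> "SceneParams":
        """Defaults for a ``size``-pixel frame.

        A smaller frame emulates a *crop* of the acquisition field:
        absolute vessel geometry (segment lengths, widths) is kept, only
        the frame and its margin shrink.
        """
        base = dict(size=size, margin=max(int(12 * size / 512), 6))
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative/additive group effects applied to scene parameters.

    Encodes the directions of interest: arteriolar shortening
    (``arteriole_length_factor`` < 1), raised arteriolar curvature,
    lymphatic expansion (``lymphatic_area_factor`` > 1), more PDPL+
    cells, and a higher α-SMA gain. All factors must be positive.
    """

    arteriole_length_factor: float = 1.0
    arteriole_tortuosity_delta: float = 0.0
    venule_length_factor: float = 1.0
    venule_tortuosity_delta: float = 0.0
    lymphatic_area_factor: float = 1.0
    pdpl_cell_rate_factor: float = 1.0
    asma_gain_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("arteriole_length_factor", "venule_length_factor",
                     "lymphatic_area_factor", "pdpl_cell_rate_factor",
                     "asma_gain_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def is_identity(self) -> bool:
        return self == EffectSpec()


@dataclass
class TruthSegment:
    """One analytic centerline segment with exact metrics."""

    vessel_class: VesselClass
    points: np.ndarray  # dense (n, 2) float array, (row, col)
    length: float
    chord: float
    tortuosity: float
    width: int


@dataclass
class SyntheticTruth:
    """Per-scene ground truth, the oracle for every pipeline stage."""

    segments: list
    class_lengths: dict
    class_pixel_counts: dict = field(default_factory=dict)
    lymph_pixel_count: int = 0
    asma_vessel_signal: float = 0.0
    asma_stromal_signal: float = 0.0
    cell_positions: list = field(default_factory=list)
    cell_count: int = 0

    def total_length(self) -> float:
        return float(sum(self.class_lengths.values()))


@dataclass
class Scene:
    """A full synthetic field: masks, channels, and the truth record."""

    blood_mask: LabelMask
    lymph_mask: LabelMask
    channels: MultiChannelImage
    truth: SyntheticTruth
    params: SceneParams


# ---------------------------------------------------------------------------
# analytic centerlines


def _curve_points(
    p0: np.ndarray, p1: np.ndarray, amp_rel: float, waves: int, density: int = _QUAD_DENSITY
) -> tuple[np.ndarray, float, float]:
    """Dense polyline, arc length and chord of a sinusoidally perturbed chord.

    The curve is ``p0 + t (p1 - p0) + a |chord| sin(pi * waves * t) n``
    with ``n`` the unit normal; arc length by trapezoid-free polygonal
    quadrature over ``density`` samples per chord pixel.
    """
    chord = float(np.linalg.norm(p1 - p0))
    n = max(int(chord * density), 8)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    if amp_rel != 0.0:
        d = (p1 - p0) / chord
        normal = np.array([-d[1], d[0]])
        pts = pts + (amp_rel * chord * np.sin(math.pi * waves * t))[:, None] * normal[None, :]
        arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    else:
        arc = chord  # straight: exact, no quadrature round-off
    return pts, arc, chord


def _class_width(cls: VesselClass, params: SceneParams) -> int:
    if cls == VesselClass.ARTERIOLE:
        return params.width_arteriole
    if cls == VesselClass.VENULE:
        return params.width_venule
    if cls == VesselClass.LYMPHATIC:
        return params.lymph_width
    return (params.width_arteriole + params.width_venule) // 2  # undetermined


class _Occupancy:
    """Coarse per-class occupancy to keep same-class branches from crossing."""

    def __init__(self, size: int):
        self.size = size
        self.grids: dict = {}

    def collides(self, cls: VesselClass, pts: np.ndarray, skip: int, width: int) -> bool:
        # vessels of either class avoid existing vessels: the trees
        # interdigitate rather than cross (projected crossings are rare
        # and are resolved by the paint-order policy when they do occur)
        ip = np.round(pts[skip:]).astype(int)
        ip = ip[(ip[:, 0] >= 0) & (ip[:, 0] < self.size) & (ip[:, 1] >= 0) & (ip[:, 1] < self.size)]
        return any(bool(grid[ip[:, 0], ip[:, 1]].any()) for grid in self.grids.values())

    def add(self, cls: VesselClass, pts: np.ndarray, width: int) -> None:
        grid = self.grids.setdefault(cls, np.zeros((self.size, self.size), bool))
        ip = np.round(pts).astype(int)
        ip = ip[(ip[:, 0] >= 0) & (ip[:, 0] < self.size) & (ip[:, 1] >= 0) & (ip[:, 1] < self.size)]
        if not len(ip):
            return
        # dilate only within the segment's padded bounding box
        r0, c0 = np.maximum(ip.min(axis=0) - width - 1, 0)
        r1, c1 = np.minimum(ip.max(axis=0) + width + 2, self.size)
        stamp = np.zeros((r1 - r0, c1 - c0), bool)
        stamp[ip[:, 0] - r0, ip[:, 1] - c0] = True
        grid[r0:r1, c0:c1] |= ndi.binary_dilation(stamp, structure=_disk(width))


def sample_network(
    params: SceneParams,
    seed: int | np.random.Generator,
    effect: EffectSpec = EffectSpec(),
) -> list:
    """Grow planar arteriolar and venular trees; returns truth segments.

    Trees start at border-anchored roots heading inward; at each segment
    end the path branches (two children, deviated headings) with
    ``branching_prob``, else extends with ``extension_prob``. A
    non-branching extension switches class with ``transition_rate``
    (arteriole <-> venule) or becomes UNDETERMINED with
    ``undetermined_rate``, producing the class-transition points the
    downstream graph must recognise. Branches avoid crossing existing
    vessels, so the trees interdigitate, as in projected dura fields.
    Fully reproducible for a fixed seed.

    Group length effects are applied *after* growth, by scaling each
    finished tree about its root by the factor of the tree's root class.
    Growing first and scaling second keeps the branching topology
    identical in distribution across groups, so the realized per-class
    total truth length scales by exactly the requested factor instead of
    being partly compensated by shorter segments fitting the frame more
    easily.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size, margin = params.size, params.margin
    occ = _Occupancy(size)
    segments: list = []

    length_factor = {
        VesselClass.ARTERIOLE: effect.arteriole_length_factor,
        VesselClass.VENULE: effect.venule_length_factor,
    }
    amplitude_delta = {
        VesselClass.ARTERIOLE: effect.arteriole_tortuosity_delta,
        VesselClass.VENULE: effect.venule_tortuosity_delta,
    }

    def length_draw(cls: VesselClass) -> float:
        return float(
            np.exp(math.log(params.segment_length_median)
                   + params.segment_length_sigma * rng.standard_normal())
        )

    def amplitude_draw(cls: VesselClass) -> float:
        base = params.curvature_amplitude + amplitude_delta.get(cls, 0.0)
        if base <= 0.0:
            return 0.0
        return base * rng.uniform(0.3, 1.5)

    def in_bounds(p: np.ndarray) -> bool:
        return margin <= p[0] <= size - margin and margin <= p[1] <= size - margin

    tree: list = []  # (TruthSegment, parent_index) for the tree being grown

    def grow(p0: np.ndarray, heading: float, cls: VesselClass, depth: int,
             parent_idx: int) -> None:
        if depth > params.max_depth:
            return
        width = _class_width(cls, params)
        for _ in range(3):  # heading retries on collision / out of bounds
            h = heading if _ == 0 else heading + rng.uniform(-0.5, 0.5)
            L = length_draw(cls)
            direction = np.array([math.sin(h), math.cos(h)])
            p1 = p0 + L * direction
            if not in_bounds(p1):
                clipped = False
                for f in np.linspace(0.85, 0.25, 7):
                    q = p0 + f * L * direction
                    if in_bounds(q):
                        p1, L, clipped = q, f * L, True
                        break
                if not clipped:
                    continue
            if L < params.min_segment_length:
                continue
            amp = amplitude_draw(cls)
            waves = int(rng.integers(1, 3))
            pts, arc, chord = _curve_points(p0, p1, amp, waves)
            # the full curve must stay inside the frame: truth length and
            # rasterized length must agree
            if pts.min() < 2 or pts.max() > size - 3:
                continue
            # children may brush their parent near the junction; root
            # segments have no parent and must stay clear from the start
            skip = min(len(pts) - 1, int(3 * width * _QUAD_DENSITY)) if parent_idx >= 0 else 0
            if occ.collides(cls, pts, skip, width):
                continue
            tort = arc / chord if chord > 0 else math.inf
            if amp == 0.0:
                tort = 1.0
            idx = len(tree)
            tree.append(
                (
                    TruthSegment(
                        vessel_class=cls, points=pts, length=arc,
                        chord=chord, tortuosity=tort, width=width,
                    ),
                    parent_idx,
                )
            )
            occ.add(cls, pts, max(1, width // 2))
            # continue growing from the far end
            u = rng.random()
            if u < params.branching_prob and depth < params.max_depth:
                for sign in (1.0, -1.0):
                    grow(p1, h + sign * rng.uniform(0.3, 0.8), cls, depth + 1, idx)
            elif u < params.branching_prob + params.extension_prob and depth < params.max_depth:
                new_cls = cls
                v = rng.random()
                if cls in (VesselClass.ARTERIOLE, VesselClass.VENULE):
                    if v < params.transition_rate:
                        new_cls = (
                            VesselClass.VENULE
                            if cls == VesselClass.ARTERIOLE
                            else VesselClass.ARTERIOLE
                        )
                    elif v < params.transition_rate + params.undetermined_rate:
                        new_cls = VesselClass.UNDETERMINED
                grow(p1, h + rng.uniform(-0.3, 0.3), new_cls, depth + 1, idx)
            return
        return

    def finish_tree(root_cls: VesselClass, root: np.ndarray) -> None:
        """Scale the grown tree about its root and keep in-frame segments."""
        factor = length_factor.get(root_cls, 1.0)
        keep: dict = {}
        for i, (seg, parent) in enumerate(tree):
            if factor != 1.0:
                pts = root[None, :] + factor * (seg.points - root[None, :])
                seg = TruthSegment(
                    vessel_class=seg.vessel_class, points=pts,
                    length=seg.length * factor, chord=seg.chord * factor,
                    tortuosity=seg.tortuosity, width=seg.width,
                )
            in_frame = bool(seg.points.min() >= 2 and seg.points.max() <= size - 3)
            # a segment survives only if its parent survived (connectivity)
            if in_frame and (parent < 0 or parent in keep):
                keep[i] = seg
        segments.extend(keep.values())
        tree.clear()

    roots = [(VesselClass.ARTERIOLE, params.n_trees_arteriole),
             (VesselClass.VENULE, params.n_trees_venule)]
    for cls, n_trees in roots:
        for _ in range(n_trees):
            side = int(rng.integers(0, 4))
            pos = float(rng.uniform(0.15, 0.85) * size)
            if side == 0:  # top edge, head downward
                p0 = np.array([float(margin), pos])
                h = rng.uniform(math.pi / 2 - 0.9, math.pi / 2 + 0.9)
            elif side == 1:  # bottom edge, head upward
                p0 = np.array([float(size - margin), pos])
                h = rng.uniform(-math.pi / 2 - 0.9, -math.pi / 2 + 0.9)
            elif side == 2:  # left edge, head right
                p0 = np.array([pos, float(margin)])
                h = rng.uniform(-0.9, 0.9)
            else:  # right edge, head left
                p0 = np.array([pos, float(size - margin)])
                h = rng.uniform(math.pi - 0.9, math.pi + 0.9)
            grow(p0, float(h), cls, 0, -1)
            finish_tree(cls, p0)
    return segments


def sample_lymph_network(
    params: SceneParams, seed: int | np.random.Generator
) -> list:
    """Lymphatic vessels running along a horizontal virtual suture band."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = params.size
    band_half = 0.5 * params.lymph_band_fraction * size
    centre = size / 2.0
    segments: list = []
    for _ in range(params.n_lymph_vessels):
        row = float(rng.uniform(centre - band_half, centre + band_half))
        r0 = row + float(rng.uniform(-4, 4))
        r1 = row + float(rng.uniform(-4, 4))
        p0 = np.array([r0, float(params.margin)])
        p1 = np.array([r1, float(size - params.margin)])
        amp = params.lymph_amplitude * rng.uniform(0.4, 1.4) if params.lymph_amplitude else 0.0
        waves = int(rng.integers(1, 4))
        pts, arc, chord = _curve_points(p0, p1, amp, waves)
        pts[:, 0] = np.clip(pts[:, 0], 2, size - 3)
        arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        tort = 1.0 if amp == 0.0 else arc / chord
        segments.append(
            TruthSegment(
                vessel_class=VesselClass.LYMPHATIC, points=pts, length=arc,
                chord=chord, tortuosity=tort, width=params.lymph_width,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# rasterization


def _stamp_segments(shape: tuple, segments: Sequence) -> np.ndarray:
    """Paint centerlines dilated to their width, grouped by width so each
    distinct width costs one dilation. Strokes end at segment endpoints."""
    out = np.zeros(shape, dtype=bool)
    size = shape[0]
    by_width: dict = {}
    for seg in segments:
        by_width.setdefault(max(1, seg.width // 2), []).append(seg)
    for radius, segs in sorted(by_width.items()):
        line = np.zeros(shape, dtype=bool)
        for seg in segs:
            ip = np.round(seg.points).astype(int)
            ip = ip[(ip[:, 0] >= 0) & (ip[:, 0] < size) & (ip[:, 1] >= 0) & (ip[:, 1] < size)]
            line[ip[:, 0], ip[:, 1]] = True
        out |= ndi.binary_dilation(line, structure=_disk(radius))
    return out


#: Paint order for overlapping classes: later classes paint over earlier
#: ones, so arterioles win over venules at crossings (recorded policy).
_PAINT_ORDER = (VesselClass.VENULE, VesselClass.UNDETERMINED, VesselClass.ARTERIOLE)


def rasterize_network(
    network: Sequence, params: SceneParams, *, image_id: str = "",
    animal_id: str = "", group: str = "", pixel_size: float = 1.0,
) -> tuple[LabelMask, dict]:
    """Rasterize blood-vessel truth segments into a class-labelled mask.

    Returns the mask and the realized per-class pixel counts (after
    overlap resolution: arteriole paints over venule).
    """
    size = params.size
    grid = np.zeros((size, size), dtype=np.uint8)
    for cls in _PAINT_ORDER:
        layer = _stamp_segments((size, size), [s for s in network if s.vessel_class == cls])
        grid[layer] = int(cls)
    counts = {
        cls: int(np.count_nonzero(grid == cls))
        for cls in (VesselClass.ARTERIOLE, VesselClass.VENULE, VesselClass.UNDETERMINED)
    }
    mask = LabelMask(grid=grid, pixel_size=pixel_size, image_id=image_id,
                     animal_id=animal_id, group=group)
    return mask, counts


def rasterize_lymph_network(
    lymph_network: Sequence, params: SceneParams, *, image_id: str = "",
    animal_id: str = "", group: str = "", pixel_size: float = 1.0,
) -> tuple[LabelMask, int]:
    """Rasterize lymphatic truth segments; returns mask and pixel count."""
    size = params.size
    layer = _stamp_segments((size, size), list(lymph_network))
    grid = np.where(layer, np.uint8(VesselClass.LYMPHATIC), np.uint8(0))
    mask = LabelMask(grid=grid, pixel_size=pixel_size, image_id=image_id,
                     animal_id=animal_id, group=group)
    return mask, int(np.count_nonzero(layer))


# ---------------------------------------------------------------------------
# channel rendering


def render_channels(
    blood_mask: LabelMask,
    lymph_mask: LabelMask,
    params: SceneParams,
    seed: int | np.random.Generator,
    *,
    asma_gain: float = 1.0,
    cell_rate: float | None = None,
) -> tuple[MultiChannelImage, dict]:
    """Render vessel / α-SMA / PDPL channels and their noiseless truth.

    α-SMA = ``asma_gain * asma_vessel_intensity`` on blood vessels plus
    random off-vessel stromal patches; PDPL = lymphatic vessels plus
    off-vessel cell disks; additive Gaussian noise (clipped at 0) and
    optional Poisson resampling on top. The returned truth dict holds
    the noiseless vessel/stromal α-SMA signals and the realized cell
    positions and count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = params.size
    blood = blood_mask.foreground()
    lymph = lymph_mask.class_mask(VesselClass.LYMPHATIC)

    vessel_ch = np.where(blood, params.vessel_marker_intensity, 0.0)

    asma = np.where(blood, asma_gain * params.asma_vessel_intensity, 0.0)
    n_patches = int(rng.poisson(params.stromal_patch_rate))
    patch_layer = np.zeros((size, size), dtype=bool)
    for _ in range(n_patches):
        r = rng.uniform(*params.stromal_patch_radius)
        centre = rng.uniform(r, size - r, size=2)
        rr, cc = np.ogrid[:size, :size]
        diskpx = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= r * r
        patch_layer |= diskpx
    patch_layer &= ~blood  # stromal patches live off-vessel
    asma[patch_layer] = params.stromal_patch_intensity
    truth_vessel_signal = float(asma[blood].sum())
    truth_stromal_signal = float(asma[~blood].sum())

    pdpl = np.where(lymph, params.pdpl_vessel_intensity, 0.0)
    rate = params.pdpl_cell_rate if cell_rate is None else cell_rate
    n_cells_target = int(rng.poisson(rate))
    cell_positions: list = []
    cr = params.pdpl_cell_radius
    # keep puncta clear of vessels and of each other so each is one
    # connected component at any threshold
    lymph_clearance = ndi.distance_transform_edt(~lymph) if lymph.any() else None
    attempts = 0
    while len(cell_positions) < n_cells_target and attempts < 50 * max(n_cells_target, 1):
        attempts += 1
        centre = rng.uniform(cr + 2, size - cr - 2, size=2)
        ir, ic = int(round(centre[0])), int(round(centre[1]))
        if lymph_clearance is not None and lymph_clearance[ir, ic] <= cr + 3:
            continue
        if any((centre[0] - p[0]) ** 2 + (centre[1] - p[1]) ** 2 <= (3 * cr + 2) ** 2
               for p in cell_positions):
            continue
        r0, c0 = max(ir - cr - 1, 0), max(ic - cr - 1, 0)
        r1, c1 = min(ir + cr + 2, size), min(ic + cr + 2, size)
        rr, cc = np.ogrid[r0:r1, c0:c1]
        diskpx = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= cr * cr
        pdpl[r0:r1, c0:c1][diskpx] = params.pdpl_cell_intensity
        cell_positions.append((float(centre[0]), float(centre[1])))

    channels = {"vessel": vessel_ch, "asma": asma, "pdpl": pdpl}
    if params.noise_sigma > 0:
        for name in channels:
            noisy = channels[name] + rng.normal(0.0, params.noise_sigma, (size, size))
            channels[name] = np.clip(noisy, 0.0, None)
    if params.poisson_noise:
        for name in channels:
            channels[name] = rng.poisson(channels[name]).astype(np.float64)

    image = MultiChannelImage(
        channels=channels, pixel_size=blood_mask.pixel_size,
        image_id=blood_mask.image_id, animal_id=blood_mask.animal_id,
        group=blood_mask.group,
    )
    truth = {
        "asma_vessel_signal": truth_vessel_signal,
        "asma_stromal_signal": truth_stromal_signal,
        "cell_positions": cell_positions,
        "cell_count": len(cell_positions),
    }
    return image, truth


# ---------------------------------------------------------------------------
# scene and cohort assembly


def apply_effect(params: SceneParams, effect: EffectSpec) -> SceneParams:
    """Fold a group effect into scene parameters (lymphatic expansion
    scales vessel width so covered area grows; cell rate and α-SMA gain
    are applied at render time via :func:`make_scene`)."""
    return replace(
        params,
        lymph_width=max(1, int(round(params.lymph_width * effect.lymphatic_area_factor))),
    )


def make_scene(
    params: SceneParams,
    seed: int | np.random.SeedSequence,
    effect: EffectSpec = EffectSpec(),
    *,
    image_id: str = "",
    animal_id: str = "",
    group: str = "",
    pixel_size: float = 1.0,
) -> Scene:
    """Generate one complete synthetic field under a group effect."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_blood, rng_lymph, rng_chan = (np.random.default_rng(s) for s in ss.spawn(3))
    eff_params = apply_effect(params, effect)
    network = sample_network(eff_params, rng_blood, effect)
    lymph_network = sample_lymph_network(eff_params, rng_lymph)

    blood_mask, counts = rasterize_network(
        network, eff_params, image_id=image_id, animal_id=animal_id,
        group=group, pixel_size=pixel_size,
    )
    lymph_mask, lymph_count = rasterize_lymph_network(
        lymph_network, eff_params, image_id=image_id, animal_id=animal_id,
        group=group, pixel_size=pixel_size,
    )
    channels, chan_truth = render_channels(
        blood_mask, lymph_mask, eff_params, rng_chan,
        asma_gain=effect.asma_gain_factor,
        cell_rate=eff_params.pdpl_cell_rate * effect.pdpl_cell_rate_factor,
    )

    class_lengths: dict = {}
    for seg in network + lymph_network:
        class_lengths[seg.vessel_class] = class_lengths.get(seg.vessel_class, 0.0) + seg.length
    truth = SyntheticTruth(
        segments=network + lymph_network,
        class_lengths=class_lengths,
        class_pixel_counts=counts,
        lymph_pixel_count=lymph_count,
        asma_vessel_signal=chan_truth["asma_vessel_signal"],
        asma_stromal_signal=chan_truth["asma_stromal_signal"],
        cell_positions=chan_truth["cell_positions"],
        cell_count=chan_truth["cell_count"],
    )
    return Scene(blood_mask=blood_mask, lymph_mask=lymph_mask,
                 channels=channels, truth=truth, params=eff_params)


#: Standard deviation of the per-animal log-normal random effect applied to
#: segment lengths and channel intensities.
ANIMAL_EFFECT_SIGMA = 0.05


def make_cohort(
    control_params: SceneParams,
    effect: EffectSpec,
    n_animals_per_group: int,
    images_per_animal: int,
    seed: int,
    *,
    groups: tuple = ("control", "ovx"),
    animal_effect_sigma: float = ANIMAL_EFFECT_SIGMA,
) -> list:
    """Build a reproducible two-group cohort of synthetic scenes.

    Control animals draw from ``control_params`` unchanged; the second
    group folds in ``effect``. Each animal additionally carries a
    log-normal random scale (sigma ``animal_effect_sigma``) on segment
    lengths and channel intensities, so images within an animal are
    correlated and the per-animal averaging step matters. All
    per-animal and per-image seeds derive from the master ``seed``.
    """
    if n_animals_per_group < 2:
        raise ValueError("need at least 2 animals per group")
    master = np.random.SeedSequence(seed)
    scenes: list = []
    group_effects = {groups[0]: EffectSpec(), groups[1]: effect}
    animal_seqs = master.spawn(2 * n_animals_per_group)
    idx = 0
    for group in groups:
        for a in range(n_animals_per_group):
            animal_id = f"{group}_{a + 1}"
            aseq = animal_seqs[idx]
            idx += 1
            arng = np.random.default_rng(aseq)
            scale = float(np.exp(animal_effect_sigma * arng.standard_normal()))
            animal_params = replace(
                control_params,
                segment_length_median=control_params.segment_length_median * scale,
                asma_vessel_intensity=control_params.asma_vessel_intensity * scale,
                pdpl_vessel_intensity=control_params.pdpl_vessel_intensity * scale,
            )
            image_seqs = aseq.spawn(images_per_animal)
            for i in range(images_per_animal):
                scenes.append(
                    make_scene(
                        animal_params,
                        image_seqs[i],
                        group_effects[group],
                        image_id=f"{animal_id}_img{i + 1}",
                        animal_id=animal_id,
                        group=group,
                    )
                )
    return scenes
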