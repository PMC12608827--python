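# Methods

## Scope and data model

`duravasc` quantifies 2D maximum-projection fields of dural
microvasculature. The unit of annotation is a class-labelled mask
(arteriole, venule, undetermined region, background; lymphatic masks
carry a single LYMPHATIC class on background). Fluorescence travels as
co-registered intensity channels (`vessel`, `asma`, `pdpl`); z-stacks
are fused by per-pixel maximum projection before analysis — the package
analyses 2D projections only, never individual planes. Coordinates are
0-based (row, col), origin top-left; pixel size is micrometres per pixel
and defaults to 1.0, in which case all lengths are in pixel units. Every
length-bearing output records its unit, and every tunable parameter that
affects a number appears in the run manifest.

## Centerline graph

The binary union of all vessel classes is thinned with a
topology-preserving 2D thinning (scikit-image `skeletonize`) to a
unit-width, 8-connected skeleton; the skeleton's connected-component
count equals the mask's.

Node taxonomy:

- **Branching points**: skeleton pixels with ≥3 skeleton neighbours.
  Thinning routinely emits 2-pixel junction clusters, so 8-connected
  junction pixels are merged into one node placed at the
  centroid-nearest pixel (row-major tie-break).
- **Endpoints**: pixels with exactly one neighbour (including segments
  cut by the image border, whose border end is an endpoint).
- **Transition points**: inserted where two consecutive centerline
  pixels carry different vessel classes; the node sits at the first
  pixel of the new class and belongs to both flanking segments.

A segment is **complete** iff both end nodes are branching or transition
points; segment-level statistics use complete segments only, while total
network length sums every segment. Two corner cases have fixed,
documented resolutions: pure cycles receive one artificial
branching-kind anchor at their lexicographically smallest pixel (the
loop's zero-chord segment is excluded from tortuosity), and a junction
cluster left with exactly two incident segments is demoted to a
transition point if their classes differ, or dissolved (the two
segments spliced through the cluster) if not. Isolated single pixels
carry no measurable geometry and are dropped.

Terminal branches shorter than `min_spur_length` (default 5 px,
configurable, recorded in the manifest) are pruned before graph
construction; pruning iterates to a fixed point, never disconnects the
skeleton, and leaves isolated paths alone. The threshold suppresses
thinning artifacts at vessel-wall irregularities; by construction it can
also delete a genuine terminal branchlet shorter than 5 px, which is the
accepted trade-off.

UNDETERMINED-class segments count toward network totals and the overall
(pooled) segment statistics but are excluded from arteriole- and
venule-specific statistics: they are part of the network but cannot be
attributed. Both the inclusive and the determined-only totals are
emitted; the inclusive one is primary.

The graph extractor is verified against an independent brute-force
enumeration (`duravasc.validation`), which recomputes nodes and segments
via a networkx pixel-adjacency graph and component contraction. The two
routes share only the documented conventions above, and agree exactly on
hundreds of random small masks.

## Length and tortuosity estimation

Centerline length is the Euclidean length of the Douglas–Peucker
simplification of the pixel polyline at tolerance 0.75 px. The naive
unit/√2 step sum over 8-connected pixels overestimates digitized curves
by up to ~8% at orientations near 22.5° (~+4.5% averaged over uniform
orientations), which is larger than the accuracy this package targets
for length recovery and arc-chord ratios. The simplification tolerance
sits above the worst-case staircase deviation of a digital straight
line (≈0.71 px) and below any real corner, so axis-aligned and diagonal
runs measure exactly (11 collinear pixels → 10.0; a 6-pixel diagonal →
5√2; an L-path → 10.0 regardless of where the corner falls), while
smooth digital arcs measure within ~1–2% (a rasterized semicircle of
radius 40 px yields an arc-chord ratio of 1.554 against the analytic
π/2 ≈ 1.571).

Tortuosity of a complete segment is path length over the Euclidean
distance between its endpoints; values within 1e−9 below 1 are clamped
to exactly 1 (floating-point guard only). Zero-chord loops are excluded
with a recorded reason, never an error.

## Fluorescence quantification

"α-SMA signal" is summed intensity, not thresholded area: coverage is
Σ intensity over the vessel mask divided by the vessel pixel count, and
stromal α-SMA is total minus vessel-associated signal, so
vessel + stromal = total holds exactly on every image. An empty vessel
mask flags the ratio as missing rather than zero.

Vessel masks may be supplied externally or produced by a deterministic
classical segmenter (Gaussian smoothing, Otsu or fixed threshold,
removal of objects under `min_object_px`); a constant image under
auto-thresholding yields a flagged empty mask. PDPL⁺ cell counting is a
declared automated rule — intensity threshold (Otsu default), connected
components, area gate (default 10–400 px), and exclusion of components
touching the lymphatic vessel mask, since the cells of interest are
vessel-external puncta. The PDPL⁺ vessel fraction is lymphatic pixels
over image pixels.

## Statistics

The animal is the experimental unit: per-image values are averaged
within animal (missing values dropped with a logged count), and the
per-animal means enter a two-sided unpaired *t*-test — Student's
pooled-variance by default, matching the common default of standard
statistics packages when an "unpaired t-test" is selected; Welch's
variant is a config switch. Degrees of freedom therefore follow animal
counts, not image counts. Significance is *p* < 0.05; no
multiple-testing correction is applied, and the report records the
number of tests run. Zero-variance edge cases follow fixed conventions:
identical constant groups give t = 0, p = 1; constant groups with
different means are flagged degenerate. Densitometry normalization is
the plain ratio of target to loading-control band intensity. Group
means are reported ± SEM over animals.

## Synthetic scenes

The generator emulates the structure of projected dural fields:
interdigitating arteriolar and venular trees grown from border-anchored
roots (default three per class in a 512×512 frame, segment lengths
log-normal with median 90 px and σ = 0.3, widths 4 and 5 px, branching
probability 0.7 to depth 3), class transitions along non-branching
extensions (rate 0.12, plus 0.03 to undetermined), a suture-band
lymphatic network (three vessels of width 8 px in a central band), an
α-SMA channel with vessel-band intensity 120 plus off-vessel stromal
patches, a PDPL channel with lymphatic vessels plus Poisson-distributed
(mean 8) off-vessel cell disks of radius 3 px, and additive Gaussian
noise (σ = 4, clipped at zero; optional Poisson resampling). Smaller
frames are treated as crops: geometry is absolute, only the frame
shrinks.

Centerlines are analytic — a chord plus a sinusoidal transverse
perturbation whose relative amplitude (default 0.06) controls
tortuosity — so true path length, chord and tortuosity are exact by
dense quadrature (4 samples per chord pixel; straight segments bypass
quadrature and are exact by construction). Rasterization dilates each
centerline to its class width with butt-capped strokes, resolving
overlaps by paint order (arterioles over venules, recorded); realized
per-class pixel counts are written back into the truth record, so area
fractions are checkable exactly. Same-class and cross-class branches
avoid crossing during growth (trees interdigitate; residual contacts at
junction starts are resolved by paint order).

Group effects are injected *after* tree growth by scaling each finished
tree about its root by the factor of its root class. Growing first and
scaling second keeps branching topology identical in distribution
across groups, so the realized per-class truth length scales by exactly
the requested factor — scaling the length draws directly would be
partly compensated by shorter segments fitting the frame more easily.
A small impurity remains: pieces that switched class mid-tree inherit
the root class's factor, contaminating the other class's group ratio by
a few percent of its total at the default transition rate. Tortuosity
effects add to the curvature amplitude per class; lymphatic expansion
scales vessel width; cell-rate and α-SMA-gain factors apply at render
time.

Cohorts draw per-animal log-normal random effects (σ = 0.05) on segment
lengths and channel intensities, so images within an animal are
correlated and per-animal averaging is consequential. All randomness
flows from one master seed through `numpy.random.SeedSequence`
spawning; fixed seeds reproduce cohorts bit-exactly.

What the generator does *not* emulate: out-of-focus haze and optical
PSF, annotation errors and inter-annotator variability, vessel diameter
variation along a segment, true 3D structure collapsed by projection,
and spatially structured background. Passing tests on these scenes
therefore demonstrates correctness of the measurement chain under known
geometry, not robustness to real staining and imaging artifacts;
externally produced masks of real data enter through the same
interfaces.

## Verification problem sizes

Ground-truth recovery runs on fifty 256×256 fields (zero channel noise,
so cell counts are checkable exactly; length recovery is assessed on
the per-class aggregate over the fifty fields, the scale at which the
±5% target is meaningful given the per-scene scatter of tree geometry).
Effect detection uses 100 replicate cohorts of 5 animals × 10 images
per group at 128×128 with a 0.75 arteriolar length factor; null
calibration uses 200 identity-effect cohorts of 5 animals × 4 images.
The brute-force graph oracle is compared on ≥500 random masks up to
12×12. These sizes keep the full verification suite to a few minutes on
one CPU while leaving each check statistically meaningful.

## Known limitations

- Vessel diameters are not measured; area fraction is the only
  width-sensitive output.
- Length estimation on strongly kinked centerlines (true corners
  sharper than the 0.75 px tolerance apart) falls back to chord sums
  and can under-read by ~1–2%.
- The two-group comparison assumes approximately normal per-animal
  means; no hierarchical model of image-within-animal structure is
  fitted.
- The classical intensity segmenter is a deterministic stand-in for
  learned segmentation; its masks are serviceable on high-contrast
  fields but are not expected to match expert annotation on real data.
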