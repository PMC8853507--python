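# Methods

## The problem and the pipeline

Tissue composition inside a pressure ulcer drives treatment: granulation
signals healing, slough and eschar signal necrosis and potential
surgery.  Hand-drawn tissue boundaries suffer large inter- and
intra-rater variability because the transitions on a wound bed are
gradual.  The pipeline implemented here pre-segments the photograph into
superpixels so that annotation becomes region *sorting* instead of
border *drawing*, carries two labeling styles into one canonical mask
representation, and derives clinical outputs (healing state, G/U ratio
and trend, metric wound size, debridement recommendation) from the
masks plus basic clinical data.

## SLIC superpixels

SLIC is localized k-means in (l, a, b, x, y).  With N pixels and a
requested K regions, seeds sit on a grid with interval S = √(N/K),
snapped to pixel positions and nudged to the lowest-gradient spot in
their 3×3 neighborhood so no seed starts on an edge.  Pixel-to-center
distance is the linear combination

    D = D_color + (m/S) · D_xy,

with D_color and D_xy Euclidean norms in color and position.  This
linear form is the package's canonical distance; the classical
quadrature form √(D_color² + (D_xy/S)²·m²) is available via
`SlicParams.original_distance` for comparison — on the synthetic scenes
the two give near-identical partitions, since both reduce to spatial
Voronoi on flat color and both are dominated by D_color at strong
edges.

Assignment searches a 2S×2S window around each center (the standard
bound that keeps each sweep O(N)), and iteration stops when the mean
center displacement falls to `tol` (default 0.1 px) or after
`max_iter` = 10 sweeps.  Defaults m = 10 and K ∈ [800, 1000] (seeded
draw) reflect the labeling protocol at the 1000-px working resolution;
tests and examples use K scaled to their smaller rasters.

Numerical choices:

* Ties in the distance comparison go to the lowest center index.  The
  comparison uses an absolute guard of 1e-9 so that floating-point
  noise from the center-mean update cannot flip a genuine tie; on
  uniform images the partition therefore equals the exact spatial
  Voronoi diagram of the initial seeds.
* After convergence, connected components smaller than (N/K)/4 pixels
  are absorbed into their largest 4-adjacent neighbor and labels are
  renumbered consecutively in row-major first-appearance order, making
  the output total, 4-connected and deterministic.
* Pixels that fall outside every search window after centers drift
  (rare, degenerate K) are attached to the spatially nearest center.

## Color and geometry conventions

RGB↔CIELAB uses the sRGB companding curve with the D65 white point —
the universal assumption for consumer-camera JPEGs.  The working-canvas
protocol scales the longest side to 1000 px (bilinear; bit-exact when
the scale is 1), anchors the content at the top-left of a 1000×1000
black canvas, and returns a scale/offset record so masks map losslessly
between source and canvas resolution.  Non-4:3 inputs are handled by
the same rule: longest side to 1000, pad both axes.

## Annotation model

Pixel coordinates are 0-based, row-major, origin top-left, with the
center of pixel (r, c) at continuous position (x=c, y=r).  Polygon
rasterization uses pixel-center inclusion under the even-odd (crossing
parity) rule with half-open boundary handling, so two abutting polygons
partition the raster without double-claiming a pixel; self-intersecting
polygons are filled even-odd with a warning.

The canonical `LabelMasks` invariants are: the four inside classes
(granulation, slough, eschar, undefined) are pairwise disjoint; the
ulceration is *defined* as their union; the re-ep rim is disjoint from
the ulceration.  "Undefined" is the residual wound bed never drawn
explicitly — a wound need not contain every tissue, which is why the
composition identity is a union, not an intersection.  In boundary
labeling, later inner polygons override earlier ones (topping order),
and re-ep is clipped to the wound's complement.  Region labeling maps
superpixels to inside classes only; the rim always comes from boundary
labeling (or is passed as a mask).

Class groupings: model 1 = {background, ulceration, re_ep} (wound
outline + healing rim); model 2 = {background, granulation, slough,
eschar, re_ep} (inside tissues).  Model 2 has no slot for the residual
class, so "undefined" pixels map to background there.

Dataset protocol: 7:2:1 split by floor(0.7n)/floor(0.2n)/remainder
after a seeded shuffle, and three disjoint exhaustive CV folds over
train+validation.  Augmentation applies geometric ops (rotation, shift,
scale) to the image bilinearly and to the categorical label map with
nearest-neighbor — transforming the single categorical map is what
preserves the disjointness invariants — while photometric ops (gaussian
blur, contrast normalization) leave masks untouched; rotations by
multiples of 90° use exact array rotation.

## Metrics

Dice = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), precision, recall,
accuracy, and the Dice loss 1 − (2TP+ε)/(2TP+FP+FN+ε) with default
ε = 1e-6.  Conventions: Dice of two empty masks is 1.0 (agreement, and
the ε-regularized loss limit) with a warning; other zero-denominator
ratios are NaN, never silently 0.  `evaluate` computes one-vs-rest
counts per class and reports both micro (pooled counts) and macro
(averaged metrics, NaN-aware) aggregates, since reported single numbers
in segmentation work rarely state their averaging scheme.

## Wound size, healing indicators, decision rules

Pinhole sizing: Length = D·sensor_size/focal_distance and
A = Length²·aspect_ratio give the physical area imaged at distance D;
the wound area is its pixel fraction of A.  Rescaling to another
distance uses A·(Dx/D)² by default — the pinhole model makes projected
area quadratic in distance, and the quadratic choice is consistent with
the Length formula; a linear exponent remains available as a
configuration knob for compatibility with the alternative reading.

The G/U ratio is |granulation|/|ulceration|.  Its trend is the
least-squares slope of the (date, ratio) series in units of /week:
above +δ improving, below −δ worsening, else stable (δ = 0.01/week
default).  Healing is flagged when at least 50 re-ep pixels lie within
a 5-px dilation of the ulceration (defaults at the 1000-px scale; both
configurable).

The debridement recommendation evaluates three booleans — *necrotic*
(|eschar ∪ slough| > 5 % of the ulceration), *infection*
(WBC > 12 000/mm³, strict inequality, or fever or local signs), and
*stalled* (G/U stable/worsening under ongoing dressing changes) — and
maps them through a rule table.  The default table: debride iff
necrotic ∧ (infection ∨ stalled); clinical review iff infection without
necrosis; otherwise continue dressing changes.  The full tree in the
source material is only partially recoverable, so the table is
configuration-overridable.  Missing clinical fields become
three-valued unknowns: every completion of the unknowns is evaluated,
and if the recommendation is not invariant the report escalates to
clinical review with the unknown flags listed — unknown is never
silently false.  The necrosis threshold (5 %), adjacency radius and
re-ep minimum are package choices where no published value exists.

## Synthetic scenes

`generate_scene` emulates: skin-toned background, one central organic
ulceration whose target fraction (default 0.418 of the frame, the
study-population average) is hit exactly up to rounding by quantile
thresholding of a low-pass-filtered noise field with central bias;
inside tissue blobs at exact mixture weights (default 0.5/0.3/0.2 for
granulation/slough/eschar — granulation-dominant wounds with a
substantial necrotic load, the regime where the decision rules are
interesting); a re-ep rim of 6 px by morphological dilation; flat
per-class colors jittered around anchors chosen from the tissues'
verbal descriptions (granulation (180,40,50), slough (200,180,80),
eschar (60,40,30), re-ep (220,170,180), skin (225,185,160)); then a
linear illumination ramp and Gaussian sensor noise (σ = 6 on the 8-bit
scale).  The jitter is redrawn until every pair of class colors stays
≥ 12 CIELAB units apart, preserving the palette-separation property
that keeps color-boundary tasks well-posed (the re-ep/skin anchor pair
is only ~19 units apart, so unconstrained jitter could make the rim
invisible even in principle).  Masks record the pre-noise geometry
exactly; clinical records are sampled from plausible ranges
(lognormal WBC around 9 000/mm³, weekly G/U series with a random
trend).

What the generator does **not** emulate: textured tissue interiors,
gradual tissue transitions, specular highlights, dressings, blood or
pus, perspective and depth.  Passing tests therefore demonstrate the
correctness of the algorithms and their plumbing on controlled scenes,
not segmentation performance on clinical photographs.

## Problem sizes

The test suite and the acceptance script run on scaled-down rasters
chosen to exercise every code path with comfortable margins: 256×256
scenes with K = 200 (the same pixels-per-superpixel density as
1000×750 at K ≈ 860) for segmentation checks, 96–128 px scenes for
bulk invariant sweeps, 20 piecewise-constant scenes for boundary
recall, 50 seeds for generator statistics.

## Known limitations

* SLIC here is the plain formulation; no LSC/SEEDS-style variants, no
  GPU path.
* The decision rules are boolean; no regression model for "potential
  infection" severity.
* Wound size assumes a planar wound perpendicular to the optical axis;
  depth and curvature are out of scope.
* EXIF orientation and non-sRGB color profiles are not handled.
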