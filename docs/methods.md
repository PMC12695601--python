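# Methods

This note documents the models, conventions and design choices behind
`ciliascope`, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic validation does and does not
show.

## Image model and normalization

Input frames are 16- or 24-bit RGB TIFFs from confocal microscopy
(typical acquisition sizes ~2024–3168 px per side): blue carries the DNA
counterstain, green and/or red the ciliary membrane marker. Intensities
are normalized by the **dtype maximum** (255 or 65535), never by the
per-image maximum, so that configured thresholds mean the same thing
across images. The `red+green` channel option combines the two marker
channels by pixel-wise **maximum**; a sum would leave the [0, 1] range
and bias bright double-stained pixels.

## Cilia detection

The fixed stage order is: channel selection → CLAHE → Gaussian → white
top-hat → Yen threshold → 8-connected components → geometry → refinement.

- **CLAHE**: applied to the normalized channel, 8×8 tile grid, clip limit
  0.01 (fraction-of-histogram convention). The published parameter set
  does not constrain these two values; both are exposed in the
  configuration (`clahe_tile_grid`, `clahe_clip_limit`).
- **Gaussian**: reflective boundaries, kernel truncated at 4σ. Default
  σ = 8 px, matched to the filament width at acquisition resolution.
- **White top-hat**: image minus its opening with a discrete disk
  (pixels within Euclidean distance ≤ radius). Default radius 13 px.
  The output is non-negative and pointwise ≤ the input (anti-extensivity
  of the opening); this is what removes the illumination gradient.
- **Yen threshold**: computed on a 256-bin histogram of the enhanced
  image; pixels **strictly above** the threshold are foreground. A
  constant image is degenerate and yields an empty mask. The
  implementation is cross-checked in the tests against an exhaustive
  maximization of Yen's entropic-correlation criterion; floating-point
  near-ties between adjacent histogram bins are resolved arbitrarily and
  accepted by the oracle when the achieved criterion equals the maximum.
- **Connectivity**: components use 8-connectivity by default (4 is
  configurable); thin diagonal filaments fragment under 4-connectivity.
- **Geometry**: the ellipse is the region's normalized second central
  moments ellipse; eccentricity `sqrt(1 − (b/a)²)`; perimeter uses the
  Crofton 4-direction estimate (pinned so the form factor
  `4πA/P²` is reproducible; CellProfiler-style alternatives can be
  swapped behind the same record). Single-pixel regions are degenerate:
  axes and skeleton 0, eccentricity 0; default thresholds remove them.
- **Skeleton length**: medial axis of the region (computed with a fixed
  tie-break seed — the library implementation otherwise breaks
  skeletonization ties randomly, which would violate determinism), then
  the longest shortest path between degree-1 skeleton pixels on the
  8-connected graph with weights 1/√2. Regions whose skeleton is a
  cycle (no endpoints) fall back to the all-pairs geodesic diameter.
  Two systematic biases of this estimator are worth knowing:
  the (1, √2)-weighted digital path overestimates continuous length by
  up to +8.2 % at orientations near 22.5°, and the thresholded mask
  extends slightly beyond the filament ends (a smoothing halo), adding
  roughly 2–4 px. On the synthetic benchmark this totals a mean
  absolute length error of ~6.5 %.
- **Refinement**: candidates are kept iff skeleton length ≥
  `CILIA_MIN_LENGTH` AND area ≥ `CILIA_MIN_AREA` AND eccentricity ≥
  `CILIA_MIN_ECCENTRICITY` AND perimeter ≥ `CILIA_MIN_PERIMETER` (all
  inclusive); `EXCLUDE_EDGE_CILIA` additionally drops border-touching
  candidates. "Length" means the skeleton length by default; a
  `length_measure` switch selects the ellipse major axis instead, since
  either reading of the published minimum-length parameter is
  defensible. All features are computed first, then filtered once.
  The published defaults (length 14, area 256 px², eccentricity 0.46,
  perimeter 67 px) are shipped as-is; note that one published analysis
  run used length 10 / area 25 instead — the defaults and any per-run
  values are deliberately kept separate concerns here.

## Nuclei segmentation

The branch follows the published protocol around the model: blue channel
→ bilinear resize to 512×512 → backend → flow-error filter → size/edge
post-filter → nearest-neighbor rescale to original coordinates.

The original tool's backend is a U-Net fine-tuned from a flow-based
segmentation model; re-training it is out of scope and requires its
weights. The `SegmentationBackend` protocol mirrors its I/O (512×512
gray in; label map plus per-instance flow errors out), so such a model
can be plugged in unchanged; instances with flow error >
`CELLPOSE_FLOW_THRESHOLD` (default 0.4) are then discarded. The shipped
**baseline backend** is a deterministic classical watershed: Gaussian
(σ = 2 at working resolution) → Otsu → hole filling → Euclidean distance
transform, lightly smoothed (σ = 1.5) so integer-valued plateaus keep a
single regional maximum per convex blob → maxima at least 10 px apart as
markers → watershed on the negated distance. It reports zero flow error
for every instance, so the flow threshold has no effect on it. Blank
channels yield zero instances, not an error.

Post-filtering removes instances **strictly below** `CELLPOSE_MIN_SIZE`
pixels (default 15, at the 512×512 working resolution, where the filter
runs) and optionally border-touching instances, then relabels
consecutively. It is idempotent. Mitotic figures are excluded only
implicitly — via the size filter and the blob model — not by a
classifier.

## Aggregated per-image features

- nuclei number; area of nuclei = 100·Σ(nucleus px)/(H·W).
- **individual nucleus area ratio** = area-of-nuclei % ÷ nuclei number,
  i.e. the mean nucleus area expressed as % of image area. (A
  per-nucleus-to-total-nuclei reading of the name is arithmetically
  inconsistent with the ratio-times-count identity this definition
  satisfies; the identity is enforced in the tests.)
- cilia number; % of cilia within cells; mean nearest centre-of-mass
  and boundary distances (means over cilia of the minimum over nuclei).
  Boundary distances use 4-connected inner-boundary pixel sets and a
  KD-tree nearest-neighbor query — equivalent to brute-force pairwise
  minimization.
- **"within a cell"** has no canonical geometric rule when only nuclei
  are segmented. Convention here: the cilium centroid lies within the
  union of nucleus masks dilated by `within_cell_radius`, default the
  median nucleus equivalent diameter of the image (a proxy for the cell
  body). The resulting percentage is therefore convention-dependent and
  is not compared against any external reference.
- Ratios and distances are reported as missing (`None` / empty CSV
  cell) when the instance set they need is empty — never as 0.
- Distances are in pixels; setting `pixel_size` (µm/px) additionally
  reports cilium lengths in micrometres. No default conversion factor is
  assumed.

## Evaluation metrics

AP is the **set-level** quantity TP/(TP+FP+FN) at a fixed IoU threshold,
not a precision–recall-curve integral. Matching is greedy one-to-one by
descending IoU with ties broken on (lower predicted id, lower truth id);
at thresholds ≥ 0.5 two disjoint truth instances cannot both clear the
threshold against one prediction, so greedy matching attains the optimal
assignment cardinality (verified against a Hungarian-assignment oracle
in the tests). Background never participates. Conventions for empty
inputs: empty prediction *and* truth give AP = precision = recall =
F1 = 1; any other division by zero yields a missing value with a
warning. CNR is undefined (missing) for an empty ground truth.

## Synthetic scenes and what passing tests show

The generator emulates the stain layout of the real preparations —
elliptical blue nuclei, thin green/red filaments placed near nucleus
perimeters (mirroring the juxta-nuclear origin of cilia), a constant +
linear-gradient + Gaussian-noise background, with one global seeded
random stream. Defaults: 512×512 frames, 15 nuclei (semi-major axis
14–26 px), 8 filaments of arc length 60–90 px, width 3 px, curvature
0–0.02 rad/px, background 0.06, gradient 0.05, noise SD 0.01. The
512×512 frame is a scaled-down stand-in for the ~2024–3168 px
acquisition frames, chosen so the full benchmark runs in seconds;
`fixture_detection_config` derives matched pipeline parameters:
refinement minima scale linearly with the frame (areas quadratically),
while the smoothing scale tracks the filament width (σ = width/3,
floored at 1 px) and the top-hat radius covers the smoothed filament
cross-section (`ceil(width/2 + 2σ)`).

The scenes deliberately exercise the gradient-removal role of the
top-hat and curved-filament length measurement. They do **not** contain
out-of-focus light, a point-spread function, touching or interrupted
cilia, mitotic figures, apoptotic bodies, or marker-negative cells;
recovery rates of 100 % on these fixtures therefore validate the
pipeline's mechanics and calibration logic, not its accuracy on real
micrographs. Touching cilia are merged and interrupted cilia split by
construction of the connected-components step — the known limitation
that requires manual editing in practice.

## Numerical conventions and degenerate inputs

- All stages are shape-preserving and bit-deterministic; a repeated run
  on the same bytes and configuration reproduces outputs exactly.
- Thresholds: refinement minima are inclusive (≥); the nucleus size
  filter is exclusive (< min is removed); Yen masks are strictly above.
- Constant images: CLAHE and Gaussian return them unchanged; top-hat
  returns zeros; Yen flags them degenerate (empty mask).
- Label maps: 0 is background; instance ids are unique but need not be
  consecutive on input; post-filtered nuclei are relabeled from 1.
- Stacked per-instance binary `.npy` masks are flattened to a label map
  by slice index + 1.
- One failed image in a folder run is recorded in the manifest and does
  not abort the run.

## Benchmark sizes

The acceptance script uses 12 noise-free cilia scenes (96 filaments)
and 10 well-separated nuclei fields per run; the test suite adds 20
recovery scenes and the oracle-equivalence batteries (200 random masks,
100 matching layouts, 50 histograms, 50 moment blobs). These sizes keep
the whole benchmark around half a minute on one CPU while leaving the
measured quantities stable to well under a percent across seeds.
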