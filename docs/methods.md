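# Methods

`pocusalign` aligns two point-of-care ultrasound (POCUS) views of the same
pediatric forearm bone — typically the dorsal and palmar longitudinal scans
of the distal radius — into a single lateral-X-ray-like picture on which
fracture angulation can be read. This note documents the model, the
numerical choices, and what the synthetic testbed does and does not show.

## Problem setting and coordinate conventions

Each view arrives as a binary mask of the segmented echogenic bone
boundary (segmentation itself is a pluggable upstream step; any method
producing a single boundary stroke works). All computations use the image
frame: origin at the raster's top-left, x rightward, y downward, and
physical millimetres (pixel index × spacing). Rotations are
counter-clockwise in this y-down frame. The two views image *opposite
cortices* of the same bone and are mirrored relative to each other, so the
view-to-view map is modeled as a horizontal flip (about x = 0) followed by
a rigid motion `(θ, tx, ty)`, represented as a homogeneous 3×3 matrix. The
transform is deliberately restricted to rigid-plus-flip rather than a
general affine map: every alignment constraint below is satisfiable
rigidly, and admitting scale would let the energy collapse the geometry.

## Landmarks

Three sparse landmarks summarize each boundary:

* `L_p` — the physis (growth plate) point, the lower-left extremity where
  the echogenic line breaks at the cartilaginous plate;
* `L_d1` — a diaphysis point in the right part of the long near-horizontal
  shaft segment;
* `L_d0` — a diaphysis point about 2–3 cm proximal of `L_d1` along the
  boundary (default 25 mm, configurable within [20, 30] mm, measured as
  arc length).

Extraction pipeline: largest connected component → skeletonization to a
one-pixel curve → spur pruning (branches under 2 mm) → a two-endpoint
check → ordered traversal from the leftmost endpoint → mm polyline. The
shaft run is found with a sliding arc-length window (default 15 mm) whose
principal direction must lie within `horizontal_tol_deg` of the x-axis;
`L_d1` sits at the 90th percentile of x inside the longest run (percentile
rather than endpoint placement keeps the metaphyseal flare from
contaminating the point), and `L_p` maximizes `y − 0.2·x` within the
leftmost 35 % of the x-range ("lower" dominates, the small x-term breaks
ties toward "left"). All rules are deterministic; ties resolve to the
first occurrence in traversal order.

`horizontal_tol_deg` defaults to 25°. The probe orientation of the
opposite view can tilt its shaft by up to ~20° in the native frame, and a
tolerance equal to the worst-case tilt would make shaft detection
borderline; 25° still rejects the metaphyseal flare, which descends at
≥ ~27° for realistic flare proportions. A mirrored boundary (physis on the
right, as in the un-flipped opposite view) is handled by
`physis_side="right"`, which mirrors the rule set exactly.

## Pose estimation

With fixed landmarks `L^f` and moving landmarks `L^m` (already mirrored),
the pose minimizes `E = w_a·C_a + w_o·C_o + w_p·C_p`:

* **Latitudinal** `C_a = w_x·|L^f_{p,x} − T(L^m_p)_x| + w_y·|d − L^f_{p,y} + T(L^m_p)_y|`
  — the two physis points share their x-component and differ in y by the
  offset `d` (the bone's thickness separates the imaged cortices).
* **Orientation** `C_o = ‖i^f_d − i^m_d‖` with `i_d` the unit diaphysis
  direction `(L_d0 − L_d1)/‖L_d0 − L_d1‖`, the moving one taken through
  the linear part of `T` and normalized by the untransformed length —
  the shafts must be parallel. Ranges over [0, 2] for rigid `T`.
* **Position** `C_p = | |(T(L^m_{d,mid}) − L^f_{d0})·n^f| − w |` — the
  distance from the transformed moving shaft midpoint to the fixed shaft
  line must equal the bone width `w` (`n^f` is the unit normal of
  `i^f_d`). Without this term the first two admit a degenerate optimum
  with both shafts collinear. At `w = 0` the term reduces to the plain
  point-to-line distance.

Defaults: `w_x = w_y = w_a = w_o = w_p = 1` (all terms are then of order
millimetres except the dimensionless `C_o`; the mix is deliberate and
documented rather than rescaled), `d = 10 mm`, and `w` defaulting to `d` —
in a pediatric distal radius the physis offset and the bone width are the
same distance, and both are exposed in the config.

**Optimizer.** Plain fixed-step gradient descent, learning rate `5e-2`,
10 000 iterations, gradients by central finite differences (step `1e-4`).
The absolute values make `E` piecewise smooth; the symmetric difference
evaluates to zero at a symmetric kink, so an exact optimum is a fixed
point of the iteration. Two conditioning choices matter:

* The descent runs in a frame centered on the moving landmarks, with θ
  scaled by the RMS landmark radius. Without this, the θ-gradient scales
  with the lever arm to the image origin (tens of mm) and a constant-step
  method oscillates by radians. The returned `(θ, tx, ty)` are converted
  back to the image-origin parameterization exactly.
* The returned transform is the best-energy iterate (the standard
  convention for constant-step subgradient methods), which also guarantees
  final energy ≤ initial energy. Strided per-iteration traces of
  `E, C_a, C_o, C_p, θ, tx, ty` are recorded.

**Initialization.** The default (`init="aligned"`) is the closed-form
landmark prealignment: rotate so the diaphysis directions coincide
(`C_o = 0`) and translate the physis onto its offset target (`C_a = 0`).
This choice is load-bearing: the energy has a mirror local minimum —
around the pinned physis, the circle of possible shaft midpoints meets the
"distance w from the fixed shaft line" constraint twice, and only the
weak `C_o` term distinguishes the two — and a descent started from a
plain physis-to-physis translation reliably falls into the wrong
intersection. Starting inside the correct basin, the literal fixed-step
descent refines to the optimum. `init="physis"` (zero rotation,
physis-to-physis translation), `init="identity"` and explicit
`(θ, tx, ty)` triples remain available.

The flip is decided before optimization (a discrete choice cannot be
descended upon); `optimize_alignment(..., pre_flip=True)` mirrors the
moving landmarks and records the flip in the returned transform.

## Fusion, angulation, evaluation metrics

The moving image is resampled into the fixed frame by inverse-mapped
interpolation (bilinear for gray images, nearest for masks) on a canvas
covering the union of both extents plus a 5 mm margin; the fused view
keeps the two channels separate (fixed → red, moving → green) rather than
compositing, since no blending rule is clinically established.

Angulation follows the standard reading protocol: the unsigned acute
angle, in degrees, between a bone-axis segment and the perpendicular to a
growth-plate segment; intact anatomy (shaft ⊥ physis) reads 0°. The
measurement is rigid-invariant and symmetric in endpoint order; a signed
variant (sign of the cross product in the y-down frame) is available
behind a flag. The growth-plate direction is an input — readers draw it —
not estimated from the image.

Alignment quality is quantified with the directed Hausdorff distance and
a Chamfer distance between resampled boundary contours (default step
0.5 mm). Several Chamfer normalizations circulate; the default here is the
symmetric mean of linear nearest-neighbor distances, which lives on the
same mm scale as the Hausdorff distance. Sum and squared-mean variants are
selectable, and the choice is a package convention, not a claim about any
particular published variant.

## Reader-study statistics

The bundled fixture holds the raw readings of a dual-modality morphology
study: three blinded readers measured fracture angulation and classified
fracture type (buckle / greenstick / none) on 11 matched fused-POCUS and
lateral X-ray image pairs. From the raw table the package computes:
per-sample reference angulation (mean of the three X-ray readings,
rounded to one decimal), per-reader per-modality MAE against the reference
excluding samples whose reference is "no fracture" (samples 1, 2, 6, 8),
the mean POCUS-minus-X-ray MAE gap, the Pearson correlation between
pooled POCUS absolute errors and the reference angulations, majority-vote
ground-truth labels, and mean classification accuracy per modality.

Two conventions are applied uniformly because they make every derived
statistic self-consistent with the raw readings: a "no fracture" reading
counts as 0.0° wherever a number is needed, and references are rounded to
display precision (one decimal) *before* errors are computed. Per-cell
classification labels are not shipped — only the per-reader accuracies
and the majority-vote ground-truth column — since the correctness marks
are not reliably machine-readable; `majority_vote` operates on
caller-supplied labels.

## Synthetic phantoms

`generate_pair` builds both views of a distal-radius-like geometry with
full ground truth: a 60 mm near-horizontal diaphysis, a steeper
metaphyseal flare (4 mm × 4 mm) descending to the physis tip, a 3 mm
physis gap, and a 6 mm epiphysis stroke beyond it; the opposing view is
the same curve offset by the 10 mm bone width, mirrored, and displaced by
a seeded random rigid pose (|θ| ≤ 20°, |t| ≤ 20 mm), each rendered as a
~0.5 mm-thick stroke at 0.1 mm/px. Dimensions approximate a pediatric
distal radius in a 6 cm scan window and are engineering choices. Fracture
angulation tilts the distal fragment (and its growth plate) about the
metaphyseal junction, so the ground-truth angulation is exact by
construction. The recorded transform zeroes all three constraints at
`d = w = bone width` up to floating-point error, and the ground-truth
landmarks are the documented extraction rules applied to the continuous
curve, so mask-based extraction error isolates rasterization and
skeletonization effects.

`corrupt` stresses robustness: spatially correlated Gaussian jitter
(control points every 3 mm, linearly interpolated — segmentation error is
smooth along the boundary, and white per-vertex noise would merely
destroy the stroke topology) and contiguous dropout of part of the curve,
with ground truth left untouched.

What the phantoms do **not** emulate: speckle, shadowing, and intensity
artifacts of real ultrasound; curvature and cortical irregularity of real
bone; segmentation failure modes of a learned model; out-of-plane probe
deviation, which in real acquisitions makes the two views images of
slightly different planes. Passing phantom tests therefore demonstrates
the geometric correctness and numerical stability of the pipeline, not
clinical accuracy on patient images.

## Problem sizes and determinism

The pose-recovery experiment uses 50 seeded noiseless phantom pairs; the
mask-to-fusion pipeline evaluation uses 8 pairs at 0.15 mm/px and reports
mean Hausdorff/Chamfer distances between the aligned and ground-truth
moving boundary; angulation is checked on 5 phantoms at 12°. Every
random draw flows from a single seeded NumPy generator, and identical
inputs yield byte-identical transform JSON and trace CSV outputs.

## Known limitations

* The landmark rules assume a roughly horizontal shaft with the physis on
  a known side; heavily rotated acquisitions need the `physis_side` /
  tolerance knobs.
* The constraint weights and the physis offset `d` are not identifiable
  from a single pair; they are clinical priors exposed as configuration.
* Angulation on fused views still requires a manually drawn growth-plate
  direction.
* The energy mixes mm-valued and dimensionless terms with unit default
  weights; reweighting changes the optimum when constraints conflict
  (they do not on noiseless phantoms, where all three vanish jointly).
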