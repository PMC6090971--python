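# Methods

This note documents the model behind `pectoseg`, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic phantoms do and do not demonstrate.

## The segmentation model

The pipeline treats pectoral-muscle removal as a sequence of set operations
on rasters rather than a line-fitting problem.

**Intensity domain.** All computation happens on float64 intensities in
[0, 1] (readers divide by 2^depth - 1). This makes the edge threshold
tau in (0, 1) meaningful across 8- and 16-bit sources, and it makes the
"preserve original intensities" steps exact: masking is a pointwise product,
so pixels inside a mask survive bit-exactly.

**Label removal.** The breast is assumed to be the largest bright connected
region; labels/markers are small disjoint blobs. Binarization is Otsu by
default (data-driven, no tuning) with a fixed-threshold fallback for images
of known intensity make-up. Connectivity is 8; components touching the
border are never discarded, because the breast always touches the chest-wall
border. The operation is idempotent: re-running it on its own output
reproduces the same mask.

**Gradient and edges.** The 3x3 Prewitt pair is the default operator;
Sobel differs only in its center-row weighting and is exposed as an option.
Convolution is true convolution (kernel flipped relative to correlation)
with edge-replicated borders — zero padding would synthesize a strong frame
edge exactly where the breast is flush with the border. The magnitude field
is globally renormalized to max 1 before thresholding, with gx, gy and the
L1 magnitude divided by the same factor so the norm inequalities
`mag <= l1 <= sqrt(2) mag` survive. A magnitude maximum below 1e-12 is
treated as exactly zero: dividing by a rounding-level maximum would amplify
float noise into spurious unit edges on flat images. The angle uses the
two-argument arctangent; the one-argument form loses quadrant information
and divides by zero on horizontal gradients.

**Threshold selection.** tau is chosen from the accumulative histogram of
the normalized magnitude: the largest value such that the fraction of
pixels strictly above it does not exceed `edge_fraction` (default 0.10,
chosen as a generous ceiling — on typical images the actual edge fraction
is far lower and the threshold lands on the zero/nonzero boundary). When
that quantile is 0 (large perfectly flat background), tau is placed just
below the smallest positive magnitude: the maximal admissible pass-set that
still keeps tau inside (0, 1).

**Closing.** Disk radius defaults to 5 px at 1024-row scale and is scaled
proportionally with image height (minimum 1). Border policy: outside pixels
are background for dilation and foreground for erosion. This is the
convention under which a full mask erodes to itself and closing is
extensive, idempotent and monotone up to the image frame; padding erosion
with background instead would shave every border-touching region and break
extensivity exactly where mammograms need it most.

**Hull and silhouette.** The topographic map collects, for each occupied
row of the closed edge map, its leftmost and rightmost pixel, and for each
occupied column its topmost and bottommost pixel. The convex hull of these
points (Qhull) is rasterized and intersected with the body mask. One
addition is needed: where the breast is flush with the image frame the
replicated-border convolution is gradient-silent, so the skin line's
continuation along the frame never appears in the edge map and the hull
would clip border-flush breast margins. Body-mask pixels lying on the frame
are therefore added to the hull's feature set.

**Pectoral boundary.** Candidate boundaries are 8-connected components of
the closed edge map that reach both the top border and the chest-wall
border (within a small margin) and descend at least 1/8 of the image height
— the span floor rejects corner noise specks that touch both borders
trivially. Two pipeline-level details make the search well-posed:

* The skin line itself runs from the top border to the chest-wall border
  and carries the strongest gradient, so the search is restricted to edges
  in the interior of the body mask (mask eroded by `close_radius + 4`).
  The outer boundary is recovered by the hull, not by this search.
* Among candidates, the largest mean gradient support wins, ties going to
  the smaller component. The returned curve is the component's rightmost
  column per row, top to bottom — a free curve, not a fitted line, so bowed
  boundaries are followed as-is.

Removal is row-wise: for every row the curve spans, pixels strictly left of
the curve are cut. The largest connected component of what remains is the
silhouette. The removed region is reported as the pectoral mask, restricted
to components that overlap the cut wedge (pixels lost purely to hull
rasterization are not muscle). An empty curve is a valid outcome and means
a pectoral-free image: nothing is removed and the pectoral mask is empty.

**Orientation.** All of the above assumes the pectoral corner is top-left.
Right-MLO inputs are mirrored before processing and all rasters mirrored
back, so the pipeline is exactly equivariant under horizontal flips. Auto
detection compares foreground mass in the two image halves.

## Evaluation

FP% is the false-positive pixel count relative to the ground-truth
*negative* region, FN% relative to the ground-truth pectoral region; the
(FP%, FN%) plane is tiled by six category bins with left-closed boundaries
at 5% and 10% (a seventh residual bin exists for totality but is
unreachable). The Hausdorff distance is the symmetric max-min Euclidean
distance between the inner boundary pixel sets of the two regions,
converted to mm with a configurable pixel spacing (default 0.2 mm/px, the
200-micron digitization of classic screen-film scans); the one-directional
variant is available via `directed=True`. The visual grade maps the
fraction of ground-truth muscle left inside the silhouette to three levels:
<= 1% successful (the 1% allows for rasterization of the boundary), >= 50%
unacceptable (half or more of the muscle kept), acceptable in between.
Cohort summaries use per-image means of the percentages and the population
standard deviation for the Hausdorff distance.

Image-quality metrics (MSE, PSNR, SSIM) are provided for ranking edge
operators. SSIM is the product of luminance, contrast and structure terms
with exponents alpha = beta = gamma = 1, computed globally by default (a
sliding-window mean is available), stabilized by
e1 = (0.01 peak)^2, e2 = (0.03 peak)^2, e3 = e2/2, and clamped to [0, 1].
The structure term uses the standard form (sigma_xy + e3) /
(sigma_x sigma_y + e3); this is the only choice under which SSIM(x, x) = 1
holds, which the metric's contract requires.

## Phantoms

A phantom paints, in order: background (0.03), a half-elliptical breast
body (0.52) flush with the chest-wall border and reaching the top border
near the corner, a triangular pectoral wedge (0.78) whose boundary chord
makes a 45-90 degree angle with the top border (default 65 degrees,
optionally bowed by a sinusoidal `curvature` term), and 2 small label
rectangles (0.95) in the background strip; optional additive Gaussian noise
is clipped to [0, 1]. The intensity ordering pectoral > breast > background
reflects the radiographic appearance of the muscle as the brightest large
structure. Masks are the exact pre-noise paint rasters, so at sigma = 0
they partition the image by intensity level exactly. Mirroring is applied
after noise, so a right-oriented phantom is the exact mirror of its
left-oriented twin at every noise level.

The default size is 256x256 (not the 1024x1024 of real scans) so the whole
test suite and the acceptance script run in seconds; every radius and
margin in the pipeline scales with image height, so behavior is
representative. Cohorts draw per-phantom jitter (typically the pectoral
angle over its full 45-90 degree range) and per-phantom child seeds from
one master seed, making them fully reproducible.

**What phantom results do not show.** Phantoms have piecewise-constant
tissue, no fibroglandular texture, no scanner blur, no skin-line intensity
falloff. Passing the phantom suite demonstrates that the geometric and
morphological logic of the pipeline is correct, and that it degrades
monotonically with noise (the cohort-level FP+FN error at sigma = 0 never
exceeds that at sigma = 0.1). It does not certify clinical performance on
real mammograms: at sigma = 0.05 the pipeline still recovers the wedge to
within ~1-2% FP+FN, while at sigma = 0.1 the edge map is noise-dominated
and the boundary search typically finds no admissible candidate, leaving
the muscle in place (FN 100%) rather than cutting unpredictably.

## Degenerate inputs and tie-breaks

Fewer than 3 foreground pixels, or a collinear foreground, has no 2-D hull
and raises a geometry error. A constant image has no foreground after
binarization and fails label removal. A constant gradient magnitude admits
no separating threshold. An empty point set has no Hausdorff distance. An
empty ground-truth pectoral region leaves FN% and the grade undefined. All
of these raise typed errors rather than returning sentinels; an empty
pectoral *curve* is the one deliberate non-error (pectoral-free images are
legitimate). Candidate ties in the boundary search are broken by component
size (smaller wins), making the pipeline deterministic end to end; the
`seed` field in the pipeline config is reserved and currently unused.
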