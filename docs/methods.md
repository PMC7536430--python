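# Methods

## The selection model

A slide is a rectangle of `width_px x height_px` pixels at isotropic
resolution `mpp` microns per pixel (default 0.25, the common 40x scanner
setting), with coordinates 0-based, origin top-left, x rightward, y
downward. All rectangles are half-open, `[x0, x1) x [y0, y1)`. The FOI is
the standard 10-HPF counting area, 2.37 mm² at 4:3; its pixel dimensions
solve `w*h = area/mpp²` and `w:h = aspect`, each rounded to nearest (at WSI
resolutions the induced area error is below 0.1 %; at very coarse
resolutions the 0.1 % bound is not attainable by any integer pair). Windows
are anchored by their center, with the top-left corner at
`center - floor(dim/2)`.

The position-dependent ground-truth mitotic count is evaluated on a regular
grid of candidate centers (default stride 50 px at full resolution — far
below the window dimensions, so the discretization error of the maximum is
small). The windowed count map is computed with an integral image over a
point-count histogram whose bin edges are the union of all clipped window
edges; because every window boundary coincides with a bin edge, each count
is a four-corner lookup and integer-exact, at O(n log n + rows·cols) total
cost. Windows at the slide border are clipped (the valid mask removes those
centers anyway; clipping keeps the map consistent with the total count). The
ground-truth window uses the 4:3 FOI shape itself (configurable; a square of
equal area is an alternative convention).

The valid mask restricts candidates to windows fully on-slide whose tissue
fraction is at least 0.95 (inclusive). Tissue is segmented on a
low-resolution render (default downsample 32) by Otsu thresholding of the
grayscale image — parameter-free and standard for H&E material; the channel
is configurable since saturation or optical density are equally defensible —
followed by morphological closing with a disk of radius 5 at that scale
(~160 px at full resolution) to bridge small gaps. Window coverage is then
an integral-image lookup on the downsampled raster with edges rounded to
downsampled pixels, so the boundary is quantized to one low-resolution
pixel. A uniform render (no contrast) yields an all-background mask with a
warning rather than an arbitrary split.

Selection takes the estimator's density map, applies the 10-HPF moving
average when the map holds raw per-patch estimates (valid-mode mean filter
with kernel `ceil(window/stride)` grid cells; identity when the estimator
already emits windowed counts, as all built-in estimators do), masks by the
valid mask, and returns the argmax. Ties break to the smallest row, then
column index — the paper-level convention is unspecified and determinism is
required. The argmax is invariant under `a*est + b` for `a > 0`, which is
why a consistently biased estimator still selects the right window.

## Training targets

The regression target counts figures fractionally at patch borders. A figure
is modelled as an axis-aligned `d x d` box around its center (`d = 50` px at
0.25 µm/px, i.e. 12.5 µm, matching the segmentation circle diameter; the
diameter is nowhere fixed numerically by the counting conventions, so it is
configurable). The per-axis weight is the continuous trapezoid
`gamma(x) = clip(d/2 - x, 0, d)` of the signed offset `x = |p| - w/2`; the
printed piecewise conditions for this weight overlap and cannot all hold
simultaneously, and the trapezoid is the unique continuous resolution — it
makes each summand of the target exactly the fractional box overlap with the
patch, which is the stated purpose of the construction. `beta = 10`
normalizes the target into a range convenient for a sigmoid output head.
Segmentation targets are unions of filled discs of diameter `d`; a pixel is
set iff its center is within `d/2` of a figure center. The patch sampler
draws from three groups — containing a mitosis, containing a hard negative,
unconditioned — with rotation uniform in `[0, 2pi)` applied about the patch
center before cropping; containment is evaluated in the rotated frame, and
"fully on slide" is enforced via the patch's bounding circle. Training patch
size defaults to 512 x 512 (unstated upstream; a common detector input size).

## Estimators

The oracle is the windowed count of the true mitosis annotations — the upper
bound any estimator approaches. The noisy oracle drops each true figure with
probability `fn_rate` and adds false positives as a Poisson process at
`fp_per_mm2` over tissue; the drop uniforms are drawn before the
false-positive draws from a seed independent of `fn_rate`, so runs sharing a
seed have nested retained sets (common-random-numbers coupling, chosen to
make regret curves comparable across miss rates). Detection lists are
thresholded on the first-stage score and, where present, the second-stage
score (defaults 0.5/0.5; operating points are deployment-specific), then
counted like annotations. Segmentation rasters are converted by dividing the
segmented area in each window by the area of one ideal figure disc,
`pi*(d/2)²`. Non-maximum suppression is assumed already applied to
detection inputs.

## Evaluation statistics

Pearson's r is the default correlation (the variant is a convention;
Spearman is provided as an option). Cohen's kappa uses the marginal-product
expected agreement with the degenerate convention kappa = 1 for perfect
agreement when `p_e = 1` (else 0). Grade groups: *clearly low* iff every
achievable count is below the threshold (default 7), *clearly high* iff
strictly more than 75 % of achievable counts reach it, else *borderline*.
Percentile scoring uses order-statistic (inverted-CDF) percentiles: a
selection is in the "upper 25 %" iff it is at or above the 75th order
statistic of the achievable-MC distribution — with linear interpolation a
selection equal to the 75th of 100 distinct values would fail its own
quartile, which contradicts the intended reading. Group summaries report
proportions with 95 % Wilson score intervals (well-behaved at proportions
near 0 or 1). Above-threshold agreement kappa is computed either against
ground truth (does the slide's maximal count clear the threshold) or
pairwise within a rater group; both readings of "agreement" are defensible,
so both are implemented, defaulting to ground truth.

## Synthetic data

The generator emulates the *statistical* structure of annotated tumor
sections, not their appearance: a patchy mitosis distribution inside an
irregular tissue region. Tissue is one principal disc centered on the slide
(guaranteeing room for at least one valid FOI) plus random satellite lobes,
rendered in H&E-like pink on white with a soft edge and mild noise so the
Otsu branch can segment it. Mitoses follow a Thomas cluster process
restricted to tissue — parents Poisson(`parent_rate`·area) uniform in
tissue, offspring Poisson(`offspring_mean`) per parent displaced by an
isotropic Gaussian of sd `cluster_sigma`, offspring falling off-tissue
rejected — plus uniform background mitoses and hard negatives. Expected
mitosis count is `(parent_rate*offspring_mean + background_rate) * area`
minus a small edge loss from the rejection (about 2–3 % at the default
spread; calibration checks carry that allowance). In the large-`sigma`
limit the thinned process approaches complete spatial randomness (quadrat
variance-to-mean ratio near 1), the standard sanity check for a cluster
process.

Defaults model a 2.5 x 2.0 mm slide (a 10x-scaled-down section) at
0.25 µm/px with rates placing the hottest windows near the grading
threshold: `parent_rate = 0.25 /mm²`, `offspring_mean = 8`,
`cluster_sigma = 150 px` (37.5 µm), `background_rate = 1 /mm²`,
`hard_negative_rate = 15 /mm²`. `SyntheticConfig.coarse()` represents the
same physical extents at 2.5 µm/px (1000 x 800 px, FOI 711 x 533 px), which
is what the test suite and the acceptance script use so that many hundreds
of replicate slides run in seconds; rates are physical and unchanged. The
planted-hotspot fixture places one tight cluster (sd = FOI min-dim / 12,
truncated to the central half of the window) at a randomly chosen valid grid
center and requires the hotspot count to exceed twice the expected
background window count plus five, so the hotspot window is the global
maximum with high probability.

What passing on synthetic slides does *not* show: robustness to staining
variation, scanner artifacts, necrosis or tissue folds (the render is a
two-tone cartoon), to annotation noise in real ground truth, or to the error
structure of real CNN detectors (the noisy oracle's misses are spatially
independent, unlike a detector's systematic failure modes).

## Numerical choices and degenerate inputs

Windowed counts and moving averages use float64 cumulative sums; counts are
integer-exact, means match brute force to 1e-12 at test sizes. The coverage
comparison uses `frac >= coverage - 1e-12` so a window at exactly the
threshold is valid regardless of float rounding. Empty point sets give zero
maps; an empty valid mask raises (there is no admissible FOI); zero-variance
inputs to the correlation raise rather than return NaN. All randomness flows
through `numpy.random.default_rng` seeded explicitly; identical configs
produce byte-identical annotation CSVs.

## Known limitations

- No multi-resolution pyramid or WSI (SVS) decoding: inputs are point
  annotations, low-resolution renders, and external model outputs.
- Isotropic pixels only.
- Single-FOI output (no top-k alternates).
- The CNN estimators themselves are out of scope; the adapters define the
  interface trained models plug into.
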