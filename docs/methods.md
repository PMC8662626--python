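# Methods

## Box-counting dimension on a voxel grid

For a structure S occupying voxels of a 3D array, the Minkowski–Bouligand
(box-counting) dimension is

    D_box(S) = lim_{eps -> 0} log N(eps) / log(1/eps),

with eps = 1/s the scaling factor of a cubic grid of box edge length s and
N(eps) the number of grid cells intersecting S. On a finite grid the limit
is estimated as the negative slope of an unweighted ordinary least-squares
fit of log10 N(s_k) on log10 s_k over a fixed schedule of box sizes. The
logarithm base cancels in the slope; base 10 is used for reported
residuals.

### Scale schedule

The default schedule is 20 box edge lengths, log-spaced as
`10**linspace(0.01, 0.9505, 20)` — identically `logspace(0.01, 1, 20,
endpoint=False)` — spanning s ≈ 1.023 to s ≈ 8.923 voxels with a constant
ratio of 10^0.0495 between consecutive scales. Twenty points balance fit
stability against cost: fewer points visibly perturb the estimate, while
more add time without moving it. Both endpoints and the point count are
configuration (`generate_scale_schedule`). Box edges at or below one voxel
are rejected rather than clamped: at eps >= 1 every occupied voxel becomes
its own box and the series degenerates to a flat ceiling that corrupts the
fit.

### Grid convention

Boxes are anchored at the index origin of the mask's bounding box: voxel
(i, j, k) belongs to cell (floor(i/s), floor(j/s), floor(k/s)), with
non-integer s supported directly. Along an axis of extent d the grid keeps
`max(1, ceil(d/s) - 1)` cells; the trailing cell, which only partially
overlaps the array, is folded into the last kept cell. Without this
boundary handling, partially covered boxes at coarse scales inflate N(s)
and bias the fitted dimension low on compact structures (a filled 64³ cube
fits at ≈ 2.94 instead of ≈ 3.02). Axes shorter than one box keep a single
covering cell, which is what lets sheet-like (d=1) masks fit cleanly.

The estimator (`estimate_fd` / `count_series`) first crops the mask to its
occupied bounding box, anchoring the grid at the region's own corner. This
makes the estimate exactly invariant to where a region sits inside the
array and to background padding — without it, padding a phantom into a
larger volume moved the estimate by up to 0.6. `count_boxes` itself counts
on the array as given, so grid placement stays inspectable.

No lattice offsets or overlapping grids are averaged; the single-grid
("traditional") box count is used.

### Linearity diagnostic

The root-mean-square residual of the fit (log10 N units) measures how well
a single dimension describes the structure. At or below the default
threshold of 0.05 the structure is flagged `fractal_ok`; above it,
`multifractal_suspect`, meaning a multifractal description may be needed.
The threshold is configurable, the flag is report-only, and no multifractal
spectrum is computed. R² is additionally reported, clipped to [0, 1] and
defined as 0 for a zero-variance response.

## Validation phantoms

Deterministic masks with known dimension make the estimator testable
without any imaging data:

| phantom        | construction               | analytic FD            |
|----------------|----------------------------|------------------------|
| filled_cube    | n³ solid                   | 3                      |
| slab           | n×n×1 sheet                | 2                      |
| line           | n×1×1 segment              | 1                      |
| menger_sponge  | level-L recursion, (3^L)³  | log 20 / log 3 ≈ 2.7268|
| random_blob    | thresholded smoothed noise | none (oracle use only) |

The sponge removes the six face centers and body center of each 3×3×3
block per level, giving exactly 20^L occupied voxels. Level 4 (81³,
160 000 voxels) is the largest default fixture: big enough for a stable
fit, seconds-scale to measure. Under the default schedule the estimator
recovers 3/2/1 within 0.05/0.10/0.10 at size 64 and the sponge dimension
within 0.15 at level 4; the residual gap is finite-size and grid
discretisation error, which shrinks with object size. The phantoms share
none of the morphology of real brain tissue — no partial-volume effects,
no segmentation noise, no anatomical anisotropy — so passing these
recovery tests validates the estimator's numerics, not its clinical
behaviour on MRI.

## Region pipeline

Segmentation output is a label volume: integer region identifiers 0–40,
background 0. Region masks are exact equality tests against a label; the
whole-brain mask is the union of all nonzero labels. Per session the
pipeline reports, for the whole volume and each requested region, the
voxel count, physical volume (count × voxel volume from the spacing), and
FD. FD is computed on the voxel grid and is dimensionless; anisotropic
spacing is flagged with a warning because the box grid is cubic in voxel
space. Absent regions yield an empty mask and a row without FD rather than
an error, keeping batch runs alive.

Multi-session comparison pivots the measures into a wide table (session
rows sorted by day, region columns) and appends a per-region relative
variation, (max − min) / mean × 100 %. The formula is a package choice —
other spread measures are defensible — and is exposed as
`relative_variation`.

Only four region labels ship as defaults (right thalamus proper 23, left
ventral DC 24, third ventricle 26, right putamen 27); other regions are
addressable through a user-supplied YAML/JSON label map, since label
assignments are a property of the upstream segmentation model.

## CDR session labeling and cohort assembly

Clinical Dementia Rating assessments and MRI sessions occur on different
days. A session is labeled by rule order: (1) if it lies between two
assessments with equal scores, that score applies at any distance; (2) if
between two assessments with different scores, the nearer score applies
only within the window (default 45 days), with equidistant conflicts
dropped as undecidable; (3) a session with assessments on only one side
takes the nearest score within the window. Everything else is dropped with
a recorded reason. Enlarging the window is monotone: it can only turn
drops into labels, never the reverse.

The cross-sectional cohort keeps exactly one labeled session per subject —
the earliest, a deterministic and defensible choice where any single
session would do — and maps CDR 0 to control and CDR ≥ 1 (at least mild
dementia) to the dementia class. CDR 0.5 falls in neither class under
these defaults and is excluded with a log message; both thresholds are
explicit `ClassPolicy` configuration because reasonable studies differ on
where very mild impairment belongs.

## Classification

Per region, a support-vector machine on (volume, FD) features separates
the classes, evaluated by stratified k-fold cross-validation (default 5
folds, seeded shuffle) with metrics computed from the pooled test
predictions. Dementia is the positive class throughout. Defaults are an
RBF kernel with C = 100 and gamma = 6; a polynomial kernel with the same
hyperparameters is selectable. Features are standardized within each
training fold (fit on train, applied to test) — volumes in mm³ sit four
orders of magnitude above unit-scale FDs, and an unscaled RBF kernel is
degenerate on that geometry. The headline metric is F-beta with
beta = 8.25, weighting recall heavily so that false negatives in the
dementia class dominate the score; beta matches the class imbalance of the
cohort the defaults were designed around. If the minority class is smaller
than the fold count, folds are reduced with a warning rather than failing.

The synthetic feature generator draws brain-stem-scale Gaussians (volume
≈ N(21000, 900) mm³, FD ≈ N(2.55, 0.04)) and shifts the dementia class by
configurable multiples of each feature's spread. The defaults (2 sd in FD,
0.3 sd in volume) emulate the qualitative pattern of overlapping volumes
with better-separated FDs; shift 0 gives the no-signal null used to bound
chance accuracy, and 10-sd shifts give separable clusters for exactness
checks. The generator makes no attempt at realistic covariance,
heteroscedasticity, or cohort imbalance unless asked; classifier results
on it validate the cross-validation plumbing and metrics, not clinical
discriminability.

## Numerical and degenerate-input choices

- Empty masks raise `EmptyRoiError` at counting; absent regions are
  reported, not raised, one level up.
- Near-integer float volumes (|frac| ≤ 1e-6) are accepted and cast;
  anything else is rejected as not a label volume.
- Centered cropping drops the extra voxel of an odd margin on the
  high-index side; cropping is idempotent at the target shape.
- `.npz` volumes carry no header: spacing defaults to 1 mm isotropic, the
  array is read from key `vol` with a first-array fallback.
- Box-count monotonicity in s is not a theorem under non-nested grids
  (two voxels two apart can occupy one box at s=2 and two at s=2.5); it
  holds empirically for masks comfortably larger than the coarsest box and
  is tested there.
- Session ids round-trip with a four-digit zero-padded day; longer day
  numbers print unpadded and still parse.

## Problem sizes

Default test and validation sizes — 64³ Euclidean phantoms, the level-4
sponge (81³), 100 random masks up to 24³ for oracle equivalence, n = 200
synthetic feature rows — were chosen so the full validation cycle runs in
a couple of minutes on one CPU while keeping finite-size error well inside
the stated tolerances.

## Known limitations

- FD is computed in voxel units; strongly anisotropic acquisitions are
  flagged but not resampled.
- The single-grid box count retains grid-phase sensitivity at the level of
  boundary cells; bounding-box anchoring removes translation sensitivity
  but not all discretisation error.
- No multifractal spectrum, lacunarity, surface-based FD, or 2D slice-wise
  FD.
- `.mgz` volumes are expected to be converted to NIfTI or `.npz` upstream;
  native parsing of that format is out of scope.
- Printed reference FDs for real cohorts depend on the upstream
  segmentation model and scan data and are treated as plausibility anchors
  (whole-brain FD ≈ 2.95, regions ≈ 2.3–2.6), not reproducible targets.
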