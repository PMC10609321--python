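# Methods

## Measurement model

A fiber cross-section is represented by two closed simple polygons in
pixel coordinates: the outer wall boundary and the lumen boundary.
All physical quantities derive from these via a calibration scale
`s` (μm/px) obtained from a reference distance measured once per
imaging setup: areas scale by `s²`, lengths by `s`.

Per fiber, with outer area `A_outer` (lumen included), outer perimeter
`P`, and lumen area `A_lumen`:

* wall area `A_true = A_outer − A_lumen` (the subtraction is exact by
  construction, so `A_outer = A_true + A_lumen` always holds);
* degree of cell-wall thickening `θ = 4π·A_true/P²`. θ is 1 for a
  solid circular section and decreases with wall thinning and
  non-circularity. Note the deliberate asymmetry: θ combines the wall
  area with the *outer* perimeter, whereas the circularity of a single
  shape is `4π·A/P²` of that shape's own area and perimeter. Both are
  dimensionless and invariant under uniform scaling.
* fineness `F = ρ·A_true` with cotton cellulose density
  ρ = 1.52 g/cm³. One μm²·g/cm³ equals 10⁻⁸ g/cm, i.e. one millitex,
  so wall area in μm² maps directly to linear density in mtex. The
  definition uses the wall area, not the lumen area: linear density is
  mass per length and the mass sits in the wall. Every published
  reference value we reproduce is consistent with this definition.
* maturity ratio `M = θ/0.577`, normalizing θ against a
  standard-maturity reference fiber, and standard fineness
  `SF = 0.577·F/θ`, the fineness the fiber would have at standard
  maturity. The identities `M·0.577 = θ` and `SF·θ = 0.577·F` hold to
  machine precision and are asserted in tests.

Values are stored at full precision; rounding to 2 decimals happens
only in report-mode output. When recomputing published per-line values
from printed (2-decimal) inputs, agreement is therefore expected only
to one unit in the last place, and three of the twenty
fineness/maturity table entries indeed differ by exactly 0.01 —
consistent with their inputs having been rounded from fuller precision.

Per-line θ is always the mean of per-fiber θ values, never θ evaluated
at the line's mean area and perimeter; the two differ because θ is a
nonlinear function of its inputs (published line-level θ values are
consistent with per-fiber averaging, not with evaluation at the means).

## Segmentation

The classical pipeline assumes bright wall material on a dark
background (lumen interior dark):

1. luminance collapse (ITU-R 601) for RGB input, then Otsu or fixed
   thresholding. An empty or constant image is an error, not an empty
   result.
2. connected components above 500 px² (configurable) become fiber
   candidates; smaller components are debris. Interior background
   regions of at least 25 px² become candidate lumens; smaller holes
   are speckle and are filled.
3. boundaries are extracted by marching squares at level 0.5 on a
   Gaussian-smoothed (σ = 1.5 px) float rendering of each component
   mask. Raw binary-mask contours overestimate perimeters by several
   percent (staircase effect; pixel-edge perimeters by up to 4/π),
   which would bias θ and circularity low by ~10%. With the smoothed
   sub-pixel contours, areas are accurate to ~0.2% and perimeters to
   ~0.1% for fibers ≥ 200 px across, and a rendered circle measures
   circularity 0.997.
4. fibers are lettered A, B, C, … (then AA, AB, …) left-to-right
   within rows, rows top-to-bottom. Rows are formed by greedy banding:
   candidates whose box-center y lies within half the median box
   height of the row's first member join that row. Ties break by
   (x, y, area), making the lettering deterministic and invariant
   under input permutation — "left to right, top to bottom" alone is
   ambiguous for staggered layouts.

When a candidate has several holes, the largest is the lumen (fiber
anatomy has exactly one); the rest count as defect holes. Components
touching the image border are kept but flagged: a clipped fiber cannot
be measured.

Touching fibers are not split (no watershed) in this version; a merged
pair presents as one oversized, low-circularity component with two
lumens and is rejected by the quality rules, mirroring the manual
practice of excluding such fibers.

## Quality filtering

A rule set with generous bounds — roughly ±50% around the ranges
healthy mature fibers occupy — rejects gross defects while passing
natural variation: outer area 20–400 μm², outer circularity 0.30–0.85,
lumen required, at most 2 defect holes, border-touching rejected,
θ ≤ 1 + 0.01 (the isoperimetric limit plus discretization tolerance).
The verdict lists every failed rule; the score is the fraction of
applicable rules passed. Scoring is a pure function of (candidate,
measures, rules), and any callable with the same signature can replace
the rule engine, e.g. a trained classifier. Filtering preserves
letters so identities stay traceable, and is idempotent.

These defaults cannot claim equivalence to any particular manual or
learned annotation standard; they are the package's own operating
point, and every bound is configurable.

## Statistics

The inferential battery per metric, with cotton line as the factor:
optional per-line outlier trimming, descriptive summaries, one-way
ANOVA, unadjusted all-pairs pooled-variance Student's t, and all-pairs
Tukey–Kramer HSD:

    q_ij = |m_i − m_j| / sqrt( MSE/2 · (1/n_i + 1/n_j) )

with MSE the pooled within-group mean square and tail probabilities
from the studentized-range distribution at (k, N−k). With equal n the
Kramer standard error collapses to `sqrt(MSE/n)`, the classical Tukey
HSD; tests verify both the algebraic identity and agreement with an
independent HSD implementation. Equal variances are assumed
throughout, matching standard fixed-effects one-way practice.

The connecting-letters display assigns one letter per maximal clique
of the non-significance graph (Bron–Kerbosch enumeration, cliques
ordered by their best-ranked member with groups sorted by descending
mean), so two lines share a letter iff their difference is not
significant — a property asserted exactly for every generated report
and validated against brute-force clique enumeration for all 1024
significance patterns on five groups.

Outlier trimming defaults to the IQR rule (k = 1.5) per line per
metric, applied before ANOVA, because visual histogram-based culling is
operator-dependent; a z-score rule (default interpretation k·sd) is
available. Removed values are always reported, never silently dropped.
Fewer than 4 values per group skips trimming with a warning. No
multiple-testing correction is applied across metrics, matching the
workflow this mirrors.

## Synthetic scenes

The simulator emulates resin-embedded sections imaged in light
microscopy: 40–60 fibers per field, bright walls, dark lumens and
background, Gaussian sensor noise (σ = 6 grey levels), and optional
faint section-crease streaks.

A dried mature fiber collapses into a ribbon-like bean ("kidney"
shape). The model is an ellipse of axis ratio `aspect` with a single
cosine-squared radial dent of depth `dent_depth` on one flat side:
`r(φ) = r_ellipse(φ)·(1 − dent·sin²φ)` for `sin φ > 0`. Two parameters
control concavity and elongation; the lumen is the same shape scaled
inward by `1 − wall_thickness_fraction`, guaranteeing a hole strictly
inside the wall. An oblique cut is an anisotropic stretch of both
boundaries by `1/cos(tilt)` along a random in-plane direction, which
multiplies the apparent area by exactly that factor (asserted to
machine precision).

Population defaults, chosen once to sit inside the published per-line
ranges and kept fixed: mean wall area 130 μm² (log-normal,
CV 0.2), aspect uniform on [0.25, 0.35] and dent on [0.2, 0.6] —
calibrated so the mean rendered outer circularity is ≈ 0.55, matching
published line means of 0.51–0.58 — wall-thickness fraction
[0.62, 0.72] (lumen/outer area fraction ≈ 0.08–0.14), tilt ≤ 6°, and
0.1 μm/px so fibers span ~150–250 px. The outer radius is solved from
the drawn wall area, so the generated polygon's wall area equals the
draw exactly.

Defect kinds are defined relative to the quality rules: *folded*
fibers are extreme ribbons (aspect 0.06–0.10, dent 0.6–0.85) whose
outer circularity falls below the 0.30 floor; *oblique* fibers are
tilted so their apparent outer area lands in 450–600 μm², above the
400 μm² ceiling. Placement is random sequential (rejection sampling on
bounding circles, auto-sized canvas at ~20% circle coverage), and all
randomness flows from a single seeded generator: the same seed
reproduces a scene bit-exactly.

What the simulator does not model: optical point-spread and defocus,
uneven illumination, resin texture, touching or overlapping fibers,
partial sections, and SEM-specific artifacts. Passing tests therefore
demonstrate correctness of the geometry, measurement and statistics
chain under clean imaging, not robustness to every real-world nuisance;
on real micrographs the thresholding step and rule bounds may need
adjustment per setup.

## Validation design

End-to-end validation simulates five lines × 100 fibers (the scale of
a typical per-line study), runs segment → filter → measure on every
scene, and compares per-line means of wall area, θ and fineness to the
exact polygon ground truth, requiring agreement within 3%; measured
bias is in fact ~0.2–0.5%. The comparison to ground truth isolates
measurement error. The sampling error of a 100-fiber line mean at
CV 0.2 is ~2% by itself, so recovery of the *generating population*
mean is checked on the pooled 500-fiber sample, where sampling noise
(se ≈ 0.9%) no longer dominates the 3% band. Statistical power is
validated separately: a line shifted by one within-line standard
deviation separates from four null lines (n = 100 each) in ≥ 95% of
replicates, and the ANOVA's type-I error under a null simulation is
0.05 ± 0.02.

## Numerical choices and edge cases

* Contours are normalized counter-clockwise (positive shoelace in the
  image frame, x right, y down, 0-based) on ingest; repeated closing
  vertices are dropped; fewer than 3 points, zero area, or
  self-intersection raise errors.
* Degenerate inputs fail loudly: constant images, zero-variance ANOVA
  input, lumen area ≥ outer area ("lumen exceeds fiber"), nonpositive
  areas/perimeters, infeasible population ranges, and placement
  failure all raise typed exceptions with actionable messages.
* A candidate with no hole is not an exception: it is handed to the
  quality filter as a missing-lumen condition and rejected there when
  a lumen is required.
* Measurement-log import converts pixels to μm at full precision
  (areas ×s², lengths ×s); circularity is dimensionless and passes
  through. In alternating mode the lumen row precedes the outer row of
  each fiber, per the manual recording order; an odd row count or an
  outer area not exceeding the lumen area is an error that names the
  offending document and suggests the likely cause.
* CSV output always uses '.' as the decimal separator regardless of
  locale; report mode rounds to 2 decimals, default mode writes 10
  significant digits (sufficient for bit-stable round trips at double
  precision measurement noise).

## Known limitations

* No splitting of touching fibers; dense sections lose those pairs to
  the quality filter rather than recovering them.
* The rule-based quality filter encodes geometry only; stain or focus
  defects that leave geometry intact pass.
* Height/width are axis-aligned box extents, not rotating-caliper
  Feret diameters, matching the manual workflow's definition.
* Line-level θ inconsistencies in published tables (θ of means vs mean
  of θ) cannot be resolved without per-fiber raw data; this package
  always reports the mean of per-fiber θ.
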