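# Methods

This note records the models, conventions, and numerical choices behind
`lnspatial`, and what the synthetic experiments do and do not demonstrate.

## Geometric descriptors

**Coordinate conventions.** Masks are indexed `(x, y, z)` with the axial
plane `(x, y)`; physical coordinates are voxel centers,
`origin + index * spacing`, in mm. All distances and angles are computed
in physical units, so anisotropic voxels are handled exactly. Volume
fractions are voxel-count fractions, valid because all structures of one
patient share a single grid. Left and right parotids are merged into one
`Parotids` structure before any histogram is computed.

**Tumor surface and signed distance.** The tumor surface is the set of
centers of 6-connectivity boundary voxels (a mask voxel with at least one
face-neighbor outside the mask or outside the image). The signed distance
of any point is the minimum Euclidean distance to these surface centers,
negated inside the mask. Defining the transform with respect to surface
*voxel centers* (rather than an interpolated interface) makes the fast
KD-tree path and the exhaustive pairwise oracle agree to floating-point
exactness; the difference from interface-based distance transforms is
sub-voxel. The full distance map is available, but the OVH path evaluates
distances only at organ voxels.

**OVH.** The cumulative histogram of signed distances within the organ
mask, evaluated at every edge of a uniform grid, by default 1 mm steps on
[−10, 150] mm. Distances outside the grid are clipped into the terminal
bins, so the curve always ends at 1. The 1 mm default resolves the
tens-of-mm scale at which cord/parotid geometry varies; both the range
and step are configurable.

**POV.** For each organ voxel the axial-plane directions to all tumor
surface points are collected; the voxel's angular coverage is the minimal
circular arc containing them, closed at both ends (a degenerate
single-direction arc still matches its own angle, and arcs crossing the
0/360° seam are handled by construction: the arc is the complement of the
largest angular gap). Two degenerate cases subtend the full circle: a
voxel axially coincident with a surface point, and a voxel whose
direction spread reaches a half-turn. The half-turn rule is deliberate:
below 180° the largest gap — hence the minimal arc — is unique, and arc
coverage is then provably monotone when the tumor mask grows (the axial
projections of a larger mask's surface always contain those of a smaller
mask's, any direction set within an open half-circle has a unique minimal
arc, and an arc of span < 180° containing two points contains the short
path between them). Without the rule, minimal arcs can flip sides of the
circle as points are added and monotonicity fails. The rule also matches
the line-projection (sinogram) reading of the descriptor, which is
180°-periodic: once directions span a half-turn, every projection line
through the voxel meets the tumor shadow. `fold_pov` provides the
180°-periodic projection form explicitly (maximum of opposite
directions).

**Occlusion.** The descriptor's "only voxels located before the tumor"
variant is under-specified in the sinogram picture, so it is exposed as a
flag rather than resolved silently. Mode `none` (default) applies the arc
rule as stated. Mode `before` additionally requires the voxel's axial
projection onto the direction of `alpha` to precede that of *every*
tumor surface point. A voxel projecting level with the nearest surface
point (difference exactly zero, which happens whenever the voxel is
axially aligned with a surface voxel) counts as *not* before; a 1e-9 mm
tolerance enforces this consistently between the vectorized path and the
per-voxel oracle, whose dot products can differ in the last ulp.

**Numerical boundary handling.** Closed-arc membership uses a 1e-9°
tolerance on both ends of the arc (including the wrap side), because
axis-aligned displacements produce arc endpoints exactly on grid angles
and independent implementations may differ by one ulp. All tolerances are
shared constants used identically by the fast paths and the brute-force
oracles, so oracle equivalence is exact (observed disagreement 0 across
random phantoms) rather than approximate.

## Spatial factors

Per (organ, histogram type) the cohort's curves form a patient × bin
matrix, reduced by PCA with mean centering only. Bins share units within
a histogram, and variance-scaling would inflate noisy tail bins (OVH bins
near saturation, POV bins rarely covered), so no per-bin scaling is
applied; this choice is recorded in the persisted model metadata. The
smallest number of leading components whose cumulative explained-variance
ratio reaches 0.75 is retained (boundary resolved by ≥). Component signs
are fixed by requiring each loading's largest-magnitude entry to be
positive, making factor values reproducible across runs and cohorts.
Validation cohorts are always projected with discovery-fitted models —
mean, loadings and selection count frozen — never refit. Patients missing
an organ contour are dropped from that organ's matrix only, and from the
final factor table only if a *selected* factor is unavailable; both drops
are logged.

## Survival modeling

Cox models use lifelines with the Efron tie correction. The screening
cascade is: univariate Cox on the screening endpoint (disease-free
survival by default) at p < 0.05; then, per surviving factor, a bivariate
factor + ordinal-N-stage model, keeping the factor only if its adjusted p
stays below 0.05 (pairwise testing first, one joint model at the end; a
factor exactly collinear with N stage is dropped outright). No
multiple-testing correction is applied across screened factors by
default, matching common practice for this cascade; a Benjamini-Hochberg
step could be added upstream by filtering the univariate p-values. N
stage enters all models as a single ordinal covariate (1/2/3), which
reports one hazard ratio for the stage trend.

The prognostic index is the uncentered linear predictor `beta . x` of the
joint model; validation indices use discovery betas. Tertile thresholds
are the 33⅓ and 66⅔ percentiles of the discovery index (linear
interpolation); group assignment sends ties to the lower-risk group, so
discovery group sizes differ by at most two. Harrell's C is oriented so
that a higher index predicting earlier failure is concordant, with 0.5
credit for tied indices. The bootstrap comparison resamples patients with
replacement (percentile 95% intervals, not BCa), redraws resamples that
contain no events (counted and logged), and reports
`p = 2 * min(frac(dC <= 0), frac(dC >= 0))` clipped to `[2/B, 1]` for the
C-index difference. The entire stage is deterministic given data and
seed; the bootstrap is the only stochastic step.

## Synthetic data

The phantom emulates the mask geometry the pipeline consumes, not
anatomy: a 48³ grid at 2 mm spacing (96 mm cube); a posterior midline
cord cylinder (radius 5 mm) spanning 95% of the grid's cranio-caudal
extent; two lateral parotid ellipsoids; optional brainstem, larynx and
mandible primitives (off by default — the default organ set is cord and
parotids); and 1–3 tumor ellipsoids with uniform laterality (8–30 mm off
midline), cranio-caudal position, in-plane semi-axes 5–12 mm and axial
semi-extent 5–24 mm. Voxels are included when their centers fall inside a
primitive, which a per-slice exhaustive center-in-primitive test verifies.
Seeding is two-level (cohort seed → per-patient child seeds) so single
patients are reproducible in isolation.

Survival follows a Weibull proportional-hazards model,
`T = scale * (-log U / exp(beta . x))^(1/shape)`, with shape 1.2, scale
320 months, exponential censoring at 0.012/month and a 72-month
administrative cutoff. With the default planted coefficients this gives a
marginal 3-year event-free fraction near 72% and roughly 60% censoring,
the regime of the multi-year head-and-neck cohorts the generator
emulates.

**Planted ground truth.** The default study plants
`OVH_SpinalCord_PC1: −0.70`, `POV_SpinalCord_PC2: +0.30`,
`n_stage: +0.80` (per-standard-deviation log-hazard contributions of
roughly −0.9, +0.9 and +0.6). The angular effect sits on the *second*
cord POV component because, in this phantom geometry, the leading OVH and
POV components both track tumor axial extent and correlate at ρ ≈ 0.5;
planting opposite-signed effects on correlated factors would cancel their
marginal associations and defeat univariate screening — the same reason a
real cohort's independent angular information appears in a higher-order
component. The protective magnitude 0.70 keeps the marginal
(noncollapsibility-attenuated) effect detectable at a few hundred
patients.

**Cross-institution shift.** The validation phantom differs only in cord
extent (55% of the grid instead of 95%), emulating an institution that
delineates less of the cord. Relative overlap volumes then rise, the
distance factors shift upward cohort-wide, the discovery-fitted index
falls, and the validation cohort over-fills the low-risk group under
discovery thresholds — the qualitative cross-site behavior
multi-hospital studies report. POV of a cylinder is unaffected by its
length (angles are axial), so the shift acts through the distance
factors, as intended.

**What passing tests do and do not show.** The phantoms exercise every
code path — anisotropic distances, arc seam cases, organ drops, cohort
projection, screening, stratification — and the planted-truth loop shows
the pipeline recovers known coefficients without bias (sampling error for
the N-stage coefficient is about ±0.2 at 200 patients, so recovery errors
of that order are expected noise). They do not establish clinical
validity: real masks have irregular shapes, inter-observer delineation
variability beyond a single cord-length parameter, correlated clinical
covariates, and informative censoring, none of which the generator
models.

## Problem sizes and determinism

Brute-force oracle comparisons run on phantoms up to 24³ (the O(N·S)
enumeration is the point, not speed); simulation-based checks use
200–1000 patients and 50–400 replicates, sizes at which the binomial and
sampling error of each assertion is small relative to its margin. A full
200+200-patient study at 48³ runs in about a minute on one CPU. All
stochastic steps take explicit seeds; rerunning any stage with the same
inputs and seed reproduces outputs bit-for-bit, and each pipeline run
writes its config, seed, package versions, patient counts and drop
reasons to `run_log.json`.

## Known limitations

* DICOM-RT parsing, contour rasterization and resampling are out of
  scope: masks must arrive as binary NIfTI volumes on a common
  per-patient grid (grid mismatches are errors, never silently fixed).
* The POV occlusion semantics ("before the tumor") are exposed as a flag
  with two defined readings rather than resolved; mode `none` is the
  default throughout.
* No time-dependent covariates, competing risks or proportional-hazards
  diagnostics; endpoints beyond the screening endpoint are
  evaluation-only.
* Tertile thresholds transfer across cohorts only up to systematic factor
  shifts; the validation phantom demonstrates the failure mode rather
  than correcting it.
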