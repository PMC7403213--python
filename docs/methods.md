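# Methods

## Coordinate frame and Frankfort alignment

All geometry lives in a right-handed millimetre frame: +x toward the
subject's left, +y superior, +z anterior. A scan is *FH-aligned* when the
least-squares plane through the four ear/orbit landmarks — left/right
tragion (tr) and left/right inferior orbital groove (or) — is horizontal,
the tragion midpoint is the origin, and the right→left tragion direction
spans the lateral axis. Classical Frankfort orientation is defined on bony
porion/orbitale; tragion and the inferior orbital groove are their standard
soft-tissue proxies and are the closest points in the landmark catalog, so
the package operationalizes FH on them. The alignment is a proper rigid
transform (orthonormal rotation, det +1): every pairwise landmark distance
and mesh edge length is preserved to round-off, and aligning an aligned scan
is the identity. Degenerate configurations (collinear FH landmarks) raise
rather than silently producing an arbitrary frame.

Reference planes, all constructed in the aligned frame:

* **midsagittal** — the vertical plane minimizing the summed squared signed
  distance of the midline landmarks (minor-axis direction of their
  horizontal scatter); contains the midline exactly for a symmetric face.
* **esthetic (Ricketts E-line)** — the pronasale–pogonion line as seen in
  the sagittal projection, extruded perpendicular to the midsagittal plane;
  anterior side positive, so lips ahead of the line score positive.
* **TVL** — the vertical plane through subnasale perpendicular to the
  midsagittal plane, anterior positive.
* **transglabellar / midfacial / transverse-nasal** — horizontal planes
  through glabella, the orbital-landmark midpoint, and subnasale.
* **plumb planes** — vertical planes through each preaurale perpendicular to
  the anterior axis. The clinical instruction "remove everything behind the
  plumb lines through the preaurale" needs a half-space, not a line, to clip
  a surface; these planes are that half-space boundary.

## The 58-parameter catalog

The catalog (19 linear distances, 7 facial depths, 3 curve lengths, 15
indices, 5 signed plane distances, 1 derived difference, 5 profile angles,
3 semi-perimeters) ships as JSON data, one entry per measurement with its
kind, operands and units. Operand conventions follow standard soft-tissue
anthropometry (e.g. morphological face height n–gn, face breadth zy–zy,
intercanthal index 100·en-en/ec-ec, nasal width index 100·NW/NH); where a
published convention is ambiguous the choice is declared in the catalog file
and can be replaced without touching code. Bilateral measurements average
left and right unless inherently bilateral. Indices are ×100 ratios and
dimensionless; angles are degrees computed with the atan2 form (stable near
0° and 180°); everything else is millimetres.

Curve entries (upper/lower vermilion curve length, mandible curve length)
use the anterior midsagittal mesh section between their window landmarks
when a mesh is present and fall back to the straight landmark chain
otherwise, with the route recorded per value in a provenance flag. The
semi-perimeters section the mesh at their transverse plane, keep the
polyline reaching furthest anterior (the facial loop), clip at the preaurale
plumb planes with exact segment/plane interpolation, and report the
remaining arc length. Mesh sectioning delegates triangle/plane intersection
to trimesh; segment chaining uses an endpoint-matching tolerance of 1e-6 ×
the bounding-box diagonal, so it is resolution-relative. On analytic shapes
the section lengths converge to the closed forms (great circle, half
cylinder) within 1% at icosphere subdivision 4 / 256 cylinder facets.

Evaluation is by topological order over the catalog dependency graph.
A missing landmark or absent mesh yields a missing value with a per-entry
diagnostic, never an exception: with a mesh all 58 values are defined; with
landmarks only, the three semi-perimeters are missing (and the curve entries
too if the chain fallback is disabled).

Invariants enforced by tests: every value is rigid-motion invariant (the
scan is re-aligned internally), uniform scaling by s multiplies mm entries
by s and fixes angles and indices, and mirroring a symmetric face changes
nothing.

## Univariate battery

Per variable: classic mean-centered Levene across the four sex × group
cells (median-centered available), a gender × disease two-way ANOVA, and
post-hoc pooled-variance t-tests within each gender (pooled because
homogeneity is checked first; Welch by flag). The ANOVA uses effect-coded
design matrices and computes sums of squares by explicit nested-model RSS
comparison — Type II by default (each main effect adjusted for the other;
the conventional choice when one factor, gender here at 34 vs 28 pairs, is
unbalanced), Types I and III by flag; F statistics use the full-model MSE
with N − 4 residual df. This direct implementation costs four small
least-squares solves per variable, which keeps simulation studies with tens
of thousands of ANOVA fits cheap; agreement with statsmodels' `anova_lm` is
pinned by test for all three SS types. Noise-free (saturated) responses are
detected by a relative residual threshold and reported as F = 0, p = 1 for
absent effects rather than 0/0.

Family-wise control is Bonferroni: threshold α/m computed exactly
(0.05/58 ≈ 8.62e-4), strict inequality p < threshold, two-sided tests
throughout. The screening summary reports per-column significant counts,
the disease∩gender and male∩female overlaps, and the direction of each
disease-significant variable from the sign of the cell-size-weighted pooled
patient mean minus control mean (a tie counts in neither direction).

## Discriminant stage

The two-class LDA is authored from first principles: pooled within-class
covariance S, weights solving (S + λI)w = μ₁ − μ₀, threshold midway between
the projected class means shifted by the log prior ratio. Priors are equal
by default (the cohorts are matched 1:1 and near-balanced); proportional
priors by flag. The ridge λ defaults to 1e-6 × the mean diagonal of S:
with 58 features and ~55–67 training rows the pooled covariance is at or
near singularity, and the small ridge makes the solve well-posed while
perturbing well-conditioned problems negligibly; λ = 0 is allowed and
raises on singularity. A discriminant score of exactly 0 classifies as
control, and loading ranks break ties lexicographically — determinism over
elegance. On full-rank problems with λ = 0 and equal priors the predicted
labels match scikit-learn's LDA label-for-label (pinned by test; the
reference implementation is used only as an oracle, never in the pipeline).

Leave-one-out cross-validation refits everything — z-scoring parameters
included — on the n−1 training rows of each fold, so the held-out subject
cannot leak into the model; a global-standardization mode exists for
fidelity experiments. Inference on the LOOCV accuracy uses a label-
permutation null (default B = 10,000, matching the published setting; tests
and the acceptance script use B = 999 or less) with the add-one estimator
p = (1 + #{null ≥ observed})/(B + 1), which is valid (super-uniform under
the null) for any B. The null distribution is persisted with the seed.
Loadings come from a full-sample z-scored fit, ranked by absolute value.
Box's M (chi-square approximation, df = p(p+1)/2 for two groups) checks
covariance homogeneity; it requires n > p per class and otherwise raises
with guidance, since the statistic needs nonsingular class covariances.
Genders are analyzed separately throughout, mirroring the sex differences
found at the univariate stage.

## Synthetic cohorts

**Feature level.** Each sex × group cell is a multivariate normal with the
cell's per-variable mean and SD and a configurable correlation: independent,
exchangeable (default ρ = 0.3 — facial measurements are mutually correlated,
and independence would make the discriminant problem unrealistically easy),
or block. The packaged specification carries the published per-cell
summaries of all 58 variables at cell sizes 34/34/28/28, so generated
cohorts match the study's first and second moments; ρ is a free parameter
that no headline quantity depends on. Draws are not truncated: SDs are
small relative to the means for every length-valued variable, and the
untruncated Gaussian keeps the distributional theory of the t/ANOVA battery
exact.

**Landmark level.** A neutral bilaterally-symmetric template (head
ellipsoid 77.5 × 105 × 95 mm; midline landmarks placed on the ellipsoid
surface so mesh profile sections pass through them; bilateral landmarks at
plausible adult positions) is deformed additively: a gender field for
males, a disease field for patients, then i.i.d. isotropic Gaussian noise
per landmark (default SD 0.5 mm, the scale of manual landmarking error).
The default disease field encodes the characteristic pattern — alar
widening, vermilion thickening/eversion, mandibular enlargement, increased
facial height and breadth; the mesh is deformed consistently via
Gaussian-weighted interpolation of the landmark displacements (σ = 15 mm).
The template's absolute measurement values are arbitrary by design: every
recovery claim is differential (patient minus control), so only the
displacement fields matter. What these cohorts do *not* emulate: real
inter-landmark correlation structure, non-Gaussian measurement error,
age/BMI covariates, and actual facial surface relief (noses, lips) beyond
the landmarks — passing recovery tests therefore demonstrates the
statistical machinery, not field performance on clinical scans.

## Problem sizes and numerical choices

The test suite and acceptance script run the permutation calibration at
n = 60 subjects, 10 features, B = 999 (one run) or B = 79 over 30 replicate
datasets (super-uniformity), the reference-equivalence check on 100 random
instances, and the landmark-level familywise-error study over 200 replicate
cohorts of 124 subjects — sizes chosen so each study completes in minutes
on one CPU while keeping Monte-Carlo error well below the margins being
asserted. Landmark files round-trip bit-exactly at 6 decimals (sub-micron,
below the 0.001 mm capture accuracy of handheld stereophotogrammetry).
Segment chaining, plane clipping and z-scoring tolerances are stated at
their definition sites; zero-variance features are dropped with a warning
before standardization rather than producing infinities.

## Known limitations

* The supplementary operand definitions of several indices (the triangle
  indices, iridio-chelial) are not published; the catalog declares
  reasonable conventions and is editable, but absolute values of those
  columns are convention-dependent.
* The printed per-variable post-hoc p-values in the packaged table are not
  reproducible from the printed summary statistics by any standard
  independent-sample t computation (e.g. MFH males: pooled t from the
  printed means/SDs gives p ≈ 3e-11, printed 6.48e-8); the packaged
  p-values are therefore treated as literal inputs for count summaries,
  never as recomputation oracles.
* With 58 features and fewer training rows the discriminant weights are
  ridge-dependent in scale (though not in the induced classification);
  loading *ranks* are the stable, interpretable output.
* No matched-pair modelling: the 1:1 matching is reflected in the balanced
  design but groups are analyzed as independent samples, as in the original
  battery.
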