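# Methods

This note documents the models, numerical choices and known limitations of
the `mtbm` pipeline in enough detail to reproduce or audit any step.

## Surface model

A nucleus surface is a lattice of `n_rings x n_around` vertices (mm).  The
around index wraps (tube), the ring index is open at both ends; for volume
computation the two end rings are capped by implicit triangle fans to their
centroids, closing the surface.  Quads are split into triangles along the
`(i,j) -> (i+1,j+1)` diagonal, consistently everywhere; volumes use the
divergence theorem over that triangulation.  Orientation is auto-detected
from the signed volume: inward-stored grids are handled transparently (a
warning, never an error), and the frame field flips its second leg so the
cross product `e1 x e2` always points outward.

Default grid: 100 x 150 = 15,000 vertices per structure.  The tube-with-caps
parameterization suits the elongated geometry of basal-ganglia nuclei; it
replaces the conformal mesh construction used on scanned segmentations
upstream of this package's scope.  Two grids correspond iff they share
dimensions; vertex `(i,j)` matches vertex `(i,j)`.

## Registration

Corresponded grids can still be misparameterized relative to each other.
`harmonic_register` corrects this inside the shared `(ring, around)`
parameter domain: it solves the discrete Laplace equation (5-point stencil,
periodic around, end rings fixed to the identity) for a reparameterization
map, with landmark pairs as hard interior Dirichlet constraints, then
resamples the subject at the mapped parameters by bilinear interpolation.
Being harmonic, the map minimizes Dirichlet energy among all maps with the
same constraint values — asserted as a test.  The linear system is solved
directly (sparse LU) up to 400k unknowns, by conjugate gradients beyond;
the residual is checked against `tol` (default 1e-10) either way.
Parameter-map folds (non-positive cell determinant) raise an error naming
the first folded cell; landmark shifts of more than ~1–2 grid units at
isolated points will fold the map, which is intended behavior for hard
point constraints.

With no landmarks the map is exactly the identity, so registration is a
no-op for generator-corresponded cohorts; the pipeline's template is the
vertex-wise mean of all subjects unless an explicit template is given.

## Morphometry

Per interior cell, both surfaces' mean edge vectors (averaged over the two
parallel edges) are expressed in per-cell orthonormal tangent frames
(`e1` along the around edge, `e2` its Gram–Schmidt complement), and `J` is
the exact 2×2 solve sending template edge coordinates to subject edge
coordinates.  Since `S = (JᵀJ)^{1/2}` is invariant to rotations (and
reflections) applied on the subject side, the analysis quantities are
robust to the arbitrary in-plane orientation of the frames; this is
asserted as a test.

Because each cell's frame is right-handed by construction, `det J` would
stay positive even across a local fold.  Folds are therefore detected by
normal agreement: a cell whose raw normal (cross product of its mean
edges) flips against the corresponding template normal is treated as
folded — its `J` is reflected so `det J < 0`, it is masked out, and a
warning reports the count.  This assumes subject and template are globally
aligned (true for this pipeline, where surfaces arrive in a common space
and templates are cohort means); a subject rotated by a large rigid motion
*relative to its template* would trip the detector.

`log S = ½ log(JᵀJ)` is evaluated by eigendecomposition of the symmetric
positive-definite `JᵀJ`; `det J ≤ 0` or condition numbers above 1e12 are
domain errors.  The three unique entries `(s11, s12, s22)` are used, the
standard multivariate TBM convention consistent with the 4×1 feature —
a symmetric 2×2 tensor has three unique entries but only two eigenvalues.

Cell quantities transfer to vertices by template-cell-area-weighted
averaging over the up-to-four adjacent valid cells (j wraps, i clamps at
end rings); vertices with no valid adjacent cell become NaN and are
excluded from maps.  MAD is the Euclidean distance from each vertex to its
ring centroid — the medial axis is the centroid polyline, the form
appropriate to ring-parameterized tubes (a pruned Voronoi medial axis
would be needed for arbitrary topology, out of scope here).

Useful identities maintained to ~1e-10 and covered by tests:
`det J = exp(s11 + s22)` per cell; rigid motions of both surfaces give
`log S = 0`, `det J = 1`; coaxial diagonal stretches compose additively in
`log S`; `det J` equals the cell-area ratio exactly for deformations that
keep cells planar (affine maps of planar-celled grids) and to discretization
accuracy otherwise.

## Statistics

**Age residualization.** Each vertex-channel is regressed on
`(intercept, age)` by OLS pooled over both groups, and replaced by its
residual; residuals are exactly mean-zero and orthogonal to age.  The fit
is pooled without a group term: with groups matched on age, a group term
would absorb part of any true group effect, which is the wrong trade for a
detection method.  Correlation maps use raw Pearson correlations (no age
covariate), keeping the correlation analysis a direct description of the
`det J`–score relationship.

**Hotelling T².** `T² = (n_A n_B / n) dᵀ Σ̂⁻¹ d` with the pooled unbiased
covariance; a ridge of `1e-8 · trace(Σ̂)/c` is added only when the
condition number exceeds 1e10.  With one channel, `T²` equals the squared
pooled t statistic exactly; `T²` is invariant under any common invertible
affine transform of the channels, so the mixed units of the feature
(mm and dimensionless) are immaterial.

**Permutation inference.** One label-shuffle schedule is drawn from the
seed and shared across all vertices, and across structures analyzed with
the same seed — this is what makes the combined left+right test well
defined.  Vertex-wise `p = (1 + #{T²_perm ≥ T²_obs}) / (1 + n_perm)`
(add-one, never zero; ties counted conservatively).  When the cohort is so
small that fewer distinct label assignments exist than `n_perm`, all
distinct assignments are enumerated instead, with a notice.

**Structure-wise correction.** The omnibus statistic is the count of
vertices significant at `alpha_vertex` (default 0.05).  To keep observed
and permuted counts exchangeable, the observed statistic joins its
`n_perm` replicates in one pool per vertex; an element is significant when
it exceeds the `(K+1)`-th largest pooled value, `K = floor(alpha·(n_perm+1))`.
The corrected p compares the observed count against each permutation's
count with the same add-one formula.  Exchangeability makes the procedure
exactly valid; the 200-replicate null-cohort calibration in the acceptance
suite measures a rejection rate of about 0.05–0.07 at the 0.05 level.
Combined-structure p values add the omnibus counts across sides (schedule
identity is enforced).  Memory stays bounded by computing permutations in
chunks of 512.

**Volume and correlation tests.** Volumes get a two-sided permutation p of
the pooled t statistic (vectorized via the fixed-total-scatter identity);
`det J`–score maps get vertex-wise Pearson r with two-sided permutation p
from score shuffles and the same count-based correction applied to `|r|`.

**Permutation vs analytic nulls.** For Gaussian data the permutation p and
the analytic reference (`T²`→F transform; t distribution for r) agree to a
few 1e-3 in the tail (p below ~0.05) at n = 23, n_perm = 10,000.  In the
bulk (p above ~0.5) the conditional permutation null genuinely deviates
from the unconditional analytic null by up to ~0.02 at this sample size;
this is a property of conditional inference, not an implementation error.
The analytic forms exist in the package only as test oracles — permutation
p values are the primary output everywhere.

## Synthetic cohorts

The generator emulates the study design the statistics serve: 10 high- and
13 low-exposure children, ages uniform on 9–15 years, one template per
structure/side, and per-subject surfaces deformed from it.  Parameters and
defaults:

| parameter | default | meaning |
|---|---|---|
| `n_high`, `n_low` | 10, 13 | group sizes |
| `n_rings x n_around` | 100 x 150 | grid (15,000 vertices) |
| `semi_axes` | per structure | ellipsoid base shape, mm; sized so template volumes match typical structure volumes (putamen ≈ 5,000 mm³, globus pallidus ≈ 1,250 mm³, caudate ≈ 4,100 mm³) |
| `effect_rings_frac` | 0.25 | anterior ring band carrying the effect |
| `effect_taper_frac` | 0.10 | raised-cosine taper width |
| `effect_scale` | 1.05 | local linear scale in the high group |
| `age_slope` | 0.01 / year | global fractional size growth |
| `noise_amp` | 0.02 | SD of fractional radius perturbation |
| `noise_modes` | 3 | highest harmonic order of the noise |
| `score_intercept/slope/sd` | 37, −65, 6 | score model vs (mask-mean det J − 1) |

The enlargement is implanted as a raised-cosine-tapered **uniform scaling
about the structure centroid** restricted to the anterior band: inside the
flat part of the taper the map is exactly conformal, so the in-surface
area contrast is exactly `effect_scale²` and recovery tests are
quantitative, not qualitative.  The ground-truth mask is the taper-≥-half-
maximum region, defined geometrically (it exists even at
`effect_scale = 1`).  Subject variability is band-limited harmonic radius
perturbation about the medial axis — smooth like anatomy, and fold-free at
default amplitudes; white noise would fold cells and is not offered.
Scores follow a higher-is-better convention with a negative slope against
mask-mean `det J`, so enlargement predicts worse fine-motor performance;
the sex ratio and water-manganese columns are descriptive only.

Left/right cohorts of the same children share one demographics stream
(same seed) while drawing distinct per-side shape noise; effects can be
implanted unilaterally.  Generation is bit-deterministic in the seed, with
demographics, per-subject noise and score residuals on separate
substreams.

**What passing tests do and do not show.**  The generator produces smooth,
correctly corresponded, fold-free surfaces with a known effect; it does
not simulate segmentation error, registration failure, MR intensity
artifacts, or non-ellipsoidal base anatomy.  Calibration and power results
on synthetic cohorts therefore validate the statistical machinery and the
tensor pipeline, not the robustness of any upstream segmentation.

## Problem sizes and runtime

Full-resolution analyses (15,000 vertices, 10,000 permutations) are the
production configuration.  The validation suite runs the statistical
calibrations at reduced sizes chosen for desk-scale runs — 30×45 grids,
n_perm = 500–1,000 for replicate simulations, n_perm = 10,000 where p-value
precision itself is under test — because the machinery is resolution- and
count-agnostic and the calibrations concern distributional behavior, not
map resolution.  A bilateral structure at 30×45 with n_perm = 1,000
analyzes in a few seconds on one CPU; the full acceptance recomputation
takes about three minutes.

## Known limitations

- Fold detection is relative to the template normal and assumes global
  pre-alignment (see Morphometry).
- MAD uses ring centroids; strongly bent tubes would need a true medial
  axis.
- The registration landmark mechanism is generic (index-pair constraints);
  no automatic landmark detection is provided.
- Sex is recorded but not modeled; the age model is a pooled linear trend.
- The combined-structure test requires identical permutation schedules on
  both sides (enforced), hence identical seeds and n_perm.
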