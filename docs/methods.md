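# Methods

## Model

The analysis discriminates I a-priori categories of row observations in an
N × J table whose columns are partitioned into K subtables (one per subject
or region of interest, widths J_k free to differ).  Each category is
summarized by its barycenter — the mass-weighted mean of its rows, with the
masses rescaled to sum to one within the category — and the I × J
barycenter matrix R is analyzed by a generalized PCA: a singular value
decomposition constrained by a row metric B (the category masses) and a
column metric W (the variable weights),

    R_c = P Δ Qᵀ,   PᵀBP = QᵀWQ = I,

where R_c is R centered at the grand barycenter (the b-weighted mean row).
Category factor scores are F = PΔ; variable factor scores are G = QΔ; the
per-dimension B-weighted variance of F equals the squared singular value
(the eigenvalue λ_ℓ).  Observations project as supplementary elements,
h = (x − center) W Q, and these projections are barycentric: the
mass-weighted category means of the observation scores reproduce F exactly.
Classification is nearest-barycenter by squared Euclidean distance in the
full factor space (all retained dimensions unless `n_components` truncates),
with argmin ties broken toward the lowest category index and counted.

### Centering

The barycenter matrix is always centered at the grand barycenter before
decomposition, and every projection subtracts the same center.  This is a
deliberate design choice rather than an optional preprocessing step: it
removes the uninformative "grand mean" dimension (so the rank is at most
I − 1), makes the grand barycenter of the factor scores exactly zero, and —
for the correspondence-analysis variant — reproduces exactly the CA
centering at the column-frequency centroid, which is what makes
discriminant correspondence analysis here agree to machine precision with a
chi-square-metric CA of the category-aggregated table.

### Variants

The metric pair (B, W) and a row transform select the geometry:

- **plain** — user masses/weights (defaults 1/N, 1/J) on any real table,
  after the configured preprocessing pipeline.
- **dica** (discriminant correspondence analysis) — for counts.  Rows are
  turned into relative-frequency profiles; row masses are the relative row
  totals (the CA convention), so category masses b are relative category
  totals and column weights are inverse column frequencies.  Under these
  masses the barycenter of observation profiles equals the profile of the
  category-aggregated counts, so "aggregate then profile" and "profile then
  average" coincide and the barycentric projection identity holds exactly.
  With user-supplied masses that are *not* proportional to row totals the
  two readings would differ; the package always uses the CA masses for this
  variant and ignores user masses there.
- **hellinger** — rows become square roots of their profiles (points on the
  unit sphere), with uniform masses and weights.  The square root is
  applied to the *observation* rows before the barycenters are computed:
  the mean of square-root profiles is not the square-root profile of the
  sum, and only the row-transform reading preserves the barycentric
  identity that every other part of the package relies on.
- **classical** — W is the pooled mass-weighted within-category covariance
  inverse, i.e. classical linear-discriminant geometry.  Near-singular
  covariances use a pseudo-inverse, optionally ridge-stabilized
  (`ridge > 0`); the condition number is recorded on the model.  Because
  this W couples columns across subtables, the per-subtable partial
  operations are undefined for it and raise.

## Preprocessing

All transforms are parameterized and strictly train-side: `fit_transform`
estimates parameters on the training rows, `transform` replays them on new
rows.  Available steps, in any user-chosen order: column centering,
column z-scoring (population denominator N, matching the mass-weighted
inertia algebra with masses 1/N), row sum or sum-of-squares normalization,
the Hellinger row transform, MFA subtable normalization (each subtable
divided by its first singular value, so no subtable dominates by sheer
leading eigenvalue), and STATIS weighting (each subtable scaled by the
square root of its weight from the first eigenvector of the between-
subtable RV-coefficient matrix, computed on column-centered cross-products
and rescaled to sum to one).  The recommended pipeline for activation-style
data is center → mfa → row-sum-of-squares, in that order.  MFA and STATIS
compose by listing both; because steps execute in the listed order, listing
`statis` after `mfa` computes the RV weights on the MFA-normalized data
(listing it first computes them on the raw scale) — both recomputation
conventions are therefore available through ordering alone.  Interacting
combinations such as z-scoring plus row normalization are allowed with a
warning.

## Inference

**Inertia decomposition.** Total inertia of the observation scores about
the grand barycenter splits exactly (ANOVA-style) into within-category and
between-category parts; R² = between/total.  The decomposition uses the
category masses aggregated from the row masses, which is what makes the
additivity an algebraic identity (relative error below 1e−8 is asserted on
every fit).  A table whose projections have zero total inertia reports
R² = 0.

**Permutation test.** Category labels are permuted across exchangeable
units — whole blocks when the design declares them (within-block rows are
temporally correlated; between-block rows are independent), otherwise
individual observations — and the model is refit per permutation on the
cached transformed data (every row transform in the package is label-free;
the classical-variant W, which does depend on labels, is recomputed).  The
p-value is the add-one estimator (1 + #{R*² ≥ R²}) / (1 + n_permutations),
which never reports zero and is valid for any finite number of random
permutations.  Blocks spanning several categories are rejected.

**Cross-validation.** Leave-one-out or leave-one-block-out.  Per fold the
preprocessing parameters, barycenters, metrics and GSVD are re-estimated on
the retained rows only; held-out rows are transformed with the fold's
stored parameters, projected (h̃ = x W₋ Q₋) and assigned to the nearest
fold barycenter.  For prediction-interval clouds the held-out row is also
carried into the *full* solution through its fold reconstruction,
ĥ = x W₋ Q₋ Q₋ᵀ W Q (reconstruct from fold scores, then project as a
supplementary element), with the fold and full centers handled on each
side.  A fold that would empty a category raises, naming the category.

**Bootstrap.** Barycenters are resampled with replacement within each
category — and within each category × block stratum when blocks are
declared fixed, as they should be for block designs — and projected in the
original factor space (the projection is affine, so the resampling runs on
the cached factor scores).  Confidence ellipses per category cover a stated
fraction of the bootstrapped barycenters.

**Ellipses.** An ellipse at level γ has center the point-cloud mean, shape
the sample covariance, and squared radius the empirical γ-quantile of the
points' squared Mahalanobis distances — the smallest radius putting
⌈γn⌉ points inside or on the boundary, so 100 points at γ = .95 give
exactly 95 inside-or-on.  Collinear clouds produce a flagged degenerate
ellipse with a pseudo-inverse metric (zero minor axis).  Tolerance ellipses
(training projections) and confidence ellipses (bootstrapped barycenters)
are centered on the cloud mean; prediction ellipses keep the mean of the
held-out-projection cloud, which need not coincide with the category mean —
the offset estimates the bias.  Pairwise multiplicity is handled by
Bonferroni (1 − 2α/(I(I−1))) or Šidák ((1−α)^(1/m), m = I(I−1)/2 pairs)
corrected levels; both reduce to 1 − α at I = 2.  Overlap between two
ellipses is decided approximately, by sampling the segment joining the
centers and testing shared membership — sufficient for a reporting flag on
convex regions, and cheaper than exact conic intersection.  Non-overlap in
any examined dimension pair implies separation in the whole space; overlap
everywhere examined is reported as inconclusive, since it may be a
projection artifact.

## Subtable integration

Partial factor scores F_k = K · R_k W_k Q_k use the *barycenter* columns of
subtable k (with the matching slice of the center), so each F_k is I × L
and the plain average over subtables recovers F exactly; observation-level
partial scores (N × L per subtable) use the data columns instead and are
also exposed.  Supplementary rows spanning a single subtable's columns
project the same way.  Partial inertias ℐ_ℓ,k = Σ_{j∈k} w_j g²_ℓ,j sum over
subtables to the dimension's eigenvalue; they are reported raw and
normalized by λ_ℓ.  The K multiplier is uniform; non-uniform subtable
weights c are stored on the table but enter no computation unless the user
maps them into the column weights.

## Synthetic data generator

The generator emulates a multi-subject block-design experiment: rows are
I categories × blocks × repeated scans; columns are K subtables of unequal
widths; category separation is a mean shift drawn once per seed, N(0,
effect_size²) per carrier column and zero elsewhere; noise is a stationary
AR(1) series within each block (lag-1 autocorrelation `intra_block_rho`,
marginal SD `noise_sd`), independent across blocks — the minimal mechanism
that makes leave-one-out and leave-one-block-out genuinely different.  A
parallel multinomial generator produces count tables with category-specific
softmax-perturbed profiles for the correspondence/Hellinger variants.
Ground truth (true means or profiles, carrier mask) is returned with the
data so recovery tests never re-derive it.

Default spec: 7 categories, 8 blocks per category, 16 scans per block
(128 scans per category — the block structure of the kind of experiment the
package targets), 10 subtables of widths 28–47 (desk-scale stand-ins for
per-subject voxel counts in the thousands), rho = 0.5, noise SD 1.  The
default effect size of 0.12 per carrier column is calibrated once so the
default design lands in a strong-but-imperfect regime (training accuracy
≈ .97, leave-one-block-out accuracy ≈ .54 against 1/7 chance, R² ≈ .67)
instead of a trivially separable one — with the shift spread over all ~360
columns, between-category distances scale like effect_size·√(2J), so unit
effects would saturate every metric.

What the generator does *not* emulate: hemodynamic response convolution,
spatial smoothness across voxels, scanner drift, or subject-level random
effects beyond subtable identity.  Passing tests therefore demonstrate the
statistical machinery under the stated noise model, not performance on real
acquisitions.

## Simulation study sizes and what they show

- Permutation-test calibration: 3 categories × 4 blocks × 4 scans,
  199 permutations, 200 replicates.  The add-one permutation p-value is
  valid at any size, so the small fast design suffices; empirical type-I
  error at α = .05 sits within 3 Monte-Carlo SE of .05.
- Chance-level accuracy: sized at the target design's 128 scans per
  category.  At much smaller per-category counts, cross-validated accuracy
  at the null is systematically *below* 1/I: leaving a block out pulls its
  own category's barycenter away from it, the known pessimistic bias of
  cross-validation at chance level.  The bias is a finite-sample property
  of the estimator (≈ −0.07 at 16 scans/category, ≈ −0.01 at 128), not a
  defect; it washes out at the sizes the method is meant for.
- Bootstrap-ellipse coverage: 128 scans per category, independent noise,
  300 bootstrap replicates, 200 data replicates.  Coverage of the true
  projected category means is near-nominal (≈ .94 measured) at this size;
  at 32 scans per category it drops to ≈ .88 because the factor space is
  itself estimated and partly chases noise — a known limitation of
  bootstrapping projections onto an estimated subspace.  Interpret
  confidence ellipses from small samples conservatively.
- Leakage demonstration: rho = .9 versus rho = 0 at a mid-range effect
  size, 20 replicates: leave-one-out beats leave-one-block-out in every
  replicate under strong autocorrelation and the gap vanishes within noise
  under independence — the reason block-out CV is the honest random-effect
  estimate for block designs.

## Numerical choices

- GSVD route: form B^{1/2} R W^{1/2} (diagonal square roots; symmetric
  eigendecomposition square root for a full SPD W), standard SVD,
  back-transform.  No cross-product matrices are formed.
- Rank tolerance max(I, J)·eps·δ_max; singular values below it are dropped.
- Sign convention: each right singular vector is flipped so its
  largest-magnitude entry is positive (ties to the lowest index), with the
  matching left vector flipped — outputs are reproducible across platforms.
- Z-scores use the population denominator N.
- Text round-trips: floats are written as %.17g and parsed with pandas'
  round-trip parser, so save/load is bit-exact.
- One master seed per stochastic routine; per-replicate streams are derived
  deterministically, so reruns are bit-identical and parallelizable.

## Known limitations

- Partial (per-subtable) operations require a diagonal column metric and
  are unavailable for the classical variant.
- The ellipse overlap flag is approximate (center-line sampling).
- Jackknife bias-corrected barycenter estimates and analytic (non-
  resampling) confidence regions are out of scope.
- Confidence-ellipse coverage is below nominal for small per-category
  sample sizes (see above).
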