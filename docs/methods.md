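# Methods

## Superimposition

Configurations are k×3 landmark matrices (mm). Centroid size is the
Frobenius norm of the centred configuration. GPA uses the
partial-Procrustes convention: every specimen is centred and scaled to
unit centroid size once, then iteratively rotated (proper rotations only —
reflections are never admitted, so a mirrored specimen keeps a positive
residual) onto the running consensus, which is the arithmetic mean of the
aligned coordinates rescaled to unit size. Convergence is declared when
the Frobenius movement of the consensus falls below `tol = 1e-10`
(default; max 100 iterations). The movement is measured as a plain matrix
norm rather than through the trigonometric distance formulas, which lose
half the floating-point digits near zero.

The GPA objective has a neutral direction — the global orientation of the
whole solution — which would otherwise be set by the arbitrary initial
reference (the first specimen). The output frame is therefore anchored
deterministically: the consensus is rotated into its principal axes with
a fixed sign convention, making `gpa` idempotent (re-superimposing an
aligned sample changes coordinates by < 1e-9) and its output orientation
independent of the input pose.

Between-shape distances: the full Procrustes distance (optimal mutual
scaling; √(1 − t²) for optimal-rotation trace t) is the default, the
partial variant (√(2 − 2t)) is exposed. Both are computed from the
explicit residual matrix for accuracy near zero. At the magnitudes seen
in this application (~0.02) full and partial differ negligibly.

Downstream statistics operate on the aligned coordinates directly — the
standard small-variation Euclidean (tangent-space) approximation. An
orthogonal projection at the consensus is available (`project_tangent=True`)
but off by default, matching mainstream morphometrics tools.

## PCA

SVD of the column-centred flattened aligned coordinates. Components with
eigenvalue below 1e-12 of the leading one are dropped; what remains
reconstructs the centred data to machine precision. Because scale and
rotation are only first-order removed by superimposition (without the
tangent projection), four near-null directions retain tiny genuine
variance, so the retained rank is min(n−1, 3k−3) — the three centering
constraints are the only exact nulls — rather than the theoretical
shape-space dimension 3k−7. Variance percentages are relative to the
retained total; the distinction changes them by well under 0.01%.

## Procrustes ANOVA (Goodall's F by permutation)

Shape is regressed on design terms by multivariate least squares on the
flattened aligned coordinates. Sums of squares are sequential (Type I) in
the order the terms are written; categorical variables are dummy-coded
(first level dropped), interactions are column products, and `size`
resolves to centroid size. Goodall's F for a term is
(SS_term/df_term)/(SS_residual/df_residual) with the residual taken from
the full model. For a single two-group factor this reduces exactly to the
classical two-sample form [d²(m̄₁,m̄₂)/(1/n₁+1/n₂)]/[SS_within/(n−2)],
which the package also implements independently as a cross-check.

Significance is assessed by residual randomization (RRPP): for each term,
the residuals of the model containing all preceding terms are row-permuted
and added back to the reduced fitted values, and the term's F is
recomputed (with the permuted full-model residual in the denominator).
For a single-factor design this coincides with raw label shuffling. The
p-value is (1 + #{F* ≥ F_obs})/(1 + n_perm); ties count as exceeding
(conservative), and with the default n_perm = 999 the attainable floor is
0.001. All permutations derive from an explicit seed; results are
reproducible bit-for-bit.

The default analysis fits two models — shape ~ sex + age + sex:age and
shape ~ size + sex + size:sex — rather than one combined model, and
reports all terms; a combined design can be passed as a single formula
string if preferred.

## Group distances

Between two groups: the full Procrustes distance between their mean
shapes (group means of aligned coordinates, rescaled and rotated onto the
consensus), and the Mahalanobis distance
D = √[(μ₁−μ₂)ᵀ S_pooled⁻¹ (μ₁−μ₂)] on the first q tangent PC scores with
the pooled within-group covariance. By default q is the largest dimension
with pooled-covariance condition number below 1e8 and q ≤ n − 4, and is
reported alongside the distance; D grows with q, so comparisons should
fix q.

## Study-design drivers

- **Cut-off cohort tests** split each sex at 55/60/65 years
  (younger = age < cutoff), re-superimpose *within* sex, and run the
  single-factor permutation ANOVA. Cells below 3 specimens are flagged,
  not computed.
- **Inter-cohort distances** use one *common* GPA (they compare across
  sexes), full Procrustes distances between the four cohort means
  (female/male split at 55/65 by default), and pairwise label-shuffling
  p-values.
- **Aging-rate curves**: within sex, specimens sorted by age (ties by id),
  windows of 20 consecutive specimens at step 1; in each window the
  aligned coordinates are regressed on age and the rate is the Euclidean
  norm of the slope vector — the displacement of the predicted mean shape
  per year, in Procrustes-coordinate units. The window centre is the mean
  age. No smoothing is applied. Note the estimator is a norm and hence
  positively biased under noise: with p = 3k coordinate dimensions,
  residual variance σ² per coordinate and age spread S_aa in the window,
  a zero true slope still yields rates around √(pσ²/S_aa) (~0.005/yr at
  the synthetic defaults). Signals below this floor are not localizable;
  the bias shrinks as the window grows.
- **Cohort mean comparison** rotates one group mean onto the other (both
  unit size) and reports per-landmark displacement vectors; the summed
  squared displacements equal the squared partial Procrustes distance.

## Generalizability theory

The reliability design is fully crossed subject × rater × variable with
one observation per cell, the variables being the k(k−1)/2 inter-landmark
distances — a superimposition-free reading of "landmark pairs" that is
invariant to specimen pose (a 3k-coordinate variant can be assembled by
the caller for sensitivity analysis). Variance components come from the
three-way random-effects expected-mean-square equations (the three-way
interaction is confounded with error); negative estimates are truncated
to zero before use, per standard GT practice. Only the relative
(norm-referenced) error enters the reported G; the absolute (Φ)
coefficient is out of scope. G is monotone non-decreasing in both facet
sizes, which doubles as a D-study.

## Synthetic generator

The generator draws the study design: two sexes × 5-year bins over 40–79
years, 10 per cell by default (n = 160), integer ages spread evenly within
bins. Per-specimen mean shape = symmetric template ± δ/2 along a fixed
unit dimorphism direction (δ = 0.03 Procrustes units) plus the sex's
accumulated age drift along its own unit direction. All effect directions
are constructed orthogonal to the 7 similarity-transform tangent
directions at the template (translations, rotations, scale), so nominal
Procrustes-unit magnitudes survive GPA instead of being partly absorbed.

Aging profiles are piecewise linear in the instantaneous rate: females
ramp from 0 at onset 50 to a peak of 0.002 units/yr at 60 and back to 0
by 70 (a local rate maximum, mirroring the observed female acceleration
in the 50–60 window); males run a constant 0.001 units/yr from 60
(`peak_age=None` gives the constant-rate drift `rate·max(0, age−onset)`).
In convergence mode the female mean instead takes yearly attraction steps
toward the *current* male mean (never overshooting), reproducing the
female-toward-male convergence of cohort distances.

Observation noise is isotropic Gaussian per landmark axis,
`noise_sd = 0.01` in unit-centroid-size units. This value makes the
default synthetic sample land where the application operates: a measured
between-sex distance ≈ 0.032 and Goodall's F in the single digits, and a
per-specimen scatter comparable to real within-group shape variation.
Centroid size is log-normal around 180 mm (σ_log = 0.06), and each
specimen receives a random rotation and translation so that readers and
GPA are exercised for real. Everything derives from a single spec seed.

What the generator does *not* emulate: correlated biological covariance
across landmarks (noise is isotropic, so synthetic PC1 carries ~10% of
variance, far less than the concentration seen in real mandibles),
landmark-specific digitization error, asymmetry, and tooth-loss-related
remodelling. Passing tests therefore validate the estimators under the
assumed model, not the anatomy.

A consequence of the honest noise level: the female aging signal (peak
rate 0.002/yr) sits below the ~0.005/yr noise floor of the 20-specimen
moving-window slope norm, so the qualitative rate-curve pattern (rise
after 50, maximum near 60, flatter males) is recovered only in a minority
of replicates at default settings; at noise_sd ≈ 0.002 it is recovered
essentially always. The acceptance suite reports the measured fraction
under the defaults without adjusting either parameter.

## Numerical conventions and degenerate inputs

- Optimal rotations by SVD with the determinant-corrected sign (Kabsch);
  rank < 2 cross-products raise (rotation unidentifiable).
- Distances and the GPA step computed from explicit residuals, never from
  √(1−t²)-type formulas, to stay exact near zero.
- Zero-centroid-size configurations, empty subsets, constant factors,
  saturated designs, missing G-study cells and mismatched landmark sets
  all raise informative errors rather than propagating NaNs.
- Permutation ties count against the observed statistic; p-values can
  never be 0.
- Tables in the pipeline driver are written with 4 decimals; SVG output
  is fixed-precision and byte-deterministic.

## Problem sizes

Default test and acceptance runs use the study-scale n = 160 (or n = 40
for the null calibration), 199–999 permutations, and 50–500 Monte-Carlo
replicates per experiment; the full acceptance script completes in a few
minutes on one CPU. The 500-replicate type-I check targets the
[0.03, 0.07] band around the nominal 0.05, which is ±2 binomial standard
errors — an intrinsically ~95% check under perfect calibration.

## Known limitations

- No missing-landmark handling (rejected on input), no sliding
  semilandmarks, no symmetry decomposition.
- Mahalanobis distances depend on the retained PC dimension q; the
  automatic choice is conservative and reported, but cross-study
  comparisons require a fixed q.
- The tangent-space approximation is excellent at the shape variation
  scales here (distances ≤ 0.07) and untested far beyond them.
- CVA/classifier accuracy is deliberately out of scope; only the
  Mahalanobis distance a CVA would yield is provided.
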