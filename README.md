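# mandimorph

Landmark-based geometric morphometrics of mandibular sexual dimorphism and
aging in adults.

Forensic and anthropological work relies on the mandible for sex
estimation, but the bone keeps remodelling throughout middle and old age,
and the onset, pace and anatomy of those changes differ between the sexes.
`mandimorph` provides the complete statistical toolchain for studying this
with 3D landmark coordinates (14 named mandibular landmarks per specimen,
typically digitized on CT reconstructions):

- **Superimposition** — generalized Procrustes analysis (GPA): every
  configuration is centred, scaled to unit centroid size
  (CS = √Σᵢ‖xᵢ − x̄‖²) and rotated by proper rotations to minimize the
  summed squared distances to an iteratively refined consensus, leaving
  pure shape.
- **Inference on shapes** — tangent-space PCA; Procrustes ANOVA with
  sequential (Type I) sums of squares where Goodall's
  F = MS_term / MS_residual is assessed by residual-randomization
  permutation (RRPP); full Procrustes and Mahalanobis distances between
  group mean shapes.
- **The aging study design** — younger/older cohort tests at age cut-offs
  (55/60/65), the 4×4 distance table among young/old × female/male
  cohorts, and a moving-window (20 specimens, step 1) multivariate
  regression of shape on age whose slope norm is the *aging rate* in
  Procrustes distance per year.
- **Digitization reliability** — generalizability theory on the crossed
  subject × rater × landmark-pair design: variance components from the
  three-way EMS equations and the relative coefficient
  G = σ²ₛ / (σ²ₛ + σ²ₛᵣ/nᵣ + σ²ₛₗ/nₗ + σ²ₛᵣₗ,ₑ/(nᵣnₗ)).
- **Figures** — consensus-wireframe comparisons (solid vs dashed, with
  magnified displacement arrows) as deterministic SVG.
- **Synthetic data** — a seeded generator reproducing the study design
  (160 specimens, 10 per sex per 5-year bin over 40–79 years) with a
  controllable sex mean-shape offset, sex-specific piecewise-linear aging
  profiles, optional female-toward-male convergence, log-normal centroid
  size and isotropic digitization noise, so every stage is testable
  without any data download.

## Worked example

```python
import mandimorph as mm

ds  = mm.simulate_dataset(mm.SimulationSpec(seed=42))   # n=160, k=14
fit = mm.gpa(ds)                                        # 4 iterations, converged
res = mm.ProcrustesANOVA(fit, "sex + age + sex:age").fit(n_perm=999, seed=1)
print(res.summary())
```

```
Procrustes ANOVA (Goodall's F, RRPP permutation)
permutations: 999, seed: 1

    term  df     SS     MS       F  p_perm
     sex   1 0.0428 0.0428 12.1887  0.0010
     age   1 0.0072 0.0072  2.0405  0.0020
 sex:age   1 0.0074 0.0074  2.1201  0.0010
Residual 156 0.5480 0.0035     NaN     NaN
```

Sex explains a mean-square 12× the residual (Goodall's F = 12.19) and no
permuted dataset reached the observed statistic (p = 1/1000, the floor at
999 permutations); age and its interaction with sex are weaker but real —
exactly the structure the generator injected (a 0.03 Procrustes-unit sex
offset plus sex-specific age drift).

```python
gd = mm.group_distance(fit, "sex", n_perm=999, seed=2)
#   mahalanobis 3.5457, procrustes 0.0328, goodall_F 12.0243, p 0.0010
t3 = mm.cutoff_cohort_tests(ds, n_perm=999, seed=3)
#   females significant at every cut-off (F≈2.2-2.4, p=0.001),
#   males only from 65 on (F=2.02, p=0.002) - earlier female onset
```

The between-sex mean-shape distance (0.0328) recovers the generated 0.03
offset up to the upward bias of estimating a norm from noisy means, and
the cut-off table shows the generator's earlier female aging onset: female
cohorts differ at every cut-off while males first separate at 65.

The same analyses run from the shell:

```bash
mandimorph simulate --seed 42 --out lm.csv meta.csv
mandimorph anova lm.csv --meta meta.csv --design "shape ~ sex + age" --perm 999 --seed 1
mandimorph replicate-paper lm.csv --meta meta.csv --perm 999 --seed 7 --out results/
```

`replicate-paper` writes the full artifact set: sample summary, cut-off
table, model terms, sex-distance table (whole sample and two 20-year age
groups), the 4-cohort distance matrix, aging-rate curves, PCA scores and
wireframe SVGs.

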