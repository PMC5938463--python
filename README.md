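# snailmorph

Disentangling genetic and plastic control of shell morphology in clonal
snail populations.

Invasive European populations of the New Zealand mud snail *Potamopyrgus
antipodarum* are wholly asexual and genetically depauperate — a handful of
clonal lineages spread across lakes, streams and brackish waters — yet their
shells vary enormously in shape and size. Because clonal genotypes are
inherited intact, a field survey of such populations acts as a natural
transplant experiment: variation that tracks lineage is genetic, variation
that tracks habitat is plastic. `snailmorph` implements the full analysis
chain for this design, for researchers in evolutionary ecology and
malacology who work with landmark data and clonal marker panels:

- **Geometric morphometrics** — TPS landmark I/O, centroid size
  CS = √Σᵢ‖pᵢ − p̄‖², partial generalized Procrustes superimposition
  (det = +1, reflections disallowed), tangent projection, allometric
  correction by regressing Procrustes coordinates on CS, PCA/CVA ordination,
  pairwise mean-shape permutation tests with Bonferroni-adjusted alpha, and
  Goodall's F repeatability test with df (2k−4, (2k−4)(n₁+n₂−2)).
- **Clonal genetics** — haplotype divergence and assignment; the
  dosage-agnostic two-characters-per-locus genotype encoding (alleles in
  alphabetical order, "??" for missing); multilocus genotype collapsing;
  pairwise-deletion genotype distances; median-joining networks.
- **Variance partitioning** — linear and generalized (Laplace) mixed models
  with haplotype and genotype-nested-in-haplotype random intercepts,
  y = Xβ + Z₁u₁ + Z₂u₂ + ε, marginal/conditional R²
  (R²m = var(Xβ̂)/[var(Xβ̂) + σ²ₕ + σ²_g + σ²_dist], R²c adds the random
  terms to the numerator), type-II Wald χ² tables and backward model
  reduction.
- **Synthetic cohorts** — a seeded generator producing TPS/CSV/FASTA inputs
  with lineage-structured shapes, environment-driven size, allometry, clonal
  genotypes and brood counts, plus the ground truth for recovery tests.

The fit/transform stages are scikit-learn-style estimators
(`GeneralizedProcrustes`, `AllometricRegression`, `ShapePCA`, `ShapeCVA`,
`LinearMixedModel`, `GeneralizedLinearMixedModel`) with functional wrappers
(`gpa`, `pca`, `cva`, `fit_lmm`, ...).

## Worked example

```python
import snailmorph as sm
from snailmorph.mixed_models import ModelSpec, build_design, fit_lmm, r2_nakagawa

# synthetic survey: 21 sites x 20 snails, two lineages at 92%/8%
cfg = sm.GeneratorConfig(seed=1)
configs, specimens, sites, genotypes, refs, truth = sm.generate_cohort(cfg)

aligned = sm.tangent_project(sm.gpa(configs))
allom = sm.allometric_regression(aligned, n_perm=999, seed=1)
space = sm.pca(allom.residuals_)
print(f"allometry R^2 = {allom.r_squared_:.4f} (p = {allom.permutation_p_})")
print(f"PC1-3 explain {space.pct_variance[:3].sum():.2f}% of shape variance")

merged = specimens.merge(sites, on="site_id")
merged["pc1"] = space.scores[:, 0]
design = build_design(merged, ModelSpec(
    response="pc1", fixed=["temperature", "latitude", "nitrate"],
    random=("haplotype", "genotype")))
fit = fit_lmm(design, method="reml")
r2m, r2c = r2_nakagawa(fit)
print({k: round(v, 5) for k, v in fit.variance_components.items()})
print(f"R2 marginal = {r2m:.3f}, conditional = {r2c:.3f}")
```

Output (seed 1):

```
allometry R^2 = 0.0434 (p = 0.001)
PC1-3 explain 59.15% of shape variance
{'haplotype': 0.00619, 'genotype_in_haplotype': 0.00014, 'residual': 3e-05}
R2 marginal = 0.006, conditional = 0.996
```

Reading: allometry accounts for ~4% of shape variation and is removed; the
first three shape axes carry most of the remaining variance; and nearly all
PC1 variance sits in the two genetic random terms (haplotype ten-fold above
genotype-within-haplotype), with only a sliver attributable to the
environmental covariates — shape is lineage-bound. Running the same model on
CS instead gives a haplotype variance of exactly 0 with large environmental
effects: size is plastic.

The ten published reference genotypes are bundled:

```python
gs = {g.genotype_id: g for g in sm.reference_genotypes()}
sm.mlg_distance(gs["9"], gs["10"])      # 3 substitutions
net = sm.median_joining_network(list(gs.values()))
```

A command-line interface wraps the pipeline:

```bash
snailmorph run --seed 1 --out results/run1          # simulate + full analysis
snailmorph models --run-dir results/run1            # re-fit models from artifacts
snailmorph fixtures --out results/fixtures          # reference genotype network
snailmorph morpho --landmarks shells.tps --out aligned.csv
```

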