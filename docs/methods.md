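# Methods

`snailmorph` reimplements, as one tested pipeline, a field-survey analysis
that asks how much of the shell-morphology variation in clonal, invasive
populations of the New Zealand mud snail *Potamopyrgus antipodarum* is
genetic (lineage-bound) and how much is plastic (environment-driven). The
pipeline has three arms — landmark geometric morphometrics, clonal
genotyping with network reconstruction, and mixed-model variance
partitioning — plus a synthetic-data generator that stands in for field
data.

## Geometric morphometrics

Each shell is a configuration of k = 20 two-dimensional landmarks (apex, six
suture/outline intersections, body-whorl extremes, four aperture extremes,
seven auxiliary outline points), read from TPS files with SCALE applied so
coordinates and centroid size (CS) are in mm. CS is the square root of the
summed squared landmark distances from the configuration centroid — the only
size measure independent of shape.

Superimposition is *partial* generalized Procrustes analysis: centre each
configuration, scale to unit CS, rotate onto the running consensus by the
optimal orthogonal rotation with det = +1 (shells are chiral, so reflections
are disallowed; a flag re-enables them), recompute the consensus, iterate.
Convergence is a root-mean-square consensus change below 1e-10 with at most
100 iterations; non-convergence flags the result instead of raising. The
converged solution is rotated onto the configuration with the
lexicographically smallest specimen id, which makes the output independent
of input order. Tangent-space projection at the consensus (orthogonal, hence
idempotent) is available and is the pipeline default; both code paths exist
because the choice is second-order at the deviations seen here (O(dev²)),
and the run manifest records which was used.

Allometry is removed by multivariate linear regression of the 2k Procrustes
coordinates on CS (raw CS by default, log CS optional). The pooled
R² is predicted-SS over total-SS summed across coordinates; its permutation
test shuffles CS against shapes with p = (1 + #{perm ≥ obs})/(n_perm + 1),
the +1 convention avoiding p = 0. All downstream shape analyses use the
residuals.

Ordination: PCA of the residual covariance matrix (coordinates are
commensurate, so no correlation-matrix option is needed), with the sign
convention that each loading's largest-magnitude entry is positive; in the
pipeline PC1 is additionally oriented so the dominant haplotype (the slender
morph) scores positive. CVA solves the between- versus pooled-within-group
eigenproblem in the subspace where the within covariance is non-singular
(rank truncation at relative eigenvalue 1e-10), retaining at most
min(g − 1, rank) axes.

Group mean-shape differences use the Euclidean distance between mean shape
vectors in the tangent space (the standard approximation to Procrustes
distance after superimposition), tested by reshuffling each pair's specimens
with group sizes preserved (default 10,000 rounds). Significance is judged
against a Bonferroni-adjusted alpha (alpha / number of pairs) reported
alongside raw p-values, not against adjusted p-values. Digitisation
repeatability uses Goodall's F,

    F = [d² / (1/n1 + 1/n2)] / [SS_within / (n1 + n2 − 2)],

with df (q, q(n1+n2−2)), q = 2k − 4; both sample sizes are explicit
arguments.

## Clonal genetics

Mitochondrial haplotypes are compared by site-wise divergence over aligned
fragments (N/-/? sites excluded from numerator and denominator; percentages
rounded half-up to two decimals) and queries are assigned to the nearest
reference, with exact ties flagged and one-off variants suggested a derived
name.

SNP genotypes use the dosage-agnostic clonal encoding: each variable locus
contributes two characters, the two allelic states in alphabetical order, so
homozygotes are doubled letters, heterozygotes two different letters, and
missing loci are "??". Because these populations reproduce by apomictic
parthenogenesis, multilocus genotypes are inherited intact and individuals
with identical encoded strings collapse into named genotypes (numbered by
descending abundance; the missing symbol is a distinct literal, so
genotypes differing only in missingness stay distinct). Genotype distances
count unequal non-missing positions under pairwise deletion — a
pseudo-metric: the triangle inequality can fail when missingness differs,
which is documented rather than asserted. Pairwise deletion (not column
masking) is required to keep the published ten-genotype set distinct.

The bundled reference genotype table preserves the published alignment
verbatim, two printed positions per locus with dots expanded against the
first row. Note that the printed pairs are not all alphabetically ordered;
the table is shipped as printed and distances operate on the literal
strings, while `encode_genotype` applied to raw calls always sorts.

The median-joining network builds the ε-relaxed minimum spanning network
(a link survives iff its endpoints are disconnected using strictly shorter
links, with ε classes of slack), then adds median vectors — position-wise
majority consensus of connected triplets — while they reduce the
minimum-spanning cost, and finally prunes medians of degree < 3.
Tie-breaking is lexicographic on (weight, node id), so results are
deterministic under fixed input order.

## Mixed models

All response variables (shape PC1, CS, smooth/ridged, embryo count) are
modelled with two independent random intercepts: haplotype and genotype
nested in haplotype (nesting is validated; violations raise). Continuous
predictors are standardized; flow (none < low < high) and turbidity
(clear < unclear) are ordinal integer scores; interactions are products of
standardized columns. Predictors flagged by the Kendall-tau collinearity
screen (default threshold 0.38, with an explicit drop-list mapping salinity
to conductivity and longitude to latitude) never enter a model.

The Gaussian LMM profiles the likelihood over the two variance ratios
g_j = σ_j²/σ² on the log scale (Nelder-Mead, three starts to guard local
optima), with fixed effects by GLS at the optimum; ML and REML are both
available. Because the combined random-effect design has only
q = (haplotypes + genotypes) columns, all solves use the Woodbury identity
on q×q matrices, so n in the thousands costs milliseconds. Ratios driven to
the boundary are reported as exact-zero variance components with a flag.

GLMMs (binomial-logit for smoothness, Poisson-log default for embryo counts;
a Gaussian switch exists for sensitivity runs since the original family is
not recorded) maximise a Laplace-approximate marginal likelihood; the inner
loop is penalized IRLS on the joint (β, u) vector, the outer loop optimizes
the two log-variances. Possible complete separation triggers a warning.

Marginal/conditional R² follow the variance-partition definition:
R²m = var(Xβ̂) / (var(Xβ̂) + Σσ²_random + σ²_dist), R²c adds the random
components to the numerator, with σ²_dist the residual variance (Gaussian),
π²/3 (logit), or the trigamma value at the intercept-implied rate (Poisson;
the lognormal alternative is available and the choice is recorded on the
fit). Type-II Wald chi-squares test each term in a refit that excludes
interactions containing it; backward reduction drops the least significant
droppable term (p > 0.05, interactions before their main effects) with a
full audit trail.

## Synthetic cohort generator

Defaults encode the surveyed conditions: 21 sites × 20 specimens (~425
snails), lineage frequencies 0.92/0.08, and the ten published reference
genotypes nested eight/two within the lineages (the central genotype at 80%
within the common lineage, one outlier several steps away). Shape is built
in the 40-dimensional Procrustes space: a slender template for the common
lineage, a stouter one (x-axis × 1.30) for the rare lineage, per-genotype
clonal offsets mostly along the slender–stout axis (sd 0.007 plus isotropic
0.002), weak environmental effects along that axis (temperature −0.003,
latitude +0.003, nitrate +0.003 per standardized unit, positive = more
slender), an allometric shift of 0.005 per CS standard deviation (giving a
cohort allometric R² near the ~0.03 the analysis expects), and isotropic
landmark noise of sd 0.005. Centroid size is environment-only by default
(base 4.0 mm; flow +0.20, latitude +0.15, turbidity +0.15, nitrate −0.15,
coverage −0.12 per standardized unit; residual sd 0.20) — the headline
contrast (shape mostly genetic, size mostly plastic) is the generator's null
configuration, so pipeline-level acceptance is meaningful. Brood counts are
Poisson (negative-binomial optional) on a log link with intercept log 23
(the observed median), a size main effect, and slender×flow (+), size×flow
(−), size×turbidity (−) interactions. Salinity is generated as a
near-deterministic function of conductivity and longitude tracks latitude,
so the collinearity screen has real work to do. Everything is drawn from a
single seeded integer-state generator (`numpy` PCG64); identical seeds give
byte-identical output files.

What the generator does *not* emulate: digitisation error structure
(noise is isotropic and independent across landmarks unless a covariance is
supplied), within-site environmental heterogeneity (covariates are
site-constant point measurements), spatial autocorrelation among sites,
missing SNP calls by default, and any biomechanics of shell growth. Passing
recovery tests therefore demonstrates that the estimators recover the
injected structure under these idealized conditions, not that field data
meet them.

The bundled haplotype reference sequences are synthetic stand-ins generated
to show the published divergence pattern (six differing sites over 481 and
497 aligned positions, 1.25% and 1.21%); they are not the deposited
sequences.

## Recovery experiments and problem sizes

The acceptance experiments run at n = 2000 observations, 2 haplotypes × 10
genotypes, 200 seeds for the variance and R² recoveries, R = 1000 replicates
of 200 permutation rounds for the type-I calibration, and 50 full-pipeline
seeds for effect-direction recovery; the acceptance script uses 100/100/30
seeds for the same quantities. One caveat is structural: with only two
haplotype levels the population variance of that component is identified
only through the single realized between-level contrast (distributed as
σ²·χ²₁, median 0.455σ²), so the recovery experiments rescale the drawn
random effects to have realized (ddof = 1) variance exactly equal to the
nominal component — the estimator is then assessed against the variance
actually present in the data, which is the only quantity a two-level design
can recover.

## Known limitations

- Wald and likelihood-based inference for the two-level haplotype factor is
  anti-conservative in principle; the package reports components and flags
  boundaries but does not attempt small-sample corrections.
- The Laplace GLMM shares lme4's known downward bias for binomial variance
  components with few, small groups.
- The MJ network follows the published construction in spirit but its
  tie-breaking is its own documented convention; only tree-shaped cases are
  guaranteed to coincide with other implementations.
- Relative aperture defaults to area/height² (dimensionless); the
  area/height variant is available, and rankings differ only when heights
  vary jointly.
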