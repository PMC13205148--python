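# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `maizecore`, in the spirit of a
statistical-software methods appendix.

## Multi-environment mixed model and BLUP

Per trait, phenotypes from a multi-environment trial follow

    y_ikb = μ + E_i + G_k + (GE)_ik + ε_ikb

with environment `E_i` a fixed effect, genotype `G_k ~ N(0, σ²_g)` random,
interaction `(GE)_ik ~ N(0, σ²_ge)` random, and residual
`ε ~ N(0, σ²_res)`. Treating environment as fixed and genotype as random is
the standard choice for germplasm evaluation over a handful of
environments: the environments are the two that were planted, while the
lines are a sample whose effects we want to shrink and rank.

By default the three blocks are first averaged to one record per line ×
environment. On that path `(GE)` and `ε` are confounded (one observation
per cell) and the model fits a single combined residual; passing
`keep_reps=True` with replicate-level data unlocks the separate G×E
component. This confounding is a property of the design, not of the
implementation, and the variance-component JSON labels the combined term
`residual` accordingly.

**Estimation.** Balanced data use the closed-form ANOVA estimators
(`σ̂²_res = MS_res`, `σ̂²_g = (MS_G − MS_res)/n_env`, and the three-way
analogues with replicates), with negative estimates truncated at zero —
the REML convention. Unbalanced data use EM-REML on Henderson's mixed-model
equations with relative tolerance 1e-8 and at most 500 iterations; the EM
update keeps all components nonnegative and the restricted likelihood
non-decreasing (asserted by a test). The balanced closed form doubles as an
independent oracle: the two paths agree to 1e-6 on balanced inputs.

**BLUPs.** The balanced-case BLUP is `h·(ȳ_k − ȳ)` with shrinkage
`h = σ²_g/(σ²_g + σ²_comb/n_env)`. BLUPs are reported both as centred
deviations and on the trait scale (`μ +` deviation); downstream stages use
the trait scale, matching how adjusted phenotypes are normally tabulated.
Whether a published BLUP table includes the grand mean is often ambiguous,
so both forms are first-class.

**Duncan's multiple range test** uses studentized-range critical points at
protection level `1 − (1−α)^(r−1)` for a span of r ordered means, the
harmonic mean of the spanned group sizes in the standard error (which makes
the two-group case collapse exactly onto the pooled-variance t-test), and
homogeneity propagation from enclosing spans. Letters are assigned from the
largest mean as maximal homogeneous intervals. With three equal groups the
all-one-letter probability is `(1−0.05)² ≈ 0.9025` by construction, which
the null-calibration test verifies empirically.

## Diversity statistics

Sturges' class count is `k = round(1 + log₂N)` with half-up rounding —
the rounding dialect that reproduces k = 9/8/7/5 at N = 222/123/82/17
(ceiling would give 8 at N = 82 and 6 at N = 17 and is therefore rejected).
The Shannon–Wiener index uses k equidistant bins over the observed range
(last bin right-closed) and natural logarithms by default;
`H = −Σ p_i ln p_i` over non-empty bins, so `0 ≤ H ≤ ln k`. Reported
diversity indices above `ln 9 ≈ 2.197` at k = 9 cannot arise under this
definition and indicate a different base or binning; the base is therefore
configurable and no attempt is made to force agreement.

Per-SNP statistics use allele frequency `p` from non-missing calls of the
group in question with `n` allele copies: `MAF = min(p, 1−p)`; `Het` the
fraction of heterozygous calls; `π = n/(n−1)·2pq` (small-sample-corrected
per-site nucleotide diversity); `PIC = 1 − (p²+q²) − 2p²q²`. Monomorphic
loci yield zeros (valid values); loci with fewer than two usable calls are
skipped with a warning. Averages run over all analyzed sites by default
(segregating-only averaging would be a one-line filter upstream).
For a biallelic locus `PIC ≤ 2pq ≤ π` — a property test asserts this chain.

Pearson p-values come from the t transform with n−2 df and are reported
raw with 0.05/0.01/0.001/0.0001 stars (Benjamini–Hochberg adjustment is
available but off by default, matching common practice in trait-correlation
tables).

## Distances and the Mantel test

The default genotype metric is 1−IBS: `d_ij = mean(|g_i − g_j|)/2` over
shared non-missing loci — the customary metric for inbred dosage panels;
Euclidean-on-dosage is switchable. Phenotype distances are Euclidean on
z-scored BLUPs, so a single trait reduces to `|z_i − z_j|`.

The Mantel statistic is the Pearson correlation of upper-triangle entries;
the null permutes rows and columns of the second matrix simultaneously.
The test is one-sided upper-tail by default (the scientific question is
whether genetically distant lines are phenotypically distant), with
`p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1)`, so p can never fall below
`1/(n_perm+1)`. Default `n_perm = 999` with a mandatory recorded seed.
An exhaustive enumerator over all n! relabelings provides the exact
reference for small n, and `skbio`'s Mantel implementation serves as an
independent cross-check in the tests.

## GWAS

Kinship is the centred cross-product `K = ZZᵀ/m` over polymorphic SNPs with
per-SNP mean imputation of missing dosages. The null model
`y = 1μ + u + ε`, `u ~ N(0, σ²_g K)` is fitted by REML over
`δ = σ²_e/σ²_g` on a log₁₀ grid of [−5, 5] (bounded Brent, tolerance 1e-6)
after projecting out the intercept and rotating by the eigenvectors of the
projected kinship. Each SNP is then tested by GLS in the rotated
coordinates with δ fixed — the EMMAX approximation, orders of magnitude
faster than re-optimizing δ per SNP. A per-SNP exact-REML scan is kept as a
slow oracle; on small instances the two agree at rank correlation ≥ 0.99.
With `K = I` the scan reduces exactly to OLS with large-sample Wald
p-values (χ²₁), which the tests assert to 1e-6.

Monomorphic SNPs are skipped and a MAF ≥ 0.05 filter is applied before
scanning (configurable). Thresholds are fixed at suggestive 1e-5 and
genome-wide 5e-8. QQ data pair sorted observed p with uniform quantiles
`i/(m+1)`; `λ_GC = median(χ²)/0.4549`. Principal-component covariates are
deliberately omitted by default: relatedness correction is carried by the
kinship alone, and the calibration tests (null type-I in [0.03, 0.07],
λ_GC in [0.9, 1.1] under a structured null) confirm that is sufficient at
the simulated divergence levels.

## Clustering and trees

PCA is a centred (optionally z-scored) SVD with a deterministic sign
convention (largest-magnitude loading positive per component). K-means
(Lloyd, `n_init` restarts, fixed seed) chooses K by maximal mean
silhouette, with the elbow (largest second difference of WSS) reported
alongside rather than silently merged — when the two disagree, both are in
the output and the silhouette winner is used. Bi-clustering is Ward/
Euclidean on z-scored values, rows and columns independently; the trait
dendrogram is cut at three groups for comparison with the a-priori
grain/plant/tassel classes.

Neighbor joining follows Saitou–Nei exactly: `Q_ij = (n−2)d_ij − r_i −
r_j`, ties broken toward the lexicographically lowest label pair, two-point
branch lengths, `d_uk = (d_ik + d_jk − d_ij)/2` updates, and a final
trifurcation. Negative branch lengths (possible on non-additive inputs)
are clamped to zero with a warning. On additive inputs the tree reproduces
the input matrix to machine precision (tested to 1e-12 on four-taxon
matrices and 1e-10 on ultrametric ones, with `skbio.tree.nj` as an
independent oracle). A visual "N major clades" partition is exposed as
`cut_clades(N)`: remove the N−1 longest internal branches and read off the
leaf components.

## Core selection

Trait directions default to grain traits (KL, KW, LWR) positive and plant
architecture plus tassel traits negative — the compact, low-ear, modest-
tassel ideotype. Weights are CVs of the BLUPs over the whole panel,
normalized to sum 1 (per-subgroup CV weighting would be a one-line change
but mixes selection pools; the whole-panel convention is used throughout).

TOPSIS uses direction-coded min-max standardization (positive
`x′ = (x−min)/(max−min)`, negative `x′ = (max−x)/(max−min)`), weighting,
ideal/anti-ideal as column max/min, Euclidean distances, and
`D = d⁻/(d⁺+d⁻)`. Min-max with an explicit direction flip is chosen over
classic vector normalization because it honours positive/negative coding
cleanly and makes D invariant to affine rescaling of any raw trait; the
vector-normalization dialect is available behind a flag. Constant trait
columns are excluded with weight renormalization.

MNND defaults to the mean distance to all other lines, with a nearest-k
variant exposed — the acronym is used both ways in the literature, and
without raw genotypes the two cannot be distinguished from published
scores, so both are first-class with mean-all as default.

Selection is two-stage: the top `n_stage1 = 50` lines by D, then the top
`n_final = 30` by `0.8·D̃ + 0.2·M̃` where D and MNND are min-max scaled
within the stage-1 set. The scaling step is an inference forced by scale
incommensurability: D lives in ≈[0.7, 0.87] and MNND on the raw distance
scale, so raw 0.2/0.4-style weighting would let the distance scale dominate
or vanish depending on the metric's units. Ties break toward higher MNND,
then label order, making the selection deterministic.

## Synthetic-data generator

The generator emulates a structured specialty-maize panel: 222 lines split
123/82/17 across three subpopulations, 2 environments × 3 blocks, 10 traits.
Subpopulation allele frequencies follow the Balding–Nichols model
`Beta(p(1−F)/F, (1−p)(1−F)/F)` around an ancestral frequency drawn
uniformly from the MAF range (0.05, 0.5], with a single F shared across
loci (default 0.2 — a moderate divergence typical of specialty-maize
subgroups; a Hudson-FST recovery test confirms realized divergence tracks
F). Ancestry vectors are Dirichlet with extra concentration on each line's
primary subpopulation (expected primary share ≈ 0.9, i.e. mostly pure
lines with visible admixture). Calls are Binomial(2, p_line); an optional
inbreeding coefficient correlates the two allele draws for users who want
selfed-panel heterozygosity, but it is off by default so the binomial
contract holds exactly. Missingness is injected uniformly at a configurable
rate (default 0, matching post-QC data).

Genetic values combine planted-QTL contributions (default 5 QTLs, effects
0.4 on the standardized trait scale, assigned round-robin to the eight
base traits) with a polygenic term whose line-by-line covariance is the
centred-genotype kinship and whose trait-by-trait correlation is a
hand-set PSD matrix encoding the panel's qualitative structure (tall plants
carry high ears, tassel lengths move together, kernel dimensions couple
weakly). The polygenic variance tops the genetic variance up to the
configured `var_g`, so the total genetic variance matches the component in
expectation regardless of how much the QTLs explain. Environment, G×E and
residual effects are independent normals with the configured variances.
Default variance shares are 0.60/0.10/0.10/0.20 (genotype/environment/
G×E/residual) on the standardized scale — a strongly heritable trait set,
appropriate for inbred lines evaluated as plot means; per-trait scales and
means default to the magnitudes of a real specialty-maize panel (e.g. PH
mean 120.52 cm, SD 29.07), so fixtures look realistic. The ratio traits
LWR = KL/KW and EPR = EH/PH are always derived, never simulated.

What the generator does **not** emulate: linkage disequilibrium blocks
(SNPs are exchangeable given ancestry), selection/drift history, assay
error structure, or trait non-normality. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every feature of field data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale — panels of 60–400 lines
and 100–2000 SNPs, 10–20 Monte-Carlo seeds per calibration — sizes chosen
so each recovery check has enough power to detect a wrong estimator while
the whole suite stays interactive. Every stochastic component takes an
explicit seed; identical configurations reproduce outputs bit-for-bit, and
the pipeline manifest records package version, seeds, parameters, and
input hashes.

## Known limitations

- Replicate-level block effects are not modelled (blocks are averaged,
  following the no-block-difference preliminary finding the design
  assumes); no spatial field-trend correction.
- Single-trait mixed models only; no AMMI/GGE stability analysis.
- The EMMAX fixed-δ approximation slightly miscalibrates when a tested SNP
  explains a large fraction of variance (the exact per-SNP oracle exists
  for auditing).
- Bayesian admixture inference is out of scope; ancestry labels are
  consumed from annotation files.
- The published core-set identity cannot be reproduced without the original
  genotypes; the selector is validated against oracles and the published
  table's internal statistics instead.
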