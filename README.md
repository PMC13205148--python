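# maizecore

Germplasm evaluation and core-collection selection for specialty maize
inbred panels (sweet, waxy, sweet–waxy), combining multi-environment
phenotypes with genome-wide SNP data.

Breeding programmes sit on large collections of inbred lines and need a
small, representative, phenotypically superior core set. `maizecore`
implements the full evaluation chain for that decision:

1. **Multi-environment BLUP.** Per trait, the mixed model
   `y_ik = μ + E_i + G_k + (GE)_ik + ε_ik` with environment fixed and
   genotype (and, given replicate-level data, G×E) random. Balanced data
   are solved by closed-form ANOVA/REML estimators, unbalanced data by
   EM-REML on Henderson's mixed-model equations; per-line BLUPs
   `μ + h·(ȳ_k − ȳ)` with `h = σ²_g/(σ²_g + σ²_res/n_env)` replace raw
   means in every downstream analysis.
2. **Diversity statistics.** Descriptive statistics and CVs, Shannon–Wiener
   indices over Sturges-binned (`k = round(1 + log₂N)`) trait values,
   Pearson correlations with significance stars; per-SNP MAF, observed
   heterozygosity, nucleotide diversity `π = n/(n−1)·2pq` and
   `PIC = 1 − (p² + q²) − 2p²q²`, overall and per subgroup.
3. **Genotype–phenotype correspondence.** 1−IBS genotype distances,
   Euclidean distances on z-scored BLUPs, and Mantel permutation tests
   (overall and per trait).
4. **GWAS.** EMMAX-style LMM: one REML fit of δ = σ²_e/σ²_g on the null
   model via the spectral decomposition of the kinship `K = ZZᵀ/m`, then
   per-SNP GLS in rotated coordinates; QQ data and λ_GC diagnostics.
5. **Structure.** Dual PCA (SNPs and BLUPs), K-means with silhouette/elbow
   model selection, Ward bi-clustering of lines and traits, and a
   Saitou–Nei neighbor-joining tree with an N-clade cut.
6. **Core selection.** TOPSIS D values `D = d⁻/(d⁺ + d⁻)` from
   direction-coded, CV-weighted, min-max standardized BLUPs (grain traits
   positive; plant architecture and tassel traits negative), MNND genetic
   uniqueness from the distance matrix, and a two-stage rule: top 50 by D,
   then top 30 by `0.8·D̃ + 0.2·MNND̃` (both min-max scaled within the
   stage-1 set).

A synthetic-data generator (Balding–Nichols subpopulation divergence,
Dirichlet admixture, planted QTLs, correlated traits with genotype /
environment / G×E / residual variance components) provides ground truth for
parameter-recovery tests of every stage. The published 30-line core-set
table ships as a reference fixture (`maizecore.load_core30_reference()`).

## Worked example

The analysis scripts run the whole chain on a synthetic 222-line panel
(123 sweet / 82 waxy / 17 sweet–waxy, 2 environments × 3 blocks,
2000 SNPs):

```sh
python analysis/01_simulate_panel.py
python analysis/02_blup.py
python analysis/03_diversity.py
python analysis/04_distances_mantel.py
python analysis/05_gwas.py
python analysis/06_clustering_tree.py
python analysis/07_core_selection.py
```

which prints, among other things:

```
panel: 222 lines x 2000 SNPs, subgroups {'SHT': 123, 'SHN': 82, 'SHTN': 17}, 2 envs x 3 blocks
fitted 10 traits; genotype variance shares: {'KL': 0.784, ..., 'PH': 0.757, ...}
highest CVs: ['TPN', 'EH']; Sturges k per group: {'all': 9, 'waxy': 7, 'sweet': 8, 'sweet-waxy': 5}
strongest trait correlation: ('LUL', 'LUT') r = 0.73
overall genotype-phenotype Mantel r = 0.2411 (p = 0.001)
PH: lambda_GC = 0.979, 1 suggestive / 0 genome-wide hits; top SNP chr8:5818212 (p = 3.03e-06)
K-means: silhouette-optimal K = 2, elbow K = 3
selected 30 core lines; D in [0.6088, 0.7058] (range 0.0970)
composition by type: {'sweet': 29, 'waxy': 1}
```

Reading the output: genotype captures ~75–80% of phenotypic variance per
trait under the generator's default heritability, the Sturges class counts
match the panel and subgroup sizes (9/8/7/5), the tassel length traits are
the most strongly correlated pair, the Mantel test finds a weak but
significant genotype–phenotype correspondence, and the two-stage selector
returns a 30-line core set dominated by the largest subgroup. Each script
writes its tables under `results/`.

The same pipeline is available as subcommands
(`maizecore simulate|blup|diversity|mantel|gwas|cluster|njtree|select-core|report`)
and as a single orchestrated run with a reproducibility manifest
(`maizecore.run_pipeline`).

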