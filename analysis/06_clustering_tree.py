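#!/usr/bin/env python
"""Dual PCA, K-means with data-driven K, trait bi-clustering, and the NJ tree.

PCA runs independently on SNP dosages and on the trait BLUPs; K-means on
z-scored BLUPs picks K by silhouette (elbow reported alongside); the trait
dendrogram is cut at three groups against the a-priori Grain/Plant/Tassel
classes; the 1-IBS NJ tree is cut into 16 clades for annotation.
"""

from pathlib import Path

import pandas as pd

from maizecore import hierarchical_bicluster, kmeans_select, nj_tree, pca, read_vcf
from maizecore.distance import read_distance_tsv

OUT = Path("results/cluster")
SEED = 2027


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno = read_vcf("results/panel/genotypes.vcf")
    blups = pd.read_csv("results/blup/blups.csv", index_col="line_id")

    pca_g = pca(pd.DataFrame(geno.masked().filled(0.0), index=geno.line_ids))
    pca_g.scores.iloc[:, :5].round(4).to_csv(OUT / "geno_pca_scores.tsv", sep="\t")
    pca_p = pca(blups, standardize=True)
    pca_p.scores.iloc[:, :5].round(4).to_csv(OUT / "pheno_pca_scores.tsv", sep="\t")
    pca_p.loadings.iloc[:, :5].round(4).to_csv(OUT / "pheno_pca_loadings.tsv",
                                               sep="\t")

    Z = (blups - blups.mean()) / blups.std(ddof=1)
    km = kmeans_select(Z, range(2, 9), seed=SEED)
    km.assignments.to_csv(OUT / "kmeans_clusters.tsv", sep="\t")
    km.cluster_means.round(3).to_csv(OUT / "kmeans_cluster_means.tsv", sep="\t")

    bic = hierarchical_bicluster(blups)
    pd.DataFrame({"trait_group": bic.trait_groups,
                  "apriori": bic.apriori_classes}).to_csv(
        OUT / "trait_groups.tsv", sep="\t")

    gdist = read_distance_tsv("results/mantel/geno_dist.tsv")
    tree = nj_tree(gdist)
    (OUT / "nj_tree.nwk").write_text(tree.newick() + "\n")
    clades = pd.Series(tree.cut_clades(16), name="clade")
    clades.rename_axis("line_id").to_csv(OUT / "nj_clades.tsv", sep="\t")

    print(f"genotypic PCA PC1+PC2: {pca_g.explained_pct[:2].sum():.1f}%; "
          f"phenotypic PCA PC1+PC2: {pca_p.explained_pct[:2].sum():.1f}%")
    print(f"K-means: silhouette-optimal K = {km.k}, elbow K = {km.elbow_k}")
    agree = (bic.trait_groups.groupby(bic.apriori_classes).nunique() == 1).mean()
    print(f"trait dendrogram vs a-priori classes: {agree:.0%} of classes uncut; "
          f"NJ tree cut into {clades.nunique()} clades -> {OUT}")


if __name__ == "__main__":
    main()
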