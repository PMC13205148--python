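#!/usr/bin/env python
"""Phenotypic and genotypic diversity of the panel and its subgroups.

Descriptive statistics with CVs, Sturges-binned Shannon indices, Pearson
correlations with significance stars, and per-SNP MAF/Het/pi/PIC summaries
overall and per specialty type, under results/diversity/.
"""

from pathlib import Path

import pandas as pd

from maizecore import (
    cv_table, locus_stats, pearson_matrix, read_vcf, shannon_index, sturges_k,
)
from maizecore.io import line_type, write_json

OUT = Path("results/diversity")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    blups = pd.read_csv("results/blup/blups.csv", index_col="line_id")
    groups = pd.Series([line_type(l) for l in blups.index], index=blups.index)

    summary = cv_table(blups, groups)
    summary.to_csv(OUT / "trait_summary.tsv", sep="\t", index=False,
                   float_format="%.4g")
    top_cv = summary[summary.group == "all"].nlargest(2, "CV")["trait"].tolist()

    shannon = {}
    for label, sub in [("all", blups)] + [(g, blups[groups == g])
                                          for g in groups.unique()]:
        k = sturges_k(len(sub))
        shannon[label] = {"k": k, **{t: round(shannon_index(sub[t], k).H, 4)
                                     for t in sub.columns}}
    write_json(shannon, OUT / "shannon.json")

    r, p, stars = pearson_matrix(blups)
    r.round(3).to_csv(OUT / "pearson_r.tsv", sep="\t")
    stars.to_csv(OUT / "pearson_stars.tsv", sep="\t")

    geno = read_vcf("results/panel/genotypes.vcf")
    stats = locus_stats(geno, [line_type(l) for l in geno.line_ids])
    snp_summary = {grp: {k: round(v, 4) for k, v in s.summary().items()}
                   for grp, s in stats.items()}
    write_json(snp_summary, OUT / "snp_diversity.json")

    import numpy as np

    off_diag = r.mask(pd.DataFrame(np.eye(len(r), dtype=bool),
                                   index=r.index, columns=r.columns))
    strongest = off_diag.abs().stack().idxmax()
    print(f"highest CVs: {top_cv}; Sturges k per group: "
          f"{ {g: shannon[g]['k'] for g in shannon} }")
    print(f"strongest trait correlation: {strongest} "
          f"r = {off_diag.stack()[strongest]:.2f}")
    print(f"SNP diversity by group: {snp_summary} -> {OUT}")


if __name__ == "__main__":
    main()
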