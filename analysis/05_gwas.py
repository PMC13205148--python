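#!/usr/bin/env python
"""Kinship-corrected association scans for the Mantel-flagged traits.

EMMAX-style LMM per trait: one REML fit of the variance ratio on the null
model, then GLS per SNP in rotated coordinates; association tables, QQ data,
and the genomic-control inflation factor land under results/gwas/.
"""

from pathlib import Path

import pandas as pd

from maizecore import association_scan, compute_kinship, qq_data, read_vcf
from maizecore.gwas import GENOME_WIDE_P, SUGGESTIVE_P

OUT = Path("results/gwas")
TRAITS = ("KL", "PH", "LUL")  # the distance-associated trait set


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno = read_vcf("results/panel/genotypes.vcf")
    blups = pd.read_csv("results/blup/blups.csv", index_col="line_id")
    blups = blups.loc[geno.line_ids]
    K = compute_kinship(geno)

    for trait in TRAITS:
        res = association_scan(geno, blups[trait].to_numpy(), K=K)
        res.table.to_csv(OUT / f"assoc_{trait}.tsv", sep="\t", index=False,
                         float_format="%.6g")
        qq_data(res).to_csv(OUT / f"qq_{trait}.tsv", sep="\t", index=False,
                            float_format="%.6g")
        n_sugg = (res.table["p"] < SUGGESTIVE_P).sum()
        n_gw = (res.table["p"] < GENOME_WIDE_P).sum()
        top = res.table.nsmallest(1, "p").iloc[0]
        print(f"{trait}: lambda_GC = {res.lambda_gc:.3f}, "
              f"{n_sugg} suggestive / {n_gw} genome-wide hits; "
              f"top SNP {top.chrom}:{top.pos} (p = {top.p:.2e})")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
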