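#!/usr/bin/env python
"""Genotype-phenotype correspondence via Mantel permutation tests.

Builds the 1-IBS genotype distance matrix and Euclidean distances on
z-scored BLUPs (overall and per trait), then tests each phenotypic matrix
against the genotypic one with 999 label permutations.
"""

from pathlib import Path

import pandas as pd

from maizecore import genotype_distance, mantel_test, phenotype_distance, read_vcf
from maizecore.distance import write_distance_tsv

OUT = Path("results/mantel")
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno = read_vcf("results/panel/genotypes.vcf")
    blups = pd.read_csv("results/blup/blups.csv", index_col="line_id")

    gdist = genotype_distance(geno)
    write_distance_tsv(gdist, OUT / "geno_dist.tsv")
    overall = phenotype_distance(blups)
    write_distance_tsv(overall, OUT / "pheno_dist.tsv")

    rows = []
    for name, dm in [("overall", overall)] + [
            (t, phenotype_distance(blups, [t])) for t in blups.columns]:
        res = mantel_test(gdist, dm, n_perm=999, seed=SEED)
        rows.append({"trait": name, "r": round(res.r, 4),
                     "p": res.p_value, "n_perm": res.n_perm, "seed": SEED})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "mantel.tsv", sep="\t", index=False)

    sig = table[(table.p < 0.05) & (table.trait != "overall")]["trait"].tolist()
    ov = table[table.trait == "overall"].iloc[0]
    print(f"overall genotype-phenotype Mantel r = {ov.r} (p = {ov.p})")
    print(f"traits significantly associated with genetic distance: {sig} -> {OUT}")


if __name__ == "__main__":
    main()
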