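#!/usr/bin/env python
"""Generate the synthetic study panel: 222 lines, 3 subpopulations, 2 envs.

Writes genotypes (VCF), replicate-level phenotypes (CSV) and the simulation
ground truth (JSON) under results/panel/ for the downstream steps.
"""

from pathlib import Path

from maizecore import SimConfig, simulate_genotypes, simulate_phenotypes
from maizecore import io as io_mod

OUT = Path("results/panel")
SEED = 2025


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    geno, truth = simulate_genotypes(cfg)
    pheno = simulate_phenotypes(geno, truth, cfg)
    io_mod.write_vcf(geno, OUT / "genotypes.vcf")
    io_mod.write_phenotypes(pheno, OUT / "phenotypes.csv")
    io_mod.write_json(truth.to_dict(), OUT / "truth.json")
    n_sub = {p: sum(l.startswith(p) and not (p == "SHT" and l.startswith("SHTN"))
                    for l in geno.line_ids) for p in ("SHT", "SHN", "SHTN")}
    print(f"panel: {geno.n_lines} lines x {geno.n_snps} SNPs, "
          f"subgroups {n_sub}, {pheno.env.nunique()} envs x "
          f"{pheno.block.nunique()} blocks -> {OUT}")


if __name__ == "__main__":
    main()
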