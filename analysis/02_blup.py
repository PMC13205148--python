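#!/usr/bin/env python
"""Fit the multi-environment mixed model per trait and extract BLUPs.

Blocks are averaged per line x environment, environment is fixed, genotype
random; variance components, their proportions, per-line BLUPs, and a
subgroup ANOVA with Duncan letters are written under results/blup/.
"""

from pathlib import Path

import pandas as pd

from maizecore import (
    anova_duncan, extract_blups, fit_all_traits, read_phenotypes,
    variance_proportions,
)
from maizecore.io import line_type, write_json

OUT = Path("results/blup")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = read_phenotypes("results/panel/phenotypes.csv")
    models = fit_all_traits(pheno)
    blups = extract_blups(models)
    blups.to_csv(OUT / "blups.csv")
    comp = {t: {"components": m.components,
                "proportions": variance_proportions(m)}
            for t, m in models.items()}
    write_json(comp, OUT / "variance_components.json")

    groups = pd.Series([line_type(l) for l in blups.index], index=blups.index)
    rows = []
    for trait in blups.columns:
        res = anova_duncan(blups[trait], groups)
        for g, mean in res.means.items():
            rows.append({"trait": trait, "group": g, "mean": round(mean, 3),
                         "letters": res.letters[g],
                         "anova_p": f"{res.p_value:.3g}"})
    duncan = pd.DataFrame(rows)
    duncan.to_csv(OUT / "duncan_letters.tsv", sep="\t", index=False)

    g_share = {t: round(comp[t]["proportions"]["genotype"], 3) for t in blups}
    print(f"fitted {len(models)} traits; genotype variance shares: {g_share}")
    sig = duncan[duncan.anova_p.astype(float) < 0.05]["trait"].nunique()
    print(f"subgroup ANOVA significant (p<0.05) for {sig}/{len(blups.columns)} traits "
          f"-> {OUT}")


if __name__ == "__main__":
    main()
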