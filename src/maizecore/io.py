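"""Readers and writers for the formats the pipeline touches.

VCF in/out (biallelic SNPs, GT field, dosage = ALT-allele count), phenotype
CSV (line_id, env, block, ten trait columns with the ratio traits recomputed
when absent), distance TSV, Newick, and the reference core-set table bundled
with the package.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, TRAITS, derive_ratio_traits, validate_pheno

# plausible measurement ranges per trait (unit sanity logging only)
_SANITY_RANGES = {
    "KL": (2, 20), "KW": (2, 15), "LWR": (0.5, 3), "PH": (30, 300),
    "EH": (2, 200), "EPR": (0.01, 1), "TPN": (0, 60), "TBL": (1, 60),
    "LUL": (2, 80), "LUT": (1, 60),
}


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Multi-allelic and non-SNP records are skipped (counted in a warning);
    dosage is the ALT-allele count with heterozygotes = 1 regardless of
    phasing; missing genotypes are preserved in the mask.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    dosages, missing, chroms, poss, refs, alts = [], [], [], [], [], []
    skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gt = rec.genotype.array()  # (n_samples, ploidy+1); -1 = missing
        alleles = gt[:, :2]
        miss = (alleles < 0).any(axis=1)
        dos = np.where(miss, 0, alleles.clip(min=0).sum(axis=1)).astype(float)
        dosages.append(dos)
        missing.append(miss)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic/non-SNP records", stacklevel=2)
    if not dosages:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(
        dosage=np.array(dosages).T,
        missing=np.array(missing).T,
        line_ids=samples,
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=int),
        ref=np.array(refs),
        alt=np.array(alts),
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCF (GT only, CHROM/POS monotone per chrom)."""
    order = np.lexsort((geno.pos, geno.chrom))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(geno.chrom[order]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.line_ids) + "\n")
        ref = geno.ref if geno.ref is not None else np.full(geno.n_snps, "A")
        alt = geno.alt if geno.alt is not None else np.full(geno.n_snps, "T")
        for j in order:
            calls = [
                "./." if geno.missing[i, j] else gt_map[int(geno.dosage[i, j])]
                for i in range(geno.n_lines)
            ]
            fh.write(f"{geno.chrom[j]}\t{geno.pos[j]}\t.\t{ref[j]}\t{alt[j]}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a replicate- or line-level phenotype CSV.

    Requires ``line_id`` and ``env`` columns; validates the ten trait names,
    recomputes LWR = KL/KW and EPR = EH/PH when absent, and logs unit-range
    oddities.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty phenotype file: {path}")
    validate_pheno(df)
    df = derive_ratio_traits(df)
    for trait, (lo, hi) in _SANITY_RANGES.items():
        if trait in df.columns:
            x = df[trait].dropna()
            if len(x) and ((x < lo) | (x > hi)).mean() > 0.05:
                warnings.warn(
                    f"{trait}: >5% of values outside plausible range [{lo}, {hi}]",
                    stacklevel=2,
                )
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    cols = ["line_id", "env"] + (["block"] if "block" in pheno.columns else [])
    cols += [t for t in TRAITS if t in pheno.columns]
    pheno[cols].to_csv(path, index=False, float_format="%.6g")


def line_type(line_id: str) -> str:
    """Specialty type from the line-name prefix (SHTN before SHT)."""
    if line_id.startswith("SHTN"):
        return "sweet-waxy"
    if line_id.startswith("SHT"):
        return "sweet"
    if line_id.startswith("SHN"):
        return "waxy"
    return "unknown"


def load_core30_reference() -> pd.DataFrame:
    """The published 30-line core-set table bundled with the package."""
    with importlib.resources.files("maizecore.data").joinpath("core30.csv").open() as fh:
        df = pd.read_csv(fh, index_col="line_id")
    df["type"] = [line_type(l) for l in df.index]
    return df


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
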