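"""Shared in-memory containers for the pipeline.

Genotypes are dosage-coded (count of ALT alleles, 0/1/2) with an explicit
missing mask; phenotypes travel as tidy pandas DataFrames with one row per
observation (``line_id``, ``env``, ``block``, one column per trait).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The ten agronomic traits, in canonical order: grain (KL, KW, LWR),
#: plant architecture (PH, EH, EPR), tassel (TPN, TBL, LUL, LUT).
TRAITS = ("KL", "KW", "LWR", "PH", "EH", "EPR", "TPN", "TBL", "LUL", "LUT")

#: Base traits that are measured directly; LWR = KL/KW and EPR = EH/PH are ratios.
BASE_TRAITS = ("KL", "KW", "PH", "EH", "TPN", "TBL", "LUL", "LUT")

#: A-priori trait classes used for the bi-clustering comparison.
TRAIT_CLASSES = {
    "KL": "Grain", "KW": "Grain", "LWR": "Grain",
    "PH": "Plant", "EH": "Plant", "EPR": "Plant",
    "TPN": "Tassel", "TBL": "Tassel", "LUL": "Tassel", "LUT": "Tassel",
}


@dataclass
class GenotypeMatrix:
    """Lines x biallelic SNPs dosage matrix with positional metadata.

    Parameters
    ----------
    dosage
        ``(n_lines, n_snps)`` float array of ALT-allele counts in {0, 1, 2};
        entries where ``missing`` is True are ignored (stored value arbitrary).
    missing
        boolean mask of the same shape, True where the call is missing.
    line_ids, chrom, pos
        labels for rows and SNP coordinates (1-based positions, as in VCF).
    """

    dosage: np.ndarray
    missing: np.ndarray
    line_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.dosage.shape != self.missing.shape:
            raise ValueError("dosage and missing mask shapes differ")
        if len(self.line_ids) != self.dosage.shape[0]:
            raise ValueError("line_ids length does not match dosage rows")
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        if self.chrom.shape[0] != self.dosage.shape[1]:
            raise ValueError("chrom length does not match dosage columns")

    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def masked(self) -> np.ma.MaskedArray:
        """Dosages as a masked array (mask = missing)."""
        return np.ma.masked_array(self.dosage, mask=self.missing)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP ALT allele frequency over non-missing calls (NaN if none)."""
        m = self.masked()
        with np.errstate(invalid="ignore"):
            return np.asarray(m.mean(axis=0).filled(np.nan)) / 2.0

    def subset_lines(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosage=self.dosage[idx],
            missing=self.missing[idx],
            line_ids=[self.line_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
        )


def validate_pheno(df: pd.DataFrame, require_blocks: bool = False) -> pd.DataFrame:
    """Validate a phenotype table: required id columns and known trait columns."""
    required = ["line_id", "env"] + (["block"] if require_blocks else [])
    for col in required:
        if col not in df.columns:
            raise ValueError(f"phenotype table missing required column {col!r}")
    unknown = [
        c for c in df.columns
        if c not in ("line_id", "env", "block") and c not in TRAITS
    ]
    if unknown:
        import warnings

        warnings.warn(f"ignoring unknown trait columns: {unknown}", stacklevel=2)
    return df


def derive_ratio_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Fill in LWR = KL/KW and EPR = EH/PH when absent from a phenotype table."""
    out = df.copy()
    if "LWR" not in out.columns and {"KL", "KW"} <= set(out.columns):
        out["LWR"] = out["KL"] / out["KW"]
    if "EPR" not in out.columns and {"EH", "PH"} <= set(out.columns):
        out["EPR"] = out["EH"] / out["PH"]
    return out
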