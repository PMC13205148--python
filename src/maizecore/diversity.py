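"""Phenotypic and genotypic diversity statistics.

Phenotypic side: descriptive statistics with coefficients of variation,
Shannon–Wiener diversity over Sturges-binned trait values, and pairwise
Pearson correlations with significance stars. Genotypic side: per-SNP minor
allele frequency (MAF), observed heterozygosity (Het), per-site nucleotide
diversity (pi, with the n/(n-1) small-sample correction) and polymorphism
information content (PIC), overall and per subgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix


# ---------------------------------------------------------------------------
# phenotypic diversity
# ---------------------------------------------------------------------------

def sturges_k(n: int) -> int:
    """Sturges' histogram class count, k = round(1 + log2 n), half-up."""
    if n < 2:
        raise ValueError("Sturges' rule needs n >= 2")
    return int(np.floor(1.0 + np.log2(n) + 0.5))


@dataclass
class ShannonResult:
    k: int
    edges: np.ndarray
    freqs: np.ndarray
    H: float
    base: float | None  # None = natural log

    @property
    def H_max(self) -> float:
        log = np.log if self.base is None else (lambda x: np.log(x) / np.log(self.base))
        return float(log(self.k))


def shannon_index(values, k: int, base: float | None = None) -> ShannonResult:
    """Shannon–Wiener index over k equidistant bins spanning [min, max].

    Bins are equal-width over the observed range, last bin right-closed;
    H = -sum p_i log p_i over non-empty bins (natural log unless ``base``).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 1:
        raise ValueError("no non-missing values")
    if k < 1:
        raise ValueError("k must be >= 1")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        warnings.warn("degenerate range: all values identical, H = 0", stacklevel=2)
        edges = np.linspace(lo, lo + 1.0, k + 1)
        freqs = np.zeros(k)
        freqs[0] = 1.0
        return ShannonResult(k=k, edges=edges, freqs=freqs, H=0.0, base=base)
    edges = np.linspace(lo, hi, k + 1)
    counts, _ = np.histogram(x, bins=edges)
    p = counts / counts.sum()
    nz = p[p > 0]
    H = float(-(nz * np.log(nz)).sum())
    if base is not None:
        H /= np.log(base)
    return ShannonResult(k=k, edges=edges, freqs=p, H=H, base=base)


def cv_table(blups: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Descriptive statistics (n, mean, SD, min, max, CV%) per trait.

    With ``groups`` given, statistics are additionally computed within each
    subgroup (rows keyed by (group, trait)). CV = SD / mean x 100; undefined
    (NaN, with warning) for zero-mean traits.
    """
    def summarize(df: pd.DataFrame, label: str) -> pd.DataFrame:
        rows = []
        for trait in df.columns:
            x = df[trait].dropna()
            if len(x) < 2:
                raise ValueError(f"need >= 2 lines for trait {trait!r} in {label!r}")
            mean, sd = x.mean(), x.std(ddof=1)
            if mean == 0:
                warnings.warn(f"zero mean for {trait!r}: CV undefined", stacklevel=3)
                cv = np.nan
            else:
                cv = sd / abs(mean) * 100.0
            rows.append({"group": label, "trait": trait, "n": len(x),
                         "mean": mean, "SD": sd, "min": x.min(), "max": x.max(),
                         "CV": cv})
        return pd.DataFrame(rows)

    parts = [summarize(blups, "all")]
    if groups is not None:
        g = groups.reindex(blups.index)
        for label, idx in blups.groupby(g).groups.items():
            parts.append(summarize(blups.loc[idx], str(label)))
    return pd.concat(parts, ignore_index=True)


def pearson_matrix(blups: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r, two-sided p (t distribution), and stars.

    Stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001. Zero-variance
    traits yield NaN against every partner.
    """
    traits = list(blups.columns)
    T = len(traits)
    r = np.full((T, T), np.nan)
    p = np.full((T, T), np.nan)
    for i in range(T):
        for j in range(i, T):
            xy = blups[[traits[i], traits[j]]].dropna()
            if len(xy) < 3:
                continue
            x, y = xy.iloc[:, 0].to_numpy(), xy.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rr = float(np.corrcoef(x, y)[0, 1])
            n = len(x)
            rr_c = min(max(rr, -1.0), 1.0)
            if abs(rr_c) == 1.0:
                pp = 0.0
            else:
                t = rr_c * np.sqrt((n - 2) / (1.0 - rr_c ** 2))
                pp = 2.0 * stats.t.sf(abs(t), n - 2)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp

    def star(pp: float) -> str:
        if np.isnan(pp):
            return ""
        for thr, s in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
            if pp < thr:
                return s
        return ""

    stars = pd.DataFrame([[star(p[i, j]) for j in range(T)] for i in range(T)],
                         index=traits, columns=traits)
    return (pd.DataFrame(r, index=traits, columns=traits),
            pd.DataFrame(p, index=traits, columns=traits),
            stars)


def bh_adjust(p: pd.DataFrame) -> pd.DataFrame:
    """Benjamini–Hochberg adjustment of the off-diagonal p-values."""
    from statsmodels.stats.multitest import multipletests

    tri = np.triu_indices(p.shape[0], k=1)
    raw = p.to_numpy()[tri]
    ok = ~np.isnan(raw)
    adj = np.full_like(raw, np.nan)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    out = np.full(p.shape, np.nan)
    out[tri] = adj
    out.T[tri] = adj
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=p.index, columns=p.columns)


# ---------------------------------------------------------------------------
# genotypic diversity
# ---------------------------------------------------------------------------

@dataclass
class LocusStats:
    """Per-SNP diversity metrics for one set of lines."""

    maf: np.ndarray
    het: np.ndarray
    pi: np.ndarray
    pic: np.ndarray
    n_used: np.ndarray          # non-missing calls per locus
    skipped: np.ndarray         # loci with < 2 usable calls

    def summary(self) -> dict[str, float]:
        ok = ~self.skipped
        return {m: float(np.nanmean(getattr(self, m)[ok]))
                for m in ("maf", "het", "pi", "pic")}


def _locus_stats_array(dosage: np.ndarray, missing: np.ndarray) -> LocusStats:
    calls = (~missing).sum(axis=0).astype(float)
    skipped = calls < 2
    if skipped.any():
        warnings.warn(f"{int(skipped.sum())} loci with <2 calls skipped", stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(missing, 0.0, dosage).sum(axis=0)
        p = alt / (2.0 * calls)
        q = 1.0 - p
        maf = np.minimum(p, q)
        het = np.where(missing, 0.0, dosage == 1).sum(axis=0) / calls
        n_allele = 2.0 * calls
        pi = n_allele / (n_allele - 1.0) * 2.0 * p * q
        pic = 1.0 - (p ** 2 + q ** 2) - 2.0 * (p ** 2) * (q ** 2)
    for arr in (maf, het, pi, pic):
        arr[skipped] = np.nan
    return LocusStats(maf=maf, het=het, pi=pi, pic=pic,
                      n_used=calls, skipped=skipped)


def locus_stats(
    geno: GenotypeMatrix, groups: pd.Series | None = None
) -> dict[str, LocusStats]:
    """MAF/Het/pi/PIC per locus, for the whole panel and per subgroup.

    Frequencies use the non-missing calls of the group in question;
    monomorphic loci yield (0, Het, 0, 0) — valid values, not errors.
    Returns a dict keyed by "all" plus each subgroup label.
    """
    out = {"all": _locus_stats_array(geno.dosage, geno.missing)}
    if groups is not None:
        if isinstance(groups, pd.Series):
            labels = groups.reindex(pd.Index(geno.line_ids)).to_numpy()
        else:
            labels = np.asarray(groups)
        if len(labels) != geno.n_lines:
            raise ValueError("groups length does not match number of lines")
        for label in pd.unique(labels):
            idx = np.where(labels == label)[0]
            sub = geno.subset_lines(idx)
            out[str(label)] = _locus_stats_array(sub.dosage, sub.missing)
    return out
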