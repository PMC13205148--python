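"""Genotype/phenotype distance matrices and the Mantel permutation test.

The default genotype metric is 1 - IBS (identity-by-state), the standard
distance for inbred dosage data; Euclidean-on-dosage is available. The
phenotype metric is Euclidean distance on z-scored BLUP values, overall or
for a single trait. The Mantel statistic is the Pearson correlation of the
two upper triangles, tested by simultaneously permuting the rows and
columns of the second matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import GenotypeMatrix


@dataclass
class DistanceMatrix:
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distances must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(labels))


def genotype_distance(geno: GenotypeMatrix, metric: str = "ibs") -> DistanceMatrix:
    """Pairwise line distances from dosages.

    ``"ibs"`` (default): d = 1 - mean over shared non-missing loci of
    (1 - |g_i - g_j| / 2). ``"euclidean"``: Euclidean on dosages over shared
    loci, scaled by sqrt(m_total / m_shared) for comparability.
    """
    if geno.n_lines < 2:
        raise ValueError("need >= 2 lines")
    X = geno.dosage
    ok = ~geno.missing
    n = geno.n_lines
    D = np.zeros((n, n))
    for i in range(n):
        shared = ok[i] & ok[i + 1:]
        m_shared = shared.sum(axis=1).astype(float)
        if np.any(m_shared == 0):
            j = int(np.where(m_shared == 0)[0][0]) + i + 1
            raise ValueError(
                f"lines {geno.line_ids[i]!r} and {geno.line_ids[j]!r} share no loci"
            )
        diff = np.abs(X[i] - X[i + 1:]) * shared
        if metric == "ibs":
            d = (diff / 2.0).sum(axis=1) / m_shared
        elif metric == "euclidean":
            d = np.sqrt((diff ** 2).sum(axis=1) * (geno.n_snps / m_shared))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return DistanceMatrix(D, list(geno.line_ids))


def phenotype_distance(
    blups: pd.DataFrame, traits: list[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance on z-scored BLUPs; a single trait gives |z_i - z_j|."""
    traits = traits if traits is not None else list(blups.columns)
    if not traits:
        raise ValueError("traits must be non-empty")
    X = blups[traits].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [t for t, k in zip(traits, keep) if not k]
        warnings.warn(f"zero-variance traits excluded: {dropped}", stacklevel=2)
        X, sd = X[:, keep], sd[keep]
    if X.shape[1] == 0:
        raise ValueError("no traits with nonzero variance")
    Z = (X - X.mean(axis=0)) / sd
    D = squareform(pdist(Z, metric="euclidean"))
    return DistanceMatrix(D, list(blups.index.astype(str)))


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int | None
    tail: str = "upper"


def mantel_test(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "upper",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of upper-triangle entries; the null is
    built by simultaneously permuting rows and columns of ``dy``. One-sided
    upper-tail p = (1 + #{r_perm >= r_obs}) / (n_perm + 1) by default;
    ``tail="two-sided"`` compares |r_perm| >= |r_obs|.
    """
    if dx.labels != dy.labels:
        if sorted(dx.labels) == sorted(dy.labels):
            dy = dy.reorder(dx.labels)
        else:
            raise ValueError("distance matrices have mismatched labels")
    n = dx.n
    iu = np.triu_indices(n, k=1)
    x = dx.values[iu]
    xc = x - x.mean()
    xden = np.sqrt((xc ** 2).sum())

    def corr_with(ymat: np.ndarray) -> float:
        y = ymat[iu]
        yc = y - y.mean()
        den = xden * np.sqrt((yc ** 2).sum())
        if den == 0:
            return 0.0
        return float((xc * yc).sum() / den)

    r_obs = corr_with(dy.values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr_with(dy.values[np.ix_(perm, perm)])
        if tail == "upper":
            hits += r_p >= r_obs
        elif tail == "two-sided":
            hits += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown tail {tail!r}")
    p = (1.0 + hits) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p_value=float(p), n_perm=n_perm, seed=seed, tail=tail)


def mantel_exhaustive(dx: DistanceMatrix, dy: DistanceMatrix,
                      tail: str = "upper") -> MantelResult:
    """Exact Mantel p over all n! relabelings (small n only)."""
    from itertools import permutations

    n = dx.n
    if n > 8:
        raise ValueError("exhaustive enumeration only sensible for n <= 8")
    iu = np.triu_indices(n, k=1)
    x = dx.values[iu]

    def corr(perm) -> float:
        y = dy.values[np.ix_(perm, perm)][iu]
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(x, y)[0, 1]
        return 0.0 if np.isnan(c) else float(c)

    r_obs = corr(tuple(range(n)))
    total = hits = 0
    for perm in permutations(range(n)):
        r_p = corr(perm)
        total += 1
        hits += (r_p >= r_obs) if tail == "upper" else (abs(r_p) >= abs(r_obs))
    return MantelResult(r=r_obs, p_value=hits / total, n_perm=total - 1,
                        seed=None, tail=tail)


def write_distance_tsv(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path, sep="\t")


def read_distance_tsv(path) -> DistanceMatrix:
    """Read a square labelled TSV; also accepts PHYLIP square format."""
    with open(path) as fh:
        first = fh.readline().strip()
    if first and first.split()[0].isdigit() and len(first.split()) == 1:
        # PHYLIP: first line is the taxon count
        df = pd.read_csv(path, sep=r"\s+", skiprows=1, header=None, index_col=0)
        df.columns = list(df.index)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), [str(l) for l in df.index])
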