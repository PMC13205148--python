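"""Kinship-corrected single-SNP association scans (EMMAX-style LMM).

The null model y = 1 mu + u + e with u ~ N(0, sg^2 K), e ~ N(0, se^2 I) is
fitted once by REML over the variance ratio delta = se^2/sg^2 using the
spectral decomposition of the kinship K; every SNP is then tested by
generalized least squares in the rotated (whitened) coordinates with delta
held fixed — the EMMAX approximation. A per-SNP exact-REML fit is provided
as a slow oracle for testing. QQ diagnostics report observed vs expected
-log10 p and the genomic-control inflation factor lambda_GC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix

#: Significance thresholds: suggestive and genome-wide (Bonferroni-style).
SUGGESTIVE_P = 1e-5
GENOME_WIDE_P = 5e-8


def _imputed_centered(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed dosages and a per-SNP polymorphism mask."""
    X = geno.dosage.copy()
    if geno.missing.any():
        m = np.ma.masked_array(X, mask=geno.missing)
        col_mean = np.asarray(m.mean(axis=0).filled(0.0))
        X[geno.missing] = np.broadcast_to(col_mean, X.shape)[geno.missing]
    poly = X.std(axis=0) > 0
    return X, poly


def compute_kinship(geno: GenotypeMatrix) -> np.ndarray:
    """K = Z Z' / m over polymorphic SNPs, Z column-centred mean-imputed dosages."""
    if geno.n_lines < 2:
        raise ValueError("need >= 2 lines")
    X, poly = _imputed_centered(geno)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    Z = X[:, poly] - X[:, poly].mean(axis=0)
    return Z @ Z.T / int(poly.sum())


@dataclass
class NullModel:
    delta: float                 # se^2 / sg^2 at the REML optimum
    sigma2_g: float
    sigma2_e: float
    loglik: float
    eigvals: np.ndarray          # of K
    eigvecs: np.ndarray
    at_bound: bool = False       # delta pinned at the search boundary


def _reml_neg_loglik(log10_delta: float, s: np.ndarray, eta: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over sg^2 (EMMA form).

    ``s``: eigenvalues of K restricted to the space orthogonal to the
    intercept; ``eta``: rotated residual phenotype in that space.
    """
    delta = 10.0 ** log10_delta
    d = s + delta
    n = eta.shape[0]
    sg2 = float((eta ** 2 / d).sum() / n)
    ll = -0.5 * (n * np.log(2.0 * np.pi * sg2) + np.log(d).sum() + n)
    return -ll


def fit_null_delta(
    y: np.ndarray,
    K: np.ndarray,
    bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-6,
) -> NullModel:
    """REML fit of the variance ratio delta on log10 scale via Brent search.

    Uses the restricted likelihood after projecting out the intercept: with
    K = U S U', the projected model has independent components with variance
    sg^2 (s_i + delta).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("kinship matrix is not PSD")
    w = np.clip(w, 0.0, None)

    # restricted space: orthogonal complement of the intercept
    one = np.ones(n) / np.sqrt(n)
    # eigen-decompose P K P on the complement via full eigh of projected K
    P = np.eye(n) - np.outer(one, one)
    s_all, V = np.linalg.eigh(P @ K @ P)
    s = s_all[1:]  # drop the (numerically zero) eigenvalue along the intercept
    eta = (V[:, 1:].T @ y)

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=bounds, args=(s, eta),
        method="bounded", options={"xatol": tol},
    )
    if not np.isfinite(res.fun):
        grid = np.linspace(bounds[0], bounds[1], 21)
        vals = [_reml_neg_loglik(g, s, eta) for g in grid]
        raise FloatingPointError(
            f"non-finite REML likelihood; delta grid diagnostics: "
            f"{list(zip(grid.round(2), np.round(vals, 3)))}"
        )
    log10_delta = float(res.x)
    at_bound = (log10_delta - bounds[0] < 1e-3) or (bounds[1] - log10_delta < 1e-3)
    delta = 10.0 ** log10_delta
    d = s + delta
    sg2 = float((eta ** 2 / d).sum() / s.shape[0])
    return NullModel(
        delta=delta, sigma2_g=sg2, sigma2_e=sg2 * delta,
        loglik=-float(res.fun), eigvals=w, eigvecs=U, at_bound=at_bound,
    )


@dataclass
class GwasResult:
    table: pd.DataFrame          # chrom, pos, maf, beta, se, wald, p per tested SNP
    delta: float
    sigma2_g: float
    lambda_gc: float
    n_lines: int
    n_tested: int
    n_skipped: int
    suggestive_p: float = SUGGESTIVE_P
    genome_wide_p: float = GENOME_WIDE_P
    qq: pd.DataFrame | None = field(default=None, repr=False)


def association_scan(
    geno: GenotypeMatrix,
    y: np.ndarray,
    K: np.ndarray | None = None,
    null: NullModel | None = None,
    maf_min: float = 0.05,
) -> GwasResult:
    """EMMAX scan: GLS of the rotated phenotype on each rotated SNP.

    With K = U S U' and fixed delta from the null fit, the weights
    1/(s_i + delta) whiten the model; each SNP is tested with an intercept
    by weighted least squares, Wald statistic (beta/se)^2 ~ chi2_1.
    Monomorphic and sub-MAF SNPs are skipped.
    """
    y = np.asarray(y, dtype=float)
    if K is None:
        K = compute_kinship(geno)
    if null is None:
        null = fit_null_delta(y, K)
    X, poly = _imputed_centered(geno)
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    test = poly & (maf >= maf_min)
    if not test.any():
        raise ValueError("no SNPs left to test (all monomorphic or below MAF filter)")

    U, s = null.eigvecs, null.eigvals
    wgt = 1.0 / (s + null.delta)
    ty = U.T @ y
    t1 = U.T @ np.ones(y.shape[0])
    G = U.T @ X[:, test]          # n x m rotated genotypes

    # per-SNP weighted LS with intercept: solve the 2x2 normal equations
    s11 = float((wgt * t1 * t1).sum())
    s1y = float((wgt * t1 * ty).sum())
    s1g = (wgt[:, None] * t1[:, None] * G).sum(axis=0)
    sgg = (wgt[:, None] * G * G).sum(axis=0)
    sgy = (wgt[:, None] * ty[:, None] * G).sum(axis=0)
    det = s11 * sgg - s1g ** 2
    beta = (s11 * sgy - s1g * s1y) / det
    alpha = (sgg * s1y - s1g * sgy) / det

    n = y.shape[0]
    df = n - 2
    # residual sum of squares in whitened coordinates, per SNP
    syy = float((wgt * ty * ty).sum())
    rss = syy - alpha * s1y - beta * sgy
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(sigma2 * s11 / det)
    wald = (beta / se) ** 2
    p = stats.chi2.sf(wald, df=1)

    table = pd.DataFrame({
        "chrom": geno.chrom[test], "pos": geno.pos[test],
        "maf": maf[test], "beta": beta, "se": se, "wald": wald, "p": p,
        "snp_index": np.where(test)[0],
    })
    lam = genomic_lambda(table["p"].to_numpy())
    return GwasResult(
        table=table, delta=null.delta, sigma2_g=null.sigma2_g,
        lambda_gc=lam, n_lines=n, n_tested=int(test.sum()),
        n_skipped=int((~test).sum()),
    )


def genomic_lambda(p: np.ndarray) -> float:
    """lambda_GC = median observed chi2(1) / 0.4549 (its null median)."""
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def qq_data(result: GwasResult) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs (uniform quantiles i/(m+1))."""
    p = np.sort(result.table["p"].to_numpy())
    m = p.shape[0]
    if m < 10:
        raise ValueError("need >= 10 tested SNPs for a QQ summary")
    expected = np.arange(1, m + 1) / (m + 1.0)
    qq = pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(np.clip(p, 1e-300, 1.0)),
    })
    result.qq = qq
    return qq


def exact_per_snp_scan(
    geno: GenotypeMatrix, y: np.ndarray, K: np.ndarray, maf_min: float = 0.05
) -> pd.DataFrame:
    """Slow oracle: re-optimize delta per SNP (exact single-marker REML LMM)."""
    X, poly = _imputed_centered(geno)
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    test = np.where(poly & (maf >= maf_min))[0]
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    rows = []
    for j in test:
        Xf = np.column_stack([np.ones(n), X[:, j]])
        # REML over delta with this SNP in the fixed part
        Q, _ = np.linalg.qr(Xf, mode="complete")
        A = Q[:, 2:]                       # basis of the residual space
        s_r, V_r = np.linalg.eigh(A.T @ K @ A)
        eta = V_r.T @ (A.T @ y)

        def neg_ll(log10_delta: float) -> float:
            delta = 10.0 ** log10_delta
            d = s_r + delta
            m = eta.shape[0]
            sg2 = float((eta ** 2 / d).sum() / m)
            return 0.5 * (m * np.log(2.0 * np.pi * sg2) + np.log(d).sum() + m)

        res = optimize.minimize_scalar(neg_ll, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-6})
        delta = 10.0 ** float(res.x)
        w, U = np.linalg.eigh(K)
        wgt = 1.0 / (np.clip(w, 0, None) + delta)
        tX = U.T @ Xf
        ty = U.T @ y
        XtWX = tX.T @ (wgt[:, None] * tX)
        XtWy = tX.T @ (wgt * ty)
        coef = np.linalg.solve(XtWX, XtWy)
        rss = float((wgt * (ty - tX @ coef) ** 2).sum())
        sigma2 = rss / (n - 2)
        cov = sigma2 * np.linalg.inv(XtWX)
        se = float(np.sqrt(cov[1, 1]))
        wald = (coef[1] / se) ** 2
        rows.append({"snp_index": j, "beta": coef[1], "se": se,
                     "wald": wald, "p": float(stats.chi2.sf(wald, df=1))})
    return pd.DataFrame(rows)
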