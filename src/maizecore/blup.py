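"""Multi-environment mixed models: variance components, BLUPs, Duncan's test.

The per-trait model is

    y_ikb = mu + E_i + G_k + (GE)_ik + e_ikb

with environment E fixed and genotype G (and, when replicate-level data are
available, the interaction GE) random. Following common multi-environment
trial practice, block values are first averaged to one record per line x
environment; on that path (GE) and the residual are confounded and a single
combined residual is fitted.

Balanced data are solved by closed-form ANOVA/REML estimators (negative
estimates truncated at zero); unbalanced data by EM-REML on Henderson's
mixed-model equations. The balanced closed form doubles as an independent
oracle for the iterative fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TRAITS, validate_pheno


# ---------------------------------------------------------------------------
# block averaging
# ---------------------------------------------------------------------------

def average_blocks(pheno: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Average replicate blocks to one record per line x environment.

    Missing block values are ignored (mean over available blocks); a cell
    with no data at all becomes missing, with a warning.
    """
    validate_pheno(pheno)
    traits = traits or [t for t in TRAITS if t in pheno.columns]
    out = pheno.groupby(["line_id", "env"], sort=False, as_index=False)[traits].mean()
    if out[traits].isna().any().any():
        warnings.warn("some line x env cells have no data; recorded as missing",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# the mixed model
# ---------------------------------------------------------------------------

@dataclass
class BlupModel:
    """A fitted per-trait mixed model."""

    trait: str
    mu: float                      # grand mean of the data
    env_effects: pd.Series         # fixed env means minus mu
    blups: pd.Series               # genotype BLUPs, deviation scale (sum ~ 0)
    var_g: float
    var_res: float                 # combined G x E + residual on the means path
    var_ge: float | None = None    # separate G x E (replicate-level fits only)
    n_envs: int = 0
    n_lines: int = 0
    method: str = "anova"
    n_iter: int = 0
    converged: bool = True
    loglik_path: list[float] = field(default_factory=list)

    @property
    def components(self) -> dict[str, float]:
        comps = {"genotype": self.var_g}
        if self.var_ge is not None:
            comps["gxe"] = self.var_ge
        comps["residual"] = self.var_res
        return comps

    def blups_on_trait_scale(self) -> pd.Series:
        """BLUPs reported as mu + deviation (the trait's natural units)."""
        return self.mu + self.blups


def _check_input(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    d = df[["line_id", "env", trait]].dropna(subset=[trait])
    if d["env"].nunique() < 2:
        raise ValueError("model is degenerate with fewer than 2 environments")
    if d["line_id"].nunique() < 3:
        raise ValueError("need at least 3 lines to separate genetic variance")
    return d


def _is_balanced(d: pd.DataFrame) -> bool:
    counts = d.groupby(["line_id", "env"]).size().unstack()
    if counts.isna().any().any():
        return False
    return np.unique(counts.to_numpy()).size == 1


def fit_lmm_reml(
    pheno: pd.DataFrame,
    trait: str,
    keep_reps: bool = False,
    method: str = "auto",
    tol: float = 1e-8,
    max_iter: int = 500,
    track_loglik: bool = False,
) -> BlupModel:
    """Fit the multi-environment mixed model for one trait.

    Parameters
    ----------
    keep_reps
        If False (default), blocks are averaged first and a combined
        residual absorbs G x E. If True and the input is replicate-level,
        G x E is fitted as its own random effect.
    method
        "auto" picks closed-form ANOVA estimators for balanced data and
        EM-REML otherwise; "anova" / "em" force a path.
    """
    if not keep_reps and "block" in pheno.columns:
        pheno = average_blocks(pheno, traits=[t for t in TRAITS if t in pheno.columns])
    d = _check_input(pheno, trait)
    balanced = _is_balanced(d)
    with_ge = keep_reps and "block" in pheno.columns and (
        d.groupby(["line_id", "env"]).size().max() > 1
    )
    if method == "auto":
        method = "anova" if balanced else "em"
    if method == "anova":
        if not balanced:
            raise ValueError("closed-form ANOVA estimators require balanced data")
        return (_fit_anova_reps if with_ge else _fit_anova_means)(d, trait)
    if method == "em":
        return _fit_em_reml(d, trait, with_ge, tol, max_iter, track_loglik)
    raise ValueError(f"unknown method {method!r}")


def _fit_anova_means(d: pd.DataFrame, trait: str) -> BlupModel:
    """Balanced two-way (line x env, one obs/cell) closed-form REML."""
    wide = d.pivot_table(index="line_id", columns="env", values=trait)
    y = wide.to_numpy()
    K, I = y.shape
    mu = y.mean()
    line_means = y.mean(axis=1)
    env_means = y.mean(axis=0)
    ss_g = I * ((line_means - mu) ** 2).sum()
    ss_e = K * ((env_means - mu) ** 2).sum()
    ss_tot = ((y - mu) ** 2).sum()
    ss_res = ss_tot - ss_g - ss_e
    ms_g = ss_g / (K - 1)
    ms_res = ss_res / ((K - 1) * (I - 1))
    var_res = ms_res
    var_g = max(0.0, (ms_g - ms_res) / I)
    h = var_g / (var_g + var_res / I) if (var_g + var_res / I) > 0 else 0.0
    blups = pd.Series(h * (line_means - mu), index=wide.index, name=trait)
    return BlupModel(
        trait=trait, mu=float(mu),
        env_effects=pd.Series(env_means - mu, index=wide.columns),
        blups=blups, var_g=float(var_g), var_res=float(var_res),
        n_envs=I, n_lines=K, method="anova",
    )


def _fit_anova_reps(d: pd.DataFrame, trait: str) -> BlupModel:
    """Balanced three-way closed form with separate G x E component."""
    cell = d.groupby(["line_id", "env"])[trait].agg(["mean", "count", "var"])
    B = int(cell["count"].iloc[0])
    wide = cell["mean"].unstack()
    y = wide.to_numpy()
    K, I = y.shape
    mu_cells = y.mean()
    line_means = y.mean(axis=1)
    env_means = y.mean(axis=0)
    ss_g = I * B * ((line_means - mu_cells) ** 2).sum()
    ss_ge = B * ((y - line_means[:, None] - env_means[None, :] + mu_cells) ** 2).sum()
    ss_within = (cell["var"].fillna(0.0) * (cell["count"] - 1)).sum()
    ms_g = ss_g / (K - 1)
    ms_ge = ss_ge / ((K - 1) * (I - 1))
    ms_within = ss_within / (K * I * (B - 1)) if B > 1 else 0.0
    var_res = ms_within
    var_ge = max(0.0, (ms_ge - ms_within) / B)
    var_g = max(0.0, (ms_g - ms_ge) / (I * B))
    denom = var_g + var_ge / I + var_res / (I * B)
    h = var_g / denom if denom > 0 else 0.0
    blups = pd.Series(h * (line_means - mu_cells), index=wide.index, name=trait)
    return BlupModel(
        trait=trait, mu=float(mu_cells),
        env_effects=pd.Series(env_means - mu_cells, index=wide.columns),
        blups=blups, var_g=float(var_g), var_res=float(var_res),
        var_ge=float(var_ge), n_envs=I, n_lines=K, method="anova",
    )


def _reml_loglik(y, X, Z_list, sig2_list, sig2_e) -> float:
    """Restricted log-likelihood of y under V = sum s2_i Z_i Z_i' + s2_e I."""
    n = y.shape[0]
    V = sig2_e * np.eye(n)
    for Z, s2 in zip(Z_list, sig2_list):
        V += s2 * (Z @ Z.T)
    sign, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdetX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * (logdetV + logdetX + r @ Vi @ r))


def _fit_em_reml(
    d: pd.DataFrame, trait: str, with_ge: bool,
    tol: float, max_iter: int, track_loglik: bool,
) -> BlupModel:
    """EM-REML on Henderson's mixed-model equations (env fixed, G [+GE] random)."""
    lines = pd.Index(sorted(d["line_id"].unique()))
    envs = pd.Index(sorted(d["env"].unique()))
    y = d[trait].to_numpy(dtype=float)
    n = y.shape[0]
    li = lines.get_indexer(d["line_id"])
    ei = envs.get_indexer(d["env"])

    X = np.zeros((n, len(envs)))
    X[np.arange(n), ei] = 1.0
    Zg = np.zeros((n, len(lines)))
    Zg[np.arange(n), li] = 1.0
    Z_list = [Zg]
    if with_ge:
        cell = li * len(envs) + ei
        used = np.unique(cell)
        remap = {c: j for j, c in enumerate(used)}
        Zge = np.zeros((n, len(used)))
        Zge[np.arange(n), [remap[c] for c in cell]] = 1.0
        Z_list.append(Zge)

    p = np.linalg.matrix_rank(X)
    tot = float(np.var(y, ddof=1))
    k = len(Z_list) + 1
    sig2 = [tot / k] * len(Z_list)
    sig2_e = tot / k

    W = np.hstack([X] + Z_list)
    WtW = W.T @ W
    Wty = W.T @ y
    q = [Z.shape[1] for Z in Z_list]
    offs = np.cumsum([X.shape[1]] + q)
    loglik_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        for j, Z in enumerate(Z_list):
            lam = sig2_e / max(sig2[j], 1e-12)
            sl = slice(offs[j], offs[j + 1])
            C[sl, sl] += lam * np.eye(q[j])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ Wty
        new_sig2 = []
        for j in range(len(Z_list)):
            sl = slice(offs[j], offs[j + 1])
            u = sol[sl]
            new_sig2.append(float((u @ u + sig2_e * np.trace(Cinv[sl, sl])) / q[j]))
        resid_term = float(y @ y - sol @ Wty)
        new_sig2_e = resid_term / (n - p)
        if track_loglik:
            loglik_path.append(_reml_loglik(y, X, Z_list, new_sig2, new_sig2_e))
        rel = max(
            abs(a - b) / max(abs(b), 1e-12)
            for a, b in zip(new_sig2 + [new_sig2_e], sig2 + [sig2_e])
        )
        sig2, sig2_e = new_sig2, new_sig2_e
        if rel < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"EM-REML did not converge in {max_iter} iterations for trait {trait!r}"
        )

    beta = sol[: X.shape[1]]
    u_g = sol[offs[0]: offs[1]]
    mu = float(np.mean(X @ beta))
    model = BlupModel(
        trait=trait, mu=mu,
        env_effects=pd.Series(beta - mu, index=envs),
        blups=pd.Series(u_g, index=lines, name=trait),
        var_g=float(sig2[0]), var_res=float(sig2_e),
        var_ge=float(sig2[1]) if with_ge else None,
        n_envs=len(envs), n_lines=len(lines),
        method="em", n_iter=it, converged=converged,
        loglik_path=loglik_path,
    )
    return model


def variance_proportions(model: BlupModel) -> dict[str, float]:
    """Share of phenotypic variance per component (sums to 1)."""
    comps = model.components
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("all variance components are zero; proportions undefined")
    return {k: v / total for k, v in comps.items()}


def extract_blups(models: dict[str, BlupModel], scale: str = "trait") -> pd.DataFrame:
    """Assemble a line x trait BLUP table from per-trait fits.

    ``scale="trait"`` reports mu + BLUP (the adjusted-phenotype convention);
    ``scale="deviation"`` reports the centred random effects.
    """
    cols = {}
    for trait, m in models.items():
        cols[trait] = m.blups_on_trait_scale() if scale == "trait" else m.blups
    out = pd.DataFrame(cols)
    out.index.name = "line_id"
    return out


def fit_all_traits(pheno: pd.DataFrame, traits: list[str] | None = None,
                   **kwargs) -> dict[str, BlupModel]:
    traits = traits or [t for t in TRAITS if t in pheno.columns]
    return {t: fit_lmm_reml(pheno, t, **kwargs) for t in traits}


# ---------------------------------------------------------------------------
# one-way ANOVA + Duncan's multiple range test
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=4096)
def _q_crit(alpha_r: float, span: int, df: int) -> float:
    # studentized_range.ppf is expensive; memoize (simulations reuse points)
    return float(stats.studentized_range.ppf(1.0 - alpha_r, span, df))


@dataclass
class DuncanResult:
    f_stat: float
    p_value: float
    means: pd.Series            # group means, sorted descending
    letters: dict[str, str]     # compact letter display per group
    alpha: float
    nonsig_spans: list[tuple[int, int]] = field(default_factory=list)

    def same_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def anova_duncan(values, groups, alpha: float = 0.05) -> DuncanResult:
    """One-way ANOVA with Duncan's multiple range test and letter display.

    Duncan's step-down range procedure: for a span of r ordered means the
    critical point is the studentized range at protection level
    1-(1-alpha)^(r-1); a span is declared homogeneous when its range falls
    short, and homogeneity propagates to all nested spans. Letters are
    assigned from the largest mean, groups sharing a letter not differing
    at level alpha.
    """
    s = pd.DataFrame({"value": np.asarray(values, dtype=float),
                      "group": np.asarray(groups)}).dropna()
    sizes = s.groupby("group")["value"].size()
    if (sizes < 2).any() or len(sizes) < 2:
        raise ValueError("need >= 2 groups with n >= 2 each")
    samples = [g["value"].to_numpy() for _, g in s.groupby("group")]
    f_stat, p_value = stats.f_oneway(*samples)

    means = s.groupby("group")["value"].mean().sort_values(ascending=False)
    order = list(means.index)
    k = len(order)
    df_w = len(s) - k
    ms_within = sum(((x - x.mean()) ** 2).sum() for x in samples) / df_w

    # significance of each ordered span, with protection propagation
    nonsig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if span < k and any(
                nonsig[a, b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (b - a + 1) > span and nonsig[a, b]
            ):
                nonsig[i, j] = True
                continue
            grp = order[i: j + 1]
            n_h = len(grp) / (1.0 / sizes[grp]).sum()
            alpha_r = 1.0 - (1.0 - alpha) ** (span - 1)
            lsr = _q_crit(alpha_r, span, df_w) * np.sqrt(ms_within / n_h)
            if means.iloc[i] - means.iloc[j] <= lsr:
                nonsig[i, j] = True
    for i in range(k):
        nonsig[i, i] = True

    # compact letter display: maximal homogeneous prefixes-to-suffixes
    reach = [max(j for j in range(i, k) if nonsig[i, j]) for i in range(k)]
    spans, last = [], -1
    for i in range(k):
        if reach[i] > last or (i > last):
            spans.append((i, reach[i]))
            last = reach[i]
    # drop spans nested in an earlier one
    spans = [sp for idx, sp in enumerate(spans)
             if not any(o[0] <= sp[0] and sp[1] <= o[1]
                        for j2, o in enumerate(spans) if j2 != idx)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for letter, (i, j) in zip(alphabet, spans):
        for g in order[i: j + 1]:
            letters[g] += letter
    return DuncanResult(
        f_stat=float(f_stat), p_value=float(p_value), means=means,
        letters=letters, alpha=alpha,
        nonsig_spans=[(int(a), int(b)) for a, b in spans],
    )
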