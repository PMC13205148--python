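"""Synthetic maize-panel generator with known ground truth.

Emulates a structured inbred panel — several subpopulations with divergent
allele frequencies (Balding–Nichols model), Dirichlet admixture, a small
number of planted large-effect QTLs — phenotyped for correlated agronomic
traits in a multi-environment trial (environments x blocks), so every
downstream stage (BLUP, diversity, Mantel, GWAS, clustering, selection) has
a parameter-recovery test without external data.

The phenotype follows the multi-environment model

    y_ikb = mu_t + E_i + g_k + (gE)_ik + e_ikb

per trait t, with genotype value ``g_k`` composed of planted-QTL effects and
a polygenic term whose line-by-line covariance is the centred-genotype
kinship, and with trait-by-trait correlations induced on the polygenic part.
The ratio traits LWR = KL/KW and EPR = EH/PH are always derived from their
parents, never simulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BASE_TRAITS, GenotypeMatrix, TRAITS

# Trait means / SDs the generator targets by default (cm / mm scales typical
# of a specialty-maize inbred panel: e.g. PH ~ 120.52 cm, EH ~ 31.5 cm).
DEFAULT_TRAIT_MEANS = {
    "KL": 8.20, "KW": 6.93, "PH": 120.52, "EH": 31.50,
    "TPN": 9.31, "TBL": 13.07, "LUL": 22.10, "LUT": 16.12,
}
DEFAULT_TRAIT_SCALES = {
    "KL": 1.00, "KW": 0.81, "PH": 29.07, "EH": 13.93,
    "TPN": 4.83, "TBL": 3.07, "LUL": 4.47, "LUT": 3.64,
}


def _default_trait_corr() -> np.ndarray:
    """Default correlation among the 8 simulated base traits.

    Encodes the qualitative structure of such panels: tall plants carry high
    ears, the tassel length traits move together, and kernel length/width
    are mildly coupled.
    """
    t = list(BASE_TRAITS)
    C = np.eye(len(t))

    def set_r(a: str, b: str, r: float) -> None:
        i, j = t.index(a), t.index(b)
        C[i, j] = C[j, i] = r

    set_r("KL", "KW", 0.30)
    set_r("PH", "EH", 0.60)
    set_r("LUL", "LUT", 0.79)
    set_r("TBL", "LUL", 0.45)
    set_r("TBL", "LUT", 0.40)
    set_r("TPN", "TBL", -0.25)
    set_r("TPN", "LUL", -0.20)
    set_r("TPN", "LUT", -0.20)
    set_r("KL", "LUL", 0.20)
    set_r("KW", "LUT", 0.20)
    # guard: nudge onto the PSD cone if the hand-set entries stray off it
    w, V = np.linalg.eigh(C)
    if w.min() < 0:
        C = (V * np.clip(w, 1e-6, None)) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study panel.

    222 lines in 3 subpopulations (123 sweet / 82 waxy / 17 sweet–waxy),
    2 environments x 3 blocks, 10 traits (8 simulated + 2 derived ratios),
    a handful of large-effect QTLs, moderate subpopulation divergence.
    """

    n_lines: int = 222
    n_snps: int = 2000
    n_subpops: int = 3
    subpop_props: tuple[float, ...] = (123 / 222, 82 / 222, 17 / 222)
    fst: float = 0.2
    admixture_alpha: float = 0.5
    primary_concentration: float = 10.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    inbreeding: float = 0.0
    missing_rate: float = 0.0
    n_envs: int = 2
    n_blocks: int = 3
    # variance components per standardized trait (shares of unit variance by
    # default; trait_scales then sets each trait's overall SD)
    var_g: float = 0.60
    var_e: float = 0.10
    var_ge: float = 0.10
    var_res: float = 0.20
    n_qtl: int = 5
    qtl_beta: float | tuple[float, ...] = 0.4
    trait_corr: np.ndarray = field(default_factory=_default_trait_corr)
    trait_means: dict | None = None
    trait_scales: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines <= 0 or self.n_snps <= 0:
            raise ValueError("n_lines and n_snps must be positive")
        if self.n_subpops <= 0:
            raise ValueError("n_subpops must be positive")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("var_g", "var_e", "var_ge", "var_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.admixture_alpha < 0:
            raise ValueError("admixture_alpha must be >= 0 (0 disables admixture)")
        C = np.asarray(self.trait_corr, dtype=float)
        if C.shape != (len(BASE_TRAITS), len(BASE_TRAITS)):
            raise ValueError(
                f"trait_corr must be {len(BASE_TRAITS)}x{len(BASE_TRAITS)} "
                "(one row per simulated base trait)"
            )
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("trait_corr must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("trait_corr must be positive semi-definite")

    def means(self) -> dict:
        return dict(DEFAULT_TRAIT_MEANS if self.trait_means is None else self.trait_means)

    def scales(self) -> dict:
        return dict(DEFAULT_TRAIT_SCALES if self.trait_scales is None else self.trait_scales)


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    true_genetic_values: np.ndarray  # n_lines x len(BASE_TRAITS), standardized scale
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    qtl_traits: list[str]
    subpop_assignments: np.ndarray  # primary subpop per line
    ancestry: np.ndarray  # n_lines x n_subpops, rows sum to 1
    realized_var_g: np.ndarray  # per base trait, sample variance of genetic values

    def to_dict(self) -> dict:
        return {
            "qtl_indices": self.qtl_indices.tolist(),
            "qtl_effects": self.qtl_effects.tolist(),
            "qtl_traits": list(self.qtl_traits),
            "subpop_assignments": self.subpop_assignments.tolist(),
            "ancestry": self.ancestry.tolist(),
            "realized_var_g": self.realized_var_g.tolist(),
            "true_genetic_values": self.true_genetic_values.tolist(),
            "base_traits": list(BASE_TRAITS),
        }


_SUBPOP_PREFIX = ("SHT", "SHN", "SHTN")


def _line_ids(config: SimConfig, assignments: np.ndarray) -> list[str]:
    ids, counters = [], {}
    for k in assignments:
        prefix = _SUBPOP_PREFIX[k % len(_SUBPOP_PREFIX)]
        counters[prefix] = counters.get(prefix, 0) + 1
        ids.append(f"{prefix}{counters[prefix]}")
    return ids


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw structured genotypes under the Balding–Nichols model.

    Per SNP an ancestral frequency p is drawn uniformly from ``maf_range``;
    each subpopulation's frequency comes from Beta(p(1-F)/F, (1-p)(1-F)/F)
    with F = ``fst`` (F = 0 keeps the ancestral frequency). Each line mixes
    subpopulation frequencies by its Dirichlet ancestry vector, and calls are
    Binomial(2, p_line) — with an optional excess-homozygosity coefficient
    for inbred-looking panels. Deterministic under a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # primary subpop per line, by configured proportions (deterministic split)
    props = np.asarray(config.subpop_props[: config.n_subpops], dtype=float)
    props = props / props.sum()
    counts = np.floor(props * config.n_lines).astype(int)
    counts[0] += config.n_lines - counts.sum()
    assignments = np.repeat(np.arange(config.n_subpops), counts)

    # ancestry proportions: Dirichlet with extra concentration on the primary
    if config.admixture_alpha == 0.0:
        ancestry = np.eye(config.n_subpops)[assignments]
    else:
        conc = np.full((config.n_lines, config.n_subpops), config.admixture_alpha)
        conc[np.arange(config.n_lines), assignments] += config.primary_concentration
        ancestry = np.vstack([rng.dirichlet(c) for c in conc])

    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_snps)
    if config.fst > 0.0:
        F = config.fst
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = rng.beta(a, b, size=(config.n_subpops, config.n_snps))
    else:
        p_sub = np.broadcast_to(p_anc, (config.n_subpops, config.n_snps)).copy()

    p_line = ancestry @ p_sub  # n_lines x n_snps
    if config.inbreeding > 0.0:
        # draw the two allele copies with correlation F_is (excess homozygosity)
        f = config.inbreeding
        a1 = rng.random(p_line.shape) < p_line
        same = rng.random(p_line.shape) < f
        a2_indep = rng.random(p_line.shape) < p_line
        a2 = np.where(same, a1, a2_indep)
        dosage = (a1.astype(float) + a2.astype(float))
    else:
        dosage = rng.binomial(2, p_line).astype(float)

    missing = np.zeros(dosage.shape, dtype=bool)
    if config.missing_rate > 0.0:
        missing = rng.random(dosage.shape) < config.missing_rate

    # coordinates: 10 chromosomes, positions monotone within each
    chroms = np.array([f"chr{c + 1}" for c in range(10)])
    chrom_idx = np.sort(rng.integers(0, 10, size=config.n_snps))
    pos = np.zeros(config.n_snps, dtype=int)
    for c in range(10):
        m = int((chrom_idx == c).sum())
        # strictly increasing positions via cumulative random gaps
        pos[chrom_idx == c] = np.cumsum(rng.integers(1, 200_000, size=m))

    geno = GenotypeMatrix(
        dosage=dosage,
        missing=missing,
        line_ids=_line_ids(config, assignments),
        chrom=chroms[chrom_idx],
        pos=pos,
        ref=np.full(config.n_snps, "A"),
        alt=np.full(config.n_snps, "T"),
    )

    # plant QTLs now so genotype and phenotype simulation share one truth
    n_qtl = min(config.n_qtl, config.n_snps)
    qtl_indices = (
        rng.choice(config.n_snps, size=n_qtl, replace=False)
        if n_qtl > 0 else np.array([], dtype=int)
    )
    betas = np.asarray(config.qtl_beta, dtype=float)
    if betas.ndim == 0:
        betas = np.full(n_qtl, float(betas))
    if betas.shape[0] < n_qtl:
        raise ValueError("qtl_beta shorter than n_qtl")
    betas = betas[:n_qtl]
    qtl_traits = [BASE_TRAITS[q % len(BASE_TRAITS)] for q in range(n_qtl)]

    truth = SimTruth(
        true_genetic_values=np.zeros((config.n_lines, len(BASE_TRAITS))),
        qtl_indices=qtl_indices,
        qtl_effects=betas,
        qtl_traits=qtl_traits,
        subpop_assignments=assignments,
        ancestry=ancestry,
        realized_var_g=np.zeros(len(BASE_TRAITS)),
    )
    return geno, truth


def _normalized_kinship(dosage: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Centred-genotype kinship scaled to mean diagonal 1 (mean-imputed)."""
    X = dosage.copy()
    if missing.any():
        m = np.ma.masked_array(X, mask=missing)
        col_mean = np.asarray(m.mean(axis=0).filled(0.0))
        X[missing] = np.broadcast_to(col_mean, X.shape)[missing]
    Z = X - X.mean(axis=0)
    K = Z @ Z.T / Z.shape[1]
    scale = np.trace(K) / K.shape[0]
    if scale > 0:
        K = K / scale
    return K


def simulate_phenotypes(
    geno: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> "pd.DataFrame":
    """Simulate replicate-level phenotypes given genotypes and planted QTLs.

    Returns a tidy table with one row per line x environment x block and the
    ten trait columns. Genetic values combine planted-QTL contributions with
    a correlated polygenic term (line covariance = normalized kinship, trait
    covariance = ``trait_corr``); the polygenic variance tops the genetic
    variance up to ``var_g`` so the total genetic variance matches the
    configured component in expectation.
    """
    import pandas as pd

    config.validate()
    if config.n_qtl > 0 and geno is None:
        raise ValueError("genotypes required when n_qtl > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n, T = config.n_lines, len(BASE_TRAITS)

    # QTL contributions on the standardized trait scale
    g_qtl = np.zeros((n, T))
    if truth.qtl_indices.size:
        X = geno.dosage[:, truth.qtl_indices].copy()
        miss = geno.missing[:, truth.qtl_indices]
        if miss.any():
            m = np.ma.masked_array(X, mask=miss)
            X[miss] = np.broadcast_to(np.asarray(m.mean(axis=0)), X.shape)[miss]
        Xc = X - X.mean(axis=0)
        for q, trait in enumerate(truth.qtl_traits):
            g_qtl[:, BASE_TRAITS.index(trait)] += truth.qtl_effects[q] * Xc[:, q]

    # polygenic part: MVN with Kronecker covariance K (x) C, scaled per trait
    # so Var(qtl) + Var(polygenic) = var_g
    K = _normalized_kinship(geno.dosage, geno.missing)
    w, V = np.linalg.eigh(K)
    Lk = V * np.sqrt(np.clip(w, 0.0, None))
    Cw, Cv = np.linalg.eigh(np.asarray(config.trait_corr, dtype=float))
    Lc = Cv * np.sqrt(np.clip(Cw, 0.0, None))
    poly = Lk @ rng.standard_normal((n, T)) @ Lc.T

    var_qtl = g_qtl.var(axis=0, ddof=1) if n > 1 else np.zeros(T)
    var_poly = np.clip(config.var_g - var_qtl, 0.0, None)
    poly_sd = poly.std(axis=0, ddof=1)
    poly_sd[poly_sd == 0] = 1.0
    poly = poly / poly_sd * np.sqrt(var_poly)
    g = g_qtl + poly

    truth.true_genetic_values = g
    truth.realized_var_g = g.var(axis=0, ddof=1) if n > 1 else np.zeros(T)

    env_eff = rng.normal(0.0, np.sqrt(config.var_e), size=(config.n_envs, T))
    ge = rng.normal(0.0, np.sqrt(config.var_ge), size=(n, config.n_envs, T))

    means, scales = config.means(), config.scales()
    records = []
    for i in range(config.n_envs):
        for b in range(config.n_blocks):
            eps = rng.normal(0.0, np.sqrt(config.var_res), size=(n, T))
            z = g + env_eff[i] + ge[:, i, :] + eps  # standardized scale
            block = {}
            for t, trait in enumerate(BASE_TRAITS):
                block[trait] = means[trait] + scales[trait] * z[:, t]
            df = pd.DataFrame(block)
            df.insert(0, "block", b + 1)
            df.insert(0, "env", f"E{i + 1}")
            df.insert(0, "line_id", geno.line_ids)
            records.append(df)
    pheno = pd.concat(records, ignore_index=True)
    pheno["LWR"] = pheno["KL"] / pheno["KW"]
    pheno["EPR"] = pheno["EH"] / pheno["PH"]
    return pheno[["line_id", "env", "block", *TRAITS]]


def simulate_panel(config: SimConfig | None = None):
    """Convenience wrapper: genotypes + phenotypes + truth in one call."""
    config = config or SimConfig()
    geno, truth = simulate_genotypes(config)
    pheno = simulate_phenotypes(geno, truth, config)
    return geno, pheno, truth
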