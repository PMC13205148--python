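"""Mixed-model fits: block averaging, variance components, BLUPs, Duncan."""

import numpy as np
import pandas as pd
import pytest

from maizecore import (
    SimConfig, anova_duncan, average_blocks, extract_blups, fit_lmm_reml,
    simulate_panel, variance_proportions,
)

UNIT = {t: 1.0 for t in ("KL", "KW", "PH", "EH", "TPN", "TBL", "LUL", "LUT")}
ZERO = {t: 0.0 for t in UNIT}


def _sim(n_lines, var_g, var_res, var_e=0.25, var_ge=0.0, seed=0, n_qtl=0):
    cfg = SimConfig(n_lines=n_lines, n_snps=100, var_g=var_g, var_e=var_e,
                    var_ge=var_ge, var_res=var_res, n_qtl=n_qtl,
                    trait_scales=UNIT, trait_means=ZERO, seed=seed)
    return simulate_panel(cfg)


# ---------------------------------------------------------------- averaging

def test_average_blocks_arithmetic_and_missing():
    df = pd.DataFrame({
        "line_id": ["L1"] * 3 + ["L2"] * 3,
        "env": ["E1"] * 6,
        "block": [1, 2, 3, 1, 2, 3],
        "PH": [10.0, 12.0, 14.0, 10.0, np.nan, 14.0],
        "KL": [5.0, 5.0, 5.0, 1.0, 1.0, 1.0],
    })
    out = average_blocks(df)
    assert out.loc[out.line_id == "L1", "PH"].item() == pytest.approx(12.0)
    assert out.loc[out.line_id == "L2", "PH"].item() == pytest.approx(12.0)
    assert out.loc[out.line_id == "L2", "KL"].item() == pytest.approx(1.0)


def test_average_blocks_single_block_identity():
    df = pd.DataFrame({"line_id": ["A", "B"], "env": ["E1", "E1"],
                       "block": [1, 1], "PH": [7.0, 9.0]})
    out = average_blocks(df)
    assert list(out["PH"]) == [7.0, 9.0]


# ---------------------------------------------------------------- REML fits

def test_null_heritability_limit():
    """var_g = 0 data: variance estimate near 0, BLUPs shrink to the mean."""
    _, pheno, _ = _sim(n_lines=300, var_g=0.0, var_res=1.0, seed=1)
    m = fit_lmm_reml(pheno, "PH")
    assert m.var_g < 0.05
    means = average_blocks(pheno).groupby("line_id")["PH"].mean()
    raw_dev = np.abs(means - means.mean()).max()
    assert np.abs(m.blups).max() < 0.5 * raw_dev  # strong shrinkage toward 0


def test_variance_recovery_balanced():
    """Balanced design, var_g=4, var_res=1: median estimate within 20%."""
    ests = []
    for seed in range(8):
        _, pheno, _ = _sim(n_lines=400, var_g=4.0, var_res=1.0, seed=seed)
        ests.append(fit_lmm_reml(pheno, "PH").var_g)
    assert abs(np.median(ests) - 4.0) / 4.0 < 0.2


def test_closed_form_equals_em_reml():
    _, pheno, _ = _sim(n_lines=80, var_g=2.0, var_res=1.0, seed=4)
    a = fit_lmm_reml(pheno, "PH", method="anova")
    e = fit_lmm_reml(pheno, "PH", method="em")
    assert a.var_g == pytest.approx(e.var_g, abs=1e-6)
    assert a.var_res == pytest.approx(e.var_res, abs=1e-6)
    assert np.allclose(a.blups.sort_index(), e.blups.sort_index(), atol=1e-6)


def test_replicate_level_separates_gxe():
    _, pheno, _ = _sim(n_lines=250, var_g=1.0, var_res=0.5, var_ge=0.8, seed=7)
    m = fit_lmm_reml(pheno, "PH", keep_reps=True)
    assert m.var_ge is not None
    assert abs(m.var_ge - 0.8) < 0.4
    # means path absorbs G x E into the residual instead
    m2 = fit_lmm_reml(pheno, "PH")
    assert m2.var_ge is None
    assert m2.var_res > m.var_res


def test_em_loglik_nondecreasing():
    _, pheno, _ = _sim(n_lines=40, var_g=1.0, var_res=1.0, seed=3)
    pheno = pheno.drop(index=pheno.index[::7])  # unbalance it
    m = fit_lmm_reml(pheno, "PH", method="em", track_loglik=True)
    ll = np.array(m.loglik_path)
    assert np.all(np.diff(ll) > -1e-8)


def test_scale_and_shift_invariance():
    _, pheno, _ = _sim(n_lines=60, var_g=1.5, var_res=1.0, seed=5)
    base = fit_lmm_reml(pheno, "PH")
    shifted = pheno.copy()
    shifted["PH"] += 100.0
    assert fit_lmm_reml(shifted, "PH").var_g == pytest.approx(base.var_g, rel=1e-9)
    scaled = pheno.copy()
    scaled["PH"] *= 3.0
    assert fit_lmm_reml(scaled, "PH").var_g == pytest.approx(9 * base.var_g, rel=1e-9)


def test_blup_shrinkage_dominated_by_raw_deviation():
    _, pheno, _ = _sim(n_lines=50, var_g=1.0, var_res=2.0, seed=6)
    m = fit_lmm_reml(pheno, "PH")
    means = average_blocks(pheno).groupby("line_id")["PH"].mean()
    raw_dev = (means - means.mean()).reindex(m.blups.index)
    assert (np.abs(m.blups) <= np.abs(raw_dev) + 1e-12).all()
    assert abs(m.blups.sum()) < 1e-6 * len(m.blups) * m.blups.std()


def test_blups_beat_raw_means_for_truth_recovery():
    """Shrinkage helps when noise is at least as large as signal."""
    wins = []
    for seed in range(10):
        cfg = SimConfig(n_lines=120, n_snps=100, var_g=1.0, var_e=0.25,
                        var_ge=0.5, var_res=1.5, n_qtl=0,
                        trait_scales=UNIT, trait_means=ZERO, seed=seed)
        geno, pheno, truth = simulate_panel(cfg)
        m = fit_lmm_reml(pheno, "PH")
        truth_ph = pd.Series(truth.true_genetic_values[:, 2], index=geno.line_ids)
        means = average_blocks(pheno).groupby("line_id")["PH"].mean()
        idx = m.blups.index
        r_blup = np.corrcoef(m.blups[idx], truth_ph[idx])[0, 1]
        r_raw = np.corrcoef(means[idx], truth_ph[idx])[0, 1]
        wins.append(r_blup - r_raw)
    assert np.median(wins) >= 0  # shrinkage never hurts on balanced data


def test_degenerate_inputs_rejected():
    df = pd.DataFrame({"line_id": ["A", "B"], "env": ["E1", "E1"],
                       "PH": [1.0, 2.0]})
    with pytest.raises(ValueError, match="degenerate"):
        fit_lmm_reml(df, "PH")


def test_extract_blups_scales():
    _, pheno, _ = _sim(n_lines=30, var_g=1.0, var_res=1.0, seed=8)
    m = {"PH": fit_lmm_reml(pheno, "PH")}
    dev = extract_blups(m, scale="deviation")
    tr = extract_blups(m, scale="trait")
    assert np.allclose(tr["PH"] - dev["PH"], m["PH"].mu)


# ---------------------------------------------------- variance proportions

def test_variance_proportions_sum_and_values():
    _, pheno, _ = _sim(n_lines=40, var_g=1.0, var_res=1.0, seed=2)
    m = fit_lmm_reml(pheno, "PH")
    props = variance_proportions(m)
    assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)
    m.var_g, m.var_res = 1.0, 1.0
    assert variance_proportions(m) == {"genotype": 0.5, "residual": 0.5}
    m.var_g, m.var_res = 2.0, 0.0
    assert variance_proportions(m)["genotype"] == 1.0
    m.var_g = m.var_res = 0.0
    with pytest.raises(ValueError):
        variance_proportions(m)


def test_proportion_recovery():
    """Configured shares (0.6/0.1/0.1/0.2 -> means-path g share 0.6) within 0.1."""
    _, pheno, _ = simulate_panel(SimConfig(n_lines=400, n_snps=100, seed=12,
                                           trait_scales=UNIT, trait_means=ZERO))
    m = fit_lmm_reml(pheno, "PH")
    props = variance_proportions(m)
    # means path: residual = var_ge + var_res/n_blocks = 0.1 + 0.2/3
    expect_g = 0.6 / (0.6 + 0.1 + 0.2 / 3)
    assert abs(props["genotype"] - expect_g) < 0.1


# ------------------------------------------------------------------ Duncan

def test_duncan_forced_separation():
    rng = np.random.default_rng(1)
    vals = np.r_[rng.normal(0, 1, 10), rng.normal(100, 1, 10)]
    groups = ["lo"] * 10 + ["hi"] * 10
    res = anova_duncan(vals, groups)
    assert res.letters["hi"] == "a"
    assert res.letters["lo"] == "b"
    assert res.p_value < 1e-10


def test_duncan_two_groups_matches_pooled_t():
    """With r=2 the Duncan decision reduces to the pooled-variance t-test."""
    from scipy import stats

    rng = np.random.default_rng(7)
    for trial in range(50):
        x = rng.normal(0, 1, 8)
        y = rng.normal(rng.uniform(0, 1.5), 1, 12)
        res = anova_duncan(np.r_[x, y], ["x"] * 8 + ["y"] * 12)
        duncan_sig = not res.same_letter("x", "y")
        t_sig = stats.ttest_ind(x, y, equal_var=True).pvalue < 0.05
        assert duncan_sig == t_sig


def test_duncan_null_calibration():
    """Under identical groups, all share one letter in >= 90% of replicates."""
    rng = np.random.default_rng(20240515)
    groups = np.repeat(["g1", "g2", "g3"], 10)
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        res = anova_duncan(rng.normal(0, 1, 30), groups)
        hits += all(len(v) == 1 for v in res.letters.values()) and \
            len(set(res.letters.values())) == 1
    assert hits / n_rep >= 0.90


def test_duncan_letters_consistent_with_ordering():
    rng = np.random.default_rng(3)
    vals = np.r_[rng.normal(0, 1, 10), rng.normal(1.2, 1, 10), rng.normal(5, 1, 10)]
    res = anova_duncan(vals, np.repeat(["a", "b", "c"], 10))
    ordered = list(res.means.index)
    # groups sharing a letter must be contiguous in the mean ordering
    for g1 in ordered:
        for g2 in ordered:
            if res.same_letter(g1, g2):
                i, j = sorted((ordered.index(g1), ordered.index(g2)))
                assert all(res.same_letter(ordered[i], ordered[k])
                           or res.same_letter(ordered[k], ordered[j])
                           for k in range(i, j + 1))


def test_duncan_rejects_tiny_groups():
    with pytest.raises(ValueError):
        anova_duncan([1.0, 2.0, 3.0], ["a", "a", "b"])
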