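"""MNND, TOPSIS, composite selection, and the published core-set table."""

import numpy as np
import pandas as pd
import pytest

from maizecore import (
    DistanceMatrix, TraitConfig, composite_select, core_report,
    load_core30_reference, mnnd_scores, topsis_scores,
)


def naive_topsis(X, weights, directions):
    """Spreadsheet-style TOPSIS oracle: explicit loops, no vectorization."""
    n, t = X.shape
    Xp = np.zeros_like(X, dtype=float)
    for j in range(t):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        for i in range(n):
            Xp[i, j] = (col[i] - lo) / (hi - lo) if directions[j] > 0 \
                else (hi - col[i]) / (hi - lo)
    V = Xp * weights
    ideal = V.max(axis=0)
    anti = V.min(axis=0)
    D = np.zeros(n)
    for i in range(n):
        dp = np.sqrt(sum((V[i, j] - ideal[j]) ** 2 for j in range(t)))
        dm = np.sqrt(sum((V[i, j] - anti[j]) ** 2 for j in range(t)))
        D[i] = dm / (dp + dm)
    return D


# -------------------------------------------------------------------- MNND

def test_mnnd_trivials():
    D = np.array([[0.0, 5.0], [5.0, 0.0]])
    m = mnnd_scores(DistanceMatrix(D, ["a", "b"]))
    assert (m == 5.0).all()
    E = np.full((3, 3), 5.0)
    np.fill_diagonal(E, 0.0)
    dm = DistanceMatrix(E, list("abc"))
    assert (mnnd_scores(dm, "mean-all") == 5.0).all()
    assert (mnnd_scores(dm, "nearest-k", k=2) == 5.0).all()


def test_mnnd_matches_loop_oracle(rng):
    M = rng.random((10, 10))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    dm = DistanceMatrix(D, [f"L{i}" for i in range(10)])
    mean_all = mnnd_scores(dm, "mean-all")
    near3 = mnnd_scores(dm, "nearest-k", k=3)
    for i in range(10):
        others = [D[i, j] for j in range(10) if j != i]
        assert mean_all.iloc[i] == pytest.approx(np.mean(others), abs=1e-12)
        assert near3.iloc[i] == pytest.approx(np.mean(sorted(others)[:3]), abs=1e-12)
    with pytest.raises(ValueError, match="mode"):
        mnnd_scores(dm, "bogus")


# ------------------------------------------------------------------ TOPSIS

def test_topsis_ideal_and_anti_ideal_lines():
    # line 0 best on all direction-coded traits, line 3 worst
    df = pd.DataFrame({
        "KL": [10.0, 8.0, 7.0, 4.0],     # positive
        "PH": [60.0, 90.0, 120.0, 190.0],  # negative
        "TPN": [2.0, 6.0, 9.0, 25.0],    # negative
    }, index=list("wxyz"))
    cfg = TraitConfig(directions={"KL": 1, "PH": -1, "TPN": -1},
                      weights=pd.Series({"KL": 0.5, "PH": 0.3, "TPN": 0.2}))
    res = topsis_scores(df, cfg)
    assert res.loc["w", "D"] == pytest.approx(1.0, abs=1e-12)
    assert res.loc["z", "D"] == pytest.approx(0.0, abs=1e-12)
    assert res["D"].between(0, 1).all()


def test_topsis_matches_naive_oracle(rng):
    X = rng.normal(size=(50, 10)) * rng.uniform(0.5, 20, size=10) + 50
    traits = [f"T{j}" for j in range(10)]
    directions = {t: (1 if j < 4 else -1) for j, t in enumerate(traits)}
    w = rng.uniform(0.5, 2.0, size=10)
    w = w / w.sum()
    cfg = TraitConfig(directions=directions,
                      weights=pd.Series(w, index=traits))
    res = topsis_scores(pd.DataFrame(X, columns=traits), cfg)
    oracle = naive_topsis(X, w, [directions[t] for t in traits])
    assert np.allclose(res["D"].to_numpy(), oracle, atol=1e-12)


def test_topsis_affine_invariance_and_direction_flip(rng):
    X = rng.normal(size=(20, 3))
    traits = ["a", "b", "c"]
    cfg = TraitConfig(directions={"a": 1, "b": -1, "c": 1},
                      weights=pd.Series([0.3, 0.3, 0.4], index=traits))
    df = pd.DataFrame(X, columns=traits)
    base = topsis_scores(df, cfg)["D"]
    df2 = df.copy()
    df2["a"] = 7.0 * df2["a"] + 3.0   # strictly increasing affine
    assert np.allclose(topsis_scores(df2, cfg)["D"], base, atol=1e-12)
    # flipping a trait's direction and negating its values is a no-op
    cfg_flip = TraitConfig(directions={"a": 1, "b": 1, "c": 1},
                           weights=cfg.weights)
    df3 = df.copy()
    df3["b"] = -df3["b"]
    assert np.allclose(topsis_scores(df3, cfg_flip)["D"], base, atol=1e-12)


def test_topsis_constant_trait_excluded(rng):
    df = pd.DataFrame({"a": rng.normal(size=10), "b": np.full(10, 3.0)})
    cfg = TraitConfig(directions={"a": 1, "b": 1},
                      weights=pd.Series({"a": 0.5, "b": 0.5}))
    with pytest.warns(UserWarning, match="constant"):
        res = topsis_scores(df, cfg)
    assert res["D"].between(0, 1).all()


def test_cv_weights_sum_to_one(rng):
    df = pd.DataFrame(rng.uniform(5, 50, size=(30, 4)), columns=list("abcd"))
    cfg = TraitConfig.from_cv(df, directions={c: 1 for c in "abcd"})
    assert cfg.weights.sum() == pytest.approx(1.0, abs=1e-12)
    cv = df.std(ddof=1) / df.mean() * 100
    assert np.allclose(cfg.weights, cv / cv.sum(), atol=1e-12)


# --------------------------------------------------------------- composite

def make_scores(rng, n=222):
    labels = [f"L{i:03d}" for i in range(n)]
    topsis = pd.DataFrame({"D": rng.uniform(0.3, 0.9, n)}, index=labels)
    mnnd = pd.Series(rng.uniform(40, 70, n), index=labels, name="MNND")
    return topsis, mnnd


def test_composite_degenerate_weights_reduce_to_topsis(rng):
    topsis, mnnd = make_scores(rng)
    sel = composite_select(topsis, mnnd, w_topsis=1.0, w_mnnd=0.0)
    top30_by_d = topsis["D"].sort_values(ascending=False).head(30).index
    assert set(sel.final.index) == set(top30_by_d)
    # equal MNND is equally uninformative
    flat = pd.Series(50.0, index=mnnd.index)
    sel2 = composite_select(topsis, flat, w_topsis=0.8, w_mnnd=0.2)
    assert set(sel2.final.index) == set(top30_by_d)


def test_composite_matches_sort_oracle(rng):
    topsis, mnnd = make_scores(rng)
    sel = composite_select(topsis, mnnd)
    # independent oracle: plain sorts and min-max arithmetic
    d = topsis["D"]
    stage1 = d.sort_values(ascending=False).head(50).index
    ds = d[stage1]
    ms = mnnd[stage1]
    d_sc = (ds - ds.min()) / (ds.max() - ds.min())
    m_sc = (ms - ms.min()) / (ms.max() - ms.min())
    comp = 0.8 * d_sc + 0.2 * m_sc
    expect = comp.sort_values(ascending=False).head(30).index
    assert set(sel.final.index) == set(expect)
    assert list(sel.final.index) == list(expect)


def test_composite_invariant_to_mnnd_rescaling(rng):
    topsis, mnnd = make_scores(rng)
    a = composite_select(topsis, mnnd)
    b = composite_select(topsis, 100.0 * mnnd + 7.0)
    assert list(a.final.index) == list(b.final.index)
    assert np.allclose(a.final["composite"], b.final["composite"], atol=1e-12)


def test_composite_validates_weights_and_sizes(rng):
    topsis, mnnd = make_scores(rng, n=40)
    with pytest.raises(ValueError, match="must equal 1"):
        composite_select(topsis, mnnd, w_topsis=0.9, w_mnnd=0.2)
    with pytest.raises(ValueError, match="n_stage1"):
        composite_select(topsis, mnnd, n_stage1=50, n_final=30)


# ------------------------------------------------- published core-set table

@pytest.fixture(scope="module")
def core30():
    return load_core30_reference()


def test_core30_d_value_range(core30):
    assert core30["D"].max() - core30["D"].min() == pytest.approx(0.1475, abs=1e-9)
    assert core30["D"].is_monotonic_decreasing
    assert (core30["rank"] == np.arange(1, 31)).all()


def test_core30_type_composition(core30):
    counts = core30["type"].value_counts()
    assert counts["sweet"] == 21
    assert counts["waxy"] == 8
    assert counts["sweet-waxy"] == 1


def test_core30_clade_and_ancestry_counts(core30):
    assert (core30["clade"] == "Clade I").sum() == 13
    anc = core30["ancestry"].value_counts()
    assert anc["Ancestry 5"] == 12
    assert anc["Ancestry 4"] == 4
    assert anc["Ancestry 7"] == 4


def test_core30_top_five_d_threshold(core30):
    assert core30["D"].head(5).min() >= 0.81
    assert list(core30.head(5).index) == ["SHT18", "SHT27", "SHT19", "SHT45", "SHT26"]


def test_core30_ratio_traits_consistent(core30):
    """EPR and LWR recomputed from PH/EH and KL/KW match at 2 dp (spot rows)."""
    for line in ["SHT18", "SHT27", "SHT19", "SHT45", "SHT26"]:
        row = core30.loc[line]
        assert round(row.EH / row.PH, 2) == pytest.approx(row.EPR, abs=1e-9)
        assert round(row.KL / row.KW, 2) == pytest.approx(row.LWR, abs=1e-9)
    # every row agrees to within one last-digit rounding step
    assert (core30.EH / core30.PH - core30.EPR).abs().max() < 0.015
    assert (core30.KL / core30.KW - core30.LWR).abs().max() < 0.015


def test_core30_mnnd_range(core30):
    assert core30["MNND"].idxmin() == "SHT38"
    assert core30["MNND"].idxmax() == "SHN69"
    assert core30["MNND"].max() - core30["MNND"].min() == pytest.approx(23.82, abs=1e-9)


def test_core_report_summary(core30, rng):
    topsis = pd.DataFrame({"D": core30["D"], "d_plus": 0.0, "d_minus": 0.0})
    mnnd = core30["MNND"]
    sel = composite_select(topsis, mnnd, n_stage1=30, n_final=30)
    blups = core30[["KL", "KW", "LWR", "PH", "EH", "EPR", "TPN", "TBL", "LUL", "LUT"]]
    rep = core_report(sel, blups, core30[["clade", "ancestry", "type"]])
    assert rep["summary"]["n_selected"] == 30
    assert rep["summary"]["d_range"] == pytest.approx(0.1475, abs=1e-9)
    assert rep["summary"]["by_type"]["sweet"] == 21
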