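"""Diversity statistics against brute-force oracles and printed worked values."""

import numpy as np
import pandas as pd
import pytest

from maizecore import (
    cv_table, locus_stats, pearson_matrix, shannon_index, sturges_k,
)
from maizecore.containers import GenotypeMatrix


def make_geno(dosage, missing=None):
    dosage = np.asarray(dosage, dtype=float)
    if missing is None:
        missing = np.zeros_like(dosage, dtype=bool)
    n, m = dosage.shape
    return GenotypeMatrix(dosage=dosage, missing=missing,
                         line_ids=[f"L{i}" for i in range(n)],
                         chrom=np.array(["chr1"] * m),
                         pos=np.arange(1, m + 1))


# ----------------------------------------------------------------- Sturges

@pytest.mark.parametrize("n,k", [(222, 9), (123, 8), (82, 7), (17, 5), (2, 2)])
def test_sturges_known_values(n, k):
    assert sturges_k(n) == k


def test_sturges_rejects_tiny_n():
    with pytest.raises(ValueError):
        sturges_k(1)


# ----------------------------------------------------------------- Shannon

def test_shannon_uniform_maximum():
    vals = np.repeat([0.5, 1.5, 2.5, 3.5, 4.5], 20)
    res = shannon_index(vals, k=5)
    assert res.H == pytest.approx(np.log(5), abs=1e-12)
    assert res.freqs.sum() == pytest.approx(1.0, abs=1e-12)


def test_shannon_single_bin_and_degenerate():
    res = shannon_index([1.0, 1.0001], k=5)
    # both values in extreme bins -> two occupied bins at most
    assert 0 <= res.H <= np.log(5)
    with pytest.warns(UserWarning, match="degenerate"):
        res0 = shannon_index([3.0, 3.0, 3.0], k=4)
    assert res0.H == 0.0


def test_shannon_matches_histogram_entropy_oracle():
    rng = np.random.default_rng(2024)
    x = rng.normal(10, 3, 222)
    res = shannon_index(x, k=9)
    counts, _ = np.histogram(x, bins=np.linspace(x.min(), x.max(), 10))
    p = counts[counts > 0] / 222
    H_oracle = float(-(p * np.log(p)).sum())
    assert res.H == pytest.approx(H_oracle, abs=1e-12)
    assert 0 <= res.H <= np.log(9)


def test_shannon_affine_invariance():
    rng = np.random.default_rng(5)
    x = rng.gamma(2, 3, 100)
    h1 = shannon_index(x, k=7).H
    h2 = shannon_index(4.0 * x - 17.0, k=7).H
    assert h1 == pytest.approx(h2, abs=1e-12)


def test_shannon_base_option():
    x = np.repeat([1, 2, 3, 4], 10)
    res = shannon_index(x, k=4, base=2)
    assert res.H == pytest.approx(2.0, abs=1e-12)


# ---------------------------------------------------------------------- CV

def test_cv_hand_arithmetic():
    df = pd.DataFrame({"X": [8.0, 12.0], "Y": [5.0, 5.0]},
                      index=["a", "b"])
    out = cv_table(df)
    cv_x = out.loc[(out.group == "all") & (out.trait == "X"), "CV"].item()
    assert cv_x == pytest.approx(np.sqrt(8.0) / 10 * 100, abs=1e-9)  # ~28.28
    cv_y = out.loc[(out.group == "all") & (out.trait == "Y"), "CV"].item()
    assert cv_y == 0.0


def test_cv_recovers_configured_ratio():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"T": rng.normal(50.0, 10.0, 2000)})
    out = cv_table(df)
    cv = out["CV"].item()
    se = 20.0 / np.sqrt(2 * 1999) * 1.5  # rough SE of CV% at n=2000
    assert abs(cv - 20.0) < 2 * se + 0.5


def test_cv_per_group_and_zero_mean_flag():
    df = pd.DataFrame({"T": [1.0, 3.0, -1.0, 1.0]}, index=list("abcd"))
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
    with pytest.warns(UserWarning, match="zero mean"):
        out = cv_table(df, groups)
    assert set(out.group) == {"all", "g1", "g2"}
    assert np.isnan(out.loc[out.group == "g2", "CV"].item())


# ------------------------------------------------------------- locus stats

def brute_force_locus(dosage, missing):
    """Per-locus loop oracle for MAF / Het / pi / PIC."""
    out = []
    for j in range(dosage.shape[1]):
        calls = [dosage[i, j] for i in range(dosage.shape[0]) if not missing[i, j]]
        n = 2 * len(calls)
        p = sum(calls) / n
        q = 1 - p
        het = sum(c == 1 for c in calls) / len(calls)
        pi = n / (n - 1) * 2 * p * q
        pic = 1 - (p ** 2 + q ** 2) - 2 * p ** 2 * q ** 2
        out.append((min(p, q), het, pi, pic))
    return np.array(out)


def test_locus_stats_brute_force_oracle(rng):
    dosage = rng.integers(0, 3, size=(50, 200)).astype(float)
    missing = rng.random((50, 200)) < 0.1
    missing[:2] = False  # keep every locus testable
    stats = locus_stats(make_geno(dosage, missing))["all"]
    oracle = brute_force_locus(dosage, missing)
    assert np.allclose(stats.maf, oracle[:, 0], atol=1e-12)
    assert np.allclose(stats.het, oracle[:, 1], atol=1e-12)
    assert np.allclose(stats.pi, oracle[:, 2], atol=1e-12)
    assert np.allclose(stats.pic, oracle[:, 3], atol=1e-12)


def test_locus_stats_all_het_and_monomorphic():
    geno = make_geno([[1, 0], [1, 0], [1, 0], [1, 0]])
    stats = locus_stats(geno)["all"]
    assert stats.maf[0] == 0.5 and stats.het[0] == 1.0
    assert stats.pic[0] == pytest.approx(0.375, abs=1e-12)
    assert stats.maf[1] == 0 and stats.het[1] == 0
    assert stats.pi[1] == 0 and stats.pic[1] == 0


def test_locus_stats_metric_ordering(rng):
    """PIC <= 2pq and 2pq <= pi for every locus with n >= 2 lines."""
    dosage = rng.integers(0, 3, size=(30, 300)).astype(float)
    geno = make_geno(dosage)
    stats = locus_stats(geno)["all"]
    p = geno.allele_freq()
    two_pq = 2 * p * (1 - p)
    assert np.all(stats.pic <= two_pq + 1e-12)
    assert np.all(two_pq <= stats.pi + 1e-12)


def test_pooled_maf_between_subgroup_extremes(rng):
    dosage = rng.integers(0, 3, size=(40, 50)).astype(float)
    geno = make_geno(dosage)
    groups = np.array(["A"] * 25 + ["B"] * 15)
    stats = locus_stats(geno, groups)
    # pooled ALT frequency lies between subgroup ALT freqs; compare on the
    # frequency scale (folding to MAF can leave the interval)
    f_all = geno.allele_freq()
    f_a = geno.subset_lines(np.where(groups == "A")[0]).allele_freq()
    f_b = geno.subset_lines(np.where(groups == "B")[0]).allele_freq()
    assert np.all(f_all >= np.minimum(f_a, f_b) - 1e-12)
    assert np.all(f_all <= np.maximum(f_a, f_b) + 1e-12)
    assert set(stats) == {"all", "A", "B"}


# ----------------------------------------------------------------- Pearson

def test_pearson_trivial_and_exact():
    x = np.arange(10.0)
    df = pd.DataFrame({"a": x, "b": -x, "c": x ** 2})
    r, p, stars = pearson_matrix(df)
    assert r.loc["a", "a"] == 1.0
    assert r.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)
    assert p.loc["a", "b"] < 1e-10
    assert stars.loc["a", "b"] == "****"


def test_pearson_sampling_near_079():
    rng = np.random.default_rng(79)
    cov = [[1, 0.79], [0.79, 1]]
    xy = rng.multivariate_normal([0, 0], cov, size=222)
    df = pd.DataFrame(xy, columns=["LUL", "LUT"])
    r, p, _ = pearson_matrix(df)
    assert abs(r.loc["LUL", "LUT"] - 0.79) < 0.08
    assert p.loc["LUL", "LUT"] < 1e-4


def test_pearson_p_matches_scipy():
    from scipy import stats as ss

    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    r, p, _ = pearson_matrix(df)
    for pair in (("a", "b"), ("a", "c"), ("b", "c")):
        ref = ss.pearsonr(df[pair[0]], df[pair[1]])
        assert r.loc[pair] == pytest.approx(ref.statistic, abs=1e-12)
        assert p.loc[pair] == pytest.approx(ref.pvalue, rel=1e-9)


def test_pearson_zero_variance_masked():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2]})
    r, p, _ = pearson_matrix(df)
    assert np.isnan(r.loc["a", "b"])
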