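"""Tiles, region matrices, SKAT-O and its permutation oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mthet import regions as R
from mthet.association import echo_threshold
from tests.conftest import toy_calls, toy_samples


@pytest.mark.parametrize("L,window,step,expected", [
    (16569, 100, 10, 1657),
    (100, 100, 10, 10),
    (50, 100, 10, 5),
])
def test_make_tiles_counts(L, window, step, expected):
    tiles = R.make_tiles(L, window, step)
    assert len(tiles) == expected
    assert tiles.windows[0] == (0, min(window, L))
    assert all(b <= L for _, b in tiles.windows)


def test_make_tiles_formula_matches_enumeration():
    for L in range(1, 501):
        for step, window in ((1, 10), (3, 10), (10, 100)):
            tiles = R.make_tiles(L, window, step)
            brute = [(s, min(s + window, L)) for s in range(0, L, step)]
            assert tiles.windows == brute
            assert len(tiles) == (L - 1) // step + 1


def test_make_tiles_rejects_bad_params():
    for window, step in ((5, 10), (10, 0), (0, 0)):
        with pytest.raises(ValueError):
            R.make_tiles(100, window, step)


def _fixture_matrix(n=60, m=4, seed=1, effect=0.0):
    rng = np.random.default_rng(seed)
    G = (rng.random((n, m)) < rng.uniform(0.05, 0.2, m)).astype(float)
    age = rng.uniform(30, 90, n)
    lin = -0.5 + 0.01 * (age - 60) + effect * G.sum(axis=1)
    y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
    X = pd.DataFrame({"const": 1.0, "age": age})
    maf = np.maximum(G.mean(axis=0), 1 / (2 * n))
    w = stats.beta.pdf(maf, 1, 25)
    return R.RegionGenotypeMatrix("fixture", G, w, y, X)


_TR = {"A": "G", "G": "A", "C": "T", "T": "C"}


def test_region_matrix_toy(ann):
    rows = [(f"s{i}", 300, ann.genome.base(300), _TR[ann.genome.base(300)], 0.5)
            for i in range(3)]
    calls = toy_calls(rows)
    samples = toy_samples([f"s{i}" for i in range(100)])
    samples.loc[:49, "group"] = "control"
    mat = R.region_matrix(calls, (249, 350), samples, case_group="HTN")
    assert mat.genotypes.shape == (100, 1)
    assert mat.genotypes.sum() == 3


def test_region_matrix_dloop_wrap(ann):
    rows = [("s0", 16100, ann.genome.base(16100), _TR[ann.genome.base(16100)], 0.5),
            ("s1", 300, ann.genome.base(300), _TR[ann.genome.base(300)], 0.5)]
    samples = toy_samples(["s0", "s1", "s2", "s3"])
    samples.loc[2:, "group"] = "control"
    dloop = ann.locus_map["MT-DLOOP"].positions()
    mat = R.region_matrix(toy_calls(rows), dloop, samples, case_group="HTN")
    assert mat.genotypes.shape[1] == 2


def test_region_matrix_class_filter_and_empty(ann):
    rows = [("s0", 300, ann.genome.base(300), _TR[ann.genome.base(300)], 0.07)]
    samples = toy_samples(["s0", "s1"])
    samples.loc[1:, "group"] = "control"
    with pytest.raises(R.EmptyRegionError):
        R.region_matrix(toy_calls(rows), (249, 350), samples,
                        het_class_filter=(0.10, 0.95), case_group="HTN")
    mat = R.region_matrix(toy_calls(rows), (249, 350), samples,
                          het_class_filter=(0.05, 0.10), case_group="HTN")
    assert mat.genotypes.sum() == 1


def test_single_variant_region_collapses():
    m = _fixture_matrix(m=1, seed=2)
    res = R.skat_o_test(m)
    assert res.p_skat == res.p_burden == res.p_skato
    assert res.n_variants == 1


def test_rho_one_equals_burden_score_test():
    """At rho = 1 the statistic is the weighted collapsing score test; compare
    with a hand-built one-degree chi-square score test."""
    m = _fixture_matrix(seed=4)
    res = R.skat_o_test(m)
    import statsmodels.api as sm

    X = m.covariates.to_numpy()
    fit = sm.GLM(m.phenotype, X, family=sm.families.Binomial()).fit()
    mu = fit.fittedvalues
    v = mu * (1 - mu)
    b = (m.genotypes * np.sqrt(m.weights)).sum(axis=1)  # collapsed burden
    score = b @ (m.phenotype - mu)
    xv = X * v[:, None]
    var = b @ (v * b) - (b @ xv) @ np.linalg.solve(X.T @ xv, xv.T @ b)
    p_hand = stats.chi2.sf(score**2 / var, 1)
    assert res.p_burden == pytest.approx(p_hand, abs=1e-6)


def test_skato_column_order_invariance():
    m = _fixture_matrix(seed=5)
    perm = [2, 0, 3, 1]
    m2 = R.RegionGenotypeMatrix(m.region, m.genotypes[:, perm],
                                m.weights[perm], m.phenotype, m.covariates)
    a, b = R.skat_o_test(m), R.skat_o_test(m2)
    assert a.p_skato == pytest.approx(b.p_skato, rel=1e-8)
    assert a.p_skat == pytest.approx(b.p_skat, rel=1e-8)


def test_moment_matching_agrees_with_permutation_oracle():
    """Fixed small instance (n=60, 4 variants): |moment p - permutation p| <= 0.02
    at 100,000 permutations."""
    for effect in (0.0, 1.0):
        m = _fixture_matrix(seed=1, effect=effect)
        res = R.skat_o_test(m)
        p_perm = R.permutation_region_test(m, n_perm=100000, seed=9)
        assert abs(res.p_skato - p_perm) <= 0.02


def test_permutation_reproducible_and_bounds():
    m = _fixture_matrix(seed=6)
    p1 = R.permutation_region_test(m, n_perm=2000, seed=3)
    p2 = R.permutation_region_test(m, n_perm=2000, seed=3)
    assert p1 == p2
    with pytest.raises(ValueError):
        R.permutation_region_test(m, n_perm=10, seed=3)


def test_permutation_separating_variant_extreme_p():
    rng = np.random.default_rng(0)
    n = 60
    y = np.zeros(n)
    y[:6] = 1
    G = y.reshape(-1, 1).copy()  # perfectly separating carrier set
    X = pd.DataFrame({"const": np.ones(n)})
    m = R.RegionGenotypeMatrix("sep", G, np.array([1.0]), y, X)
    n_perm = 1999
    p = R.permutation_region_test(m, n_perm=n_perm, seed=1)
    assert p == pytest.approx(1 / (1 + n_perm))


def test_permutation_null_p_uniform():
    """Null permutation p-values follow U(0,1) over replicate datasets."""
    ps = []
    for i in range(200):
        m = _fixture_matrix(n=60, m=3, seed=3000 + i)
        ps.append(R.permutation_region_test(m, n_perm=1000, seed=i))
    _, p_ks = stats.kstest(ps, "uniform")
    assert p_ks > 0.01


def test_genomewide_scan_thresholds(ann, small_cohort):
    regions = ann.locus_map.region_sets()
    assert len(regions) == 39
    df, thr = R.genomewide_region_scan(small_cohort.calls.head(200),
                                       small_cohort.samples, regions,
                                       case_group="HTN",
                                       covariates=("age",))
    assert echo_threshold(thr) == pytest.approx(0.001)
    assert len(df) == 39
    tested = df[df["method"] != "untested"]
    assert ((tested["p_skato"] > 0) & (tested["p_skato"] <= 1)).all()
    tiles = R.make_tiles()
    assert echo_threshold(0.05 / len(tiles)) == pytest.approx(3e-05)
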