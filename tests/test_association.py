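"""NB burden regression and the cohort-level comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from mthet import association as A
from tests.conftest import toy_samples


def _design(y, X_df):
    return A.DesignMatrix(response=np.asarray(y, dtype=float), exog=X_df)


def _make_nb_data(n=2000, beta=np.log(2), alpha=0.5, seed=0):
    rng = np.random.default_rng(seed)
    grp = (rng.random(n) < 0.5).astype(float)
    mu = np.exp(0.2 + beta * grp)
    y = rng.poisson(mu * rng.gamma(1 / alpha, alpha, n))
    X = pd.DataFrame({"const": 1.0, "grp": grp})
    return y, X


def _independent_nb_mle(y, X):
    """Full NB2 log-likelihood optimised directly; oracle for fit_nb_glm."""
    Xm = X.to_numpy(dtype=float)

    def nll(params):
        beta, la = params[:-1], params[-1]
        a = np.exp(la)
        mu = np.exp(Xm @ beta)
        size = 1 / a
        ll = (special.gammaln(y + size) - special.gammaln(size)
              - special.gammaln(y + 1)
              + size * np.log(size / (size + mu))
              + y * np.log(mu / (size + mu)))
        return -ll.sum()

    x0 = np.append(np.zeros(Xm.shape[1]), 0.0)
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-8,
                                     "fatol": 1e-10})
    return res.x[:-1], np.exp(res.x[-1])


def test_nb_fit_matches_independent_optimizer():
    y, X = _make_nb_data()
    res = A.fit_nb_glm(_design(y, X))
    beta_hat, alpha_hat = _independent_nb_mle(y, X)
    assert res.model == "negbin"
    assert np.allclose(res.params["beta"].to_numpy(), beta_hat, atol=1e-3)
    assert abs(res.alpha - alpha_hat) < 1e-2
    assert abs(res["grp"]["beta"] - np.log(2)) < 2 * res["grp"]["se"]


def test_intercept_only_constant_counts_poisson_limit():
    y = np.full(500, 3.0)
    X = pd.DataFrame({"const": np.ones(500)})
    res = A.fit_nb_glm(_design(y, X))
    assert res.model == "poisson"  # equidispersion limit
    assert res["const"]["beta"] == pytest.approx(np.log(3), abs=1e-8)


def test_nb_reduces_to_poisson_on_poisson_data():
    rng = np.random.default_rng(1)
    n = 5000
    x = rng.normal(size=n)
    mu = np.exp(0.3 + 0.4 * x)
    y = rng.poisson(mu)
    X = pd.DataFrame({"const": 1.0, "x": x})
    res_nb = A.fit_nb_glm(_design(y, X))
    import statsmodels.api as sm
    res_pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    assert np.allclose(res_nb.params["beta"].to_numpy(),
                       np.asarray(res_pois.params), atol=1e-3)


def test_wald_p_invariant_to_covariate_rescaling():
    y, X = _make_nb_data(seed=3)
    rng = np.random.default_rng(3)
    X["age"] = rng.uniform(30, 90, len(y))
    p1 = A.fit_nb_glm(_design(y, X)).params["p"]
    X2 = X.copy()
    X2["age"] = X2["age"] / 10 + 5.0
    p2 = A.fit_nb_glm(_design(y, X2)).params["p"]
    # invariance holds up to the optimizer's convergence tolerance
    assert p1["grp"] == pytest.approx(p2["grp"], rel=1e-2)
    assert p1["age"] == pytest.approx(p2["age"], rel=1e-2)


def test_rank_deficiency_and_shape_errors():
    y, X = _make_nb_data(n=100)
    X["dup"] = X["grp"]
    with pytest.raises(np.linalg.LinAlgError):
        A.fit_nb_glm(_design(y, X))
    with pytest.raises(ValueError):
        A.fit_nb_glm(_design(np.arange(2), pd.DataFrame({"const": [1.0, 1.0],
                                                         "a": [0.0, 1.0],
                                                         "b": [1.0, 0.0]})))


@pytest.mark.parametrize("alpha,m,expected,echoed", [
    (0.05, 6, 0.05 / 6, 0.008),
    (0.05, 5, 0.01, 0.01),
    (0.05, 39, 0.05 / 39, 0.001),
    (0.05, 1657, 0.05 / 1657, 3e-05),
    (0.05, 1, 0.05, 0.05),
])
def test_bonferroni_and_echo(alpha, m, expected, echoed):
    thr = A.bonferroni_threshold(alpha, m)
    assert thr == pytest.approx(expected)
    assert A.echo_threshold(thr) == pytest.approx(echoed)


def test_bonferroni_rejects_bad_m():
    with pytest.raises(ValueError):
        A.bonferroni_threshold(0.05, 0)


def test_spearman_examples():
    rho, _ = A.spearman_frequency_concordance([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert rho == pytest.approx(1.0)
    rho, _ = A.spearman_frequency_concordance([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
    assert rho == pytest.approx(-1.0)
    rho, _ = A.spearman_frequency_concordance([1, 2, 3, 4, 5], [1, 3, 2, 4, 5])
    assert rho == pytest.approx(0.9)
    with pytest.raises(A.DegenerateInputError):
        A.spearman_frequency_concordance([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        A.spearman_frequency_concordance([1, 2], [1, 2])


def test_ks_examples():
    x = np.linspace(0.1, 0.9, 50)
    d, p = A.ks_hf_compare(x, x)
    assert d == pytest.approx(0.0)
    d, _ = A.ks_hf_compare(np.linspace(0, 0.4, 40), np.linspace(0.6, 1.0, 40))
    assert d == pytest.approx(1.0)
    with pytest.raises(ValueError):
        A.ks_hf_compare([], x)


def test_ks_detects_shifted_pathogenic_hfs():
    rng = np.random.default_rng(0)
    dloop = rng.beta(2.5, 1.8, 400)          # high-HF reference
    path = rng.beta(1.6, 2.8, 300)           # stochastically lower
    _, p = A.ks_hf_compare(path, dloop)
    assert p < 0.01


def test_score_comparisons_null_and_degenerate():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "group": ["HTN"] * 200 + ["control"] * 200,
        "cls": (["intermediate", "low"] * 100) * 2,
        "score": rng.beta(2, 2, 400),
    })
    out = A.score_comparisons(df)
    assert out["mannwhitney"]["HTN"]["p"] > 0.05
    assert out["anova"].loc["C(grp)", "PR(>F)"] > 0.05
    df_const = df.assign(score=0.5)
    with pytest.raises(A.DegenerateInputError):
        A.score_comparisons(df_const)
    with pytest.raises(ValueError):
        A.score_comparisons(df[df["group"] == "HTN"])


def test_mannwhitney_power_under_location_shift():
    rng = np.random.default_rng(1)
    hits = 0
    reps = 40
    for _ in range(reps):
        a = rng.normal(0.5, 0.15, 200)
        b = rng.normal(0.3, 0.15, 200)
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        hits += p < 0.05
    assert hits / reps > 0.95


def test_association_suite_family_thresholds(default_qc, ann):
    from mthet.burden import individual_burden

    b = individual_burden(default_qc.calls, default_qc.samples, ann)
    results = A.burden_association_suite(b, default_qc.samples)
    assert len(results) == 2  # one disease x two classes
    assert results[0]["threshold"] == pytest.approx(0.05 / 2)
    cats = A.burden_association_suite(
        b, default_qc.samples, classes=("intermediate",),
        categories=("non-synonymous", "synonymous", "tRNA", "rRNA", "D-loop"))
    assert len(cats) == 5
    assert cats[0]["threshold"] == pytest.approx(0.01)
    for item in cats:
        assert 0 < item["result"]["case"]["p"] <= 1


def test_familywise_error_under_null():
    """3 diseases x 2 classes on null burden: family-wise error near 5%."""
    rng = np.random.default_rng(7)
    n_per = 90
    groups = ["HTN"] * n_per + ["IHD"] * n_per + ["IS"] * n_per + ["control"] * n_per
    reps, fw_hits = 100, 0
    for _ in range(reps):
        samples = toy_samples([f"s{i}" for i in range(4 * n_per)])
        samples["group"] = groups
        samples["age"] = rng.uniform(30, 90, len(samples))
        counts = rng.poisson(1.2 * rng.gamma(2.0, 0.5, len(samples)))
        burden = pd.DataFrame({("intermediate", "total"): counts,
                               ("low", "total"): rng.poisson(0.4, len(samples))},
                              index=pd.Index(samples["sample_id"],
                                             name="sample_id"))
        res = A.burden_association_suite(burden, samples, covariates=("age",))
        thr = res[0]["threshold"]
        assert thr == pytest.approx(0.05 / 6)
        fw_hits += any(item["result"]["case"]["p"] < thr for item in res)
    assert fw_hits / reps <= 0.12  # 5% nominal + binomial slack
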