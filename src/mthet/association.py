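"""Burden association models and cohort-level comparison statistics.

The central model is a negative-binomial (NB2) regression of per-individual
heteroplasmy burden on case status with age, sex, mean read depth and
mitochondrial ancestry as covariates; the dispersion is estimated by maximum
likelihood and the fit falls back to Poisson when the data are equidispersed.
Bonferroni thresholds for each test family echo the one-significant-figure
convention used in reports (0.05/6 -> 0.008, 0.05/39 -> 0.001, ...).

Also provided: Spearman frequency concordance against reference panels,
two-sample Kolmogorov-Smirnov comparisons of HF distributions against the
D-loop reference, Mann-Whitney U for conservation scores, and a two-way
fixed-effects ANOVA for pathogenicity scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_COVARIATES = ("age", "sex", "mean_depth", "mt_ancestry")


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined on the given input."""


@dataclass
class DesignMatrix:
    response: np.ndarray
    exog: pd.DataFrame  # includes an intercept column named "const"
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.response) != len(self.exog):
            raise ValueError("response and predictors have different lengths")
        if np.asarray(self.exog).ndim != 2:
            raise ValueError("exog must be 2-D")
        if pd.isna(self.exog.to_numpy(dtype=float)).any() or np.isnan(
                np.asarray(self.response, dtype=float)).any():
            raise ValueError("missing values in used columns")


@dataclass
class RegressionResult:
    params: pd.DataFrame  # index: term; columns: beta, se, p
    alpha: float          # NB2 dispersion (0 under the Poisson fallback)
    model: str            # "negbin" | "poisson"
    converged: bool
    n_obs: int
    threshold: float | None = None  # Bonferroni threshold of the test family

    def __getitem__(self, term: str) -> pd.Series:
        return self.params.loc[term]


def _encode(samples: pd.DataFrame, covariates, case_group: str | None) -> pd.DataFrame:
    X = pd.DataFrame(index=samples.index)
    X["const"] = 1.0
    if case_group is not None:
        X["case"] = (samples["group"] == case_group).astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex_M"] = (samples["sex"] == "M").astype(float)
        elif cov == "mt_ancestry":
            # treatment coding, reference level = European
            X["ancestry_nonEur"] = (samples["mt_ancestry"] != "European").astype(float)
        else:
            X[cov] = samples[cov].astype(float)
    return X


def build_design(burden: pd.DataFrame, samples: pd.DataFrame,
                 response_class: str = "intermediate",
                 category: str = "total",
                 case_group: str | None = None,
                 covariates=DEFAULT_COVARIATES) -> DesignMatrix:
    """Assemble a regression design from a burden table and sample metadata.

    Rows with missing values in any used covariate are dropped
    (complete-case analysis).
    """
    s = samples.set_index("sample_id")
    y = burden[(response_class, category)].reindex(s.index)
    used = [c for c in covariates if c not in ("sex", "mt_ancestry")]
    keep = s[used].notna().all(axis=1) & y.notna() if used else y.notna()
    s = s[keep]
    X = _encode(s.reset_index(), covariates, case_group)
    return DesignMatrix(
        response=y[keep].to_numpy(dtype=float),
        exog=X.set_index(s.index),
        sample_ids=list(s.index),
    )


def _result_frame(res, terms) -> pd.DataFrame:
    return pd.DataFrame(
        {"beta": np.asarray(res.params)[: len(terms)],
         "se": np.asarray(res.bse)[: len(terms)],
         "p": np.asarray(res.pvalues)[: len(terms)]},
        index=terms,
    )


def fit_nb_glm(design: DesignMatrix, alpha_floor: float = 1e-6) -> RegressionResult:
    """NB2 regression with MLE dispersion; Poisson fallback when equidispersed.

    Wald z p-values per coefficient. Non-convergence is flagged, never
    silently reported; a rank-deficient design raises.
    """
    y = np.asarray(design.response, dtype=float)
    X = design.exog
    if np.any(y < 0):
        raise ValueError("burden counts must be non-negative")
    if len(y) <= X.shape[1]:
        raise ValueError("more predictors than observations")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient (collinearity)")
    terms = list(X.columns)

    def poisson_fit() -> RegressionResult:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        return RegressionResult(_result_frame(res, terms), 0.0, "poisson",
                                True, len(y))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            start = np.append(sm.GLM(y, X, family=sm.families.Poisson()).fit().params,
                              0.1)
            nb = sm.NegativeBinomial(y, X, loglike_method="nb2")
            res = nb.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            return poisson_fit()
    alpha = float(np.asarray(res.params)[-1])
    bse = np.asarray(res.bse)
    if (not converged or not np.all(np.isfinite(bse[:-1])) or alpha < alpha_floor):
        out = poisson_fit()
        out.converged = True if alpha < alpha_floor else converged
        return out
    return RegressionResult(_result_frame(res, terms), alpha, "negbin",
                            converged, len(y))


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m < 1:
        raise ValueError("the number of tests must be >= 1")
    return alpha / m


def echo_threshold(threshold: float) -> float:
    """One-significant-figure echo used in human-readable reports
    (0.05/6 -> 0.008, 0.05/39 -> 0.001, 0.05/1657 -> 3e-05)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exp = np.floor(np.log10(threshold))
    return float(round(threshold / 10**exp) * 10**exp)


def burden_association_suite(burden: pd.DataFrame, samples: pd.DataFrame,
                             contrasts: list[str] | None = None,
                             classes: tuple[str, ...] = ("intermediate", "low"),
                             categories: tuple[str, ...] = ("total",),
                             covariates=DEFAULT_COVARIATES,
                             alpha: float = 0.05) -> list[dict]:
    """One NB model per (disease vs control) x class x category, with the
    Bonferroni threshold of the family attached to every result."""
    groups = [g for g in samples["group"].unique() if g != "control"]
    contrasts = contrasts or sorted(groups)
    jobs = [(d, cls, cat) for d in contrasts for cls in classes for cat in categories]
    threshold = bonferroni_threshold(alpha, len(jobs))
    out = []
    for disease, cls, cat in jobs:
        sub = samples[samples["group"].isin([disease, "control"])]
        design = build_design(burden, sub, response_class=cls, category=cat,
                              case_group=disease, covariates=covariates)
        res = fit_nb_glm(design)
        res.threshold = threshold
        out.append({"disease": disease, "class": cls, "category": cat,
                    "result": res, "threshold": threshold})
    return out


def spearman_frequency_concordance(cohort_afs: np.ndarray,
                                   panel_afs: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties), two-sided p."""
    x = np.asarray(cohort_afs, dtype=float)
    y = np.asarray(panel_afs, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 shared sites")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def ks_hf_compare(class_hfs: np.ndarray, dloop_hfs: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided KS statistic and asymptotic p; the D-loop HF
    sample is the reference distribution."""
    a = np.asarray(class_hfs, dtype=float)
    b = np.asarray(dloop_hfs, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS comparison requires non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def score_comparisons(scores: pd.DataFrame, group_col: str = "group",
                      class_col: str = "cls",
                      score_col: str = "score") -> dict:
    """Mann-Whitney U per disease-vs-control contrast and a two-way
    fixed-effects ANOVA (group x heteroplasmy class)."""
    import statsmodels.formula.api as smf

    df = scores.dropna(subset=[score_col, group_col, class_col])
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("score comparison needs at least two groups")
    if df[score_col].nunique() == 1:
        raise DegenerateInputError("all scores equal: test statistics undefined")
    mwu = {}
    control = df[df[group_col] == "control"][score_col]
    for g in groups:
        if g == "control" or control.empty:
            continue
        u, p = stats.mannwhitneyu(df[df[group_col] == g][score_col], control,
                                  alternative="two-sided", method="asymptotic")
        mwu[g] = {"U": float(u), "p": float(p)}
    d = df.rename(columns={group_col: "grp", class_col: "hclass",
                           score_col: "score_"})
    model = smf.ols("score_ ~ C(grp) + C(hclass)", data=d).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return {"mannwhitney": mwu, "anova": anova}
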