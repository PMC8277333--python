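"""Statistical analyses of self-weighing frequency and weight change.

Three layers, mirroring the study design:

* **Descriptives** — per-BMI-group summary tables with between-group tests
  (chi-square for counts, one-way ANOVA for means, Kruskal-Wallis for
  skewed variables), and the break-analysis table for users with at least
  one >=30-day break.
* **User level** — Pearson/Spearman correlations between self-weighing
  frequency and weight change (overall and per BMI group), and OLS models
  with a frequency x BMI-group interaction, optionally adjusted for sex,
  age, initial BMI and follow-up duration.  Normal weight is always the
  reference group.
* **Pair level** — linear mixed-effects models of weight change per day on
  the day gap between consecutive measurements (or on the categorical
  self-weighing frequency, reference = daily), with a per-subject random
  intercept and slope; adjusted variants add sex, age, initial BMI,
  weekday and the morning/evening combination.  REML is the default
  criterion.  Pairs flagged as excluded (>20% change per day) are dropped.

Model estimation delegates to statsmodels/scipy; the bespoke part of the
package is the pipeline feeding these models, not the estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import logger
from .metrics import BMI_GROUPS, FREQ_CATEGORIES

__all__ = [
    "AnalysisResult",
    "summarize_cohort",
    "correlate",
    "fit_interaction_model",
    "fit_temporal_lme",
    "break_analysis",
]


@dataclass
class AnalysisResult:
    """Coefficient/correlation tables plus free-form extras."""

    name: str
    params: pd.DataFrame = None        # term | estimate | se | p
    table: pd.DataFrame = None         # group summary table, if any
    extras: dict = field(default_factory=dict)
    model: object = None               # fitted statsmodels results, if any


def _coef_table(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {"term": fit.params.index, "estimate": fit.params.to_numpy(),
         "se": fit.bse.to_numpy(), "p": fit.pvalues.to_numpy()}
    ).reset_index(drop=True)


def _mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.2f} ({x.std(ddof=1):.2f})"


def _median_iqr(x: pd.Series) -> str:
    q1, q2, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{q2:.2f} ({q1:.2f} to {q3:.2f})"


def _groups(metrics: pd.DataFrame):
    return [metrics.loc[metrics["bmi_group"] == g] for g in BMI_GROUPS]


def _testable(groups) -> bool:
    """Tests run across the groups actually present; each needs >= 2 users."""
    present = [g for g in groups if len(g) > 0]
    return len(present) >= 2 and all(len(g) >= 2 for g in present)


def summarize_cohort(metrics: pd.DataFrame) -> AnalysisResult:
    """Background/self-weighing summary per BMI group with between-group tests."""
    groups = _groups(metrics)
    ok = _testable(groups)
    rows = [{"characteristic": "n", "all": str(len(metrics)),
             **{g: str(len(sub)) for g, sub in zip(BMI_GROUPS, groups)},
             "test": "", "statistic": np.nan, "p": np.nan}]

    def add(label, col, agg, test):
        row = {"characteristic": label, "all": agg(metrics[col]),
               **{g: agg(sub[col]) if len(sub) else "" for g, sub in zip(BMI_GROUPS, groups)}}
        stat, p, tname = np.nan, np.nan, "n/a"
        if test and ok:
            vals = [sub[col].dropna() for sub in groups if len(sub)]
            if test == "anova":
                stat, p = stats.f_oneway(*vals)
                tname = "anova"
            elif test == "kruskal":
                stat, p = stats.kruskal(*vals)
                tname = "kruskal"
        row.update({"test": tname if test else "", "statistic": stat, "p": p})
        rows.append(row)

    # sex: chi-square on the group x sex contingency table, no continuity correction
    n_male = (metrics["sex"] == "male").sum()
    row = {"characteristic": "male, n (%)",
           "all": f"{n_male} ({100 * n_male / len(metrics):.1f})"}
    for g, sub in zip(BMI_GROUPS, groups):
        m = (sub["sex"] == "male").sum()
        row[g] = f"{m} ({100 * m / len(sub):.1f})" if len(sub) else ""
    if ok and metrics["sex"].nunique() > 1:
        tab = pd.crosstab(metrics["bmi_group"], metrics["sex"])
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        row.update({"test": "chi2", "statistic": chi2, "p": p})
    else:
        row.update({"test": "n/a", "statistic": np.nan, "p": np.nan})
    rows.append(row)

    add("age (years), mean (SD)", "age", _mean_sd, "anova")
    add("initial weight (kg), mean (SD)", "initial_weight_kg", _mean_sd, None)
    add("BMI (kg/m2), mean (SD)", "bmi", _mean_sd, None)
    add("follow-up (days), mean (SD)", "follow_up_days", _mean_sd, "anova")
    add("measurements, median (IQR)", "n_measurements", _median_iqr, "kruskal")
    add("% days measured, mean (SD)", "pct_days_measured", _mean_sd, "anova")
    add("measurements/week, mean (SD)", "per_week", _mean_sd, "anova")
    add("weight change (kg), mean (SD)", "weight_change_kg", _mean_sd, "anova")
    add("weight change (%), mean (SD)", "weight_change_pct", _mean_sd, "anova")
    add("max weight change (kg), median (IQR)", "max_weight_change_kg", _median_iqr, "kruskal")
    return AnalysisResult(name="cohort_summary", table=pd.DataFrame(rows))


def correlate(
    metrics: pd.DataFrame,
    x: str = "pct_days_measured",
    y: str = "weight_change_kg",
    method: str = "pearson",
    by_group: bool = True,
) -> AnalysisResult:
    """Correlation between two user-level variables, overall and per BMI group.

    Zero-variance input yields NaN with a warning rather than an error.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    func = stats.pearsonr if method == "pearson" else stats.spearmanr

    def one(sub):
        xs, ys = sub[x].dropna(), sub[y].dropna()
        common = sub[[x, y]].dropna()
        if len(common) < 3:
            return np.nan, np.nan, len(common)
        if common[x].nunique() == 1 or common[y].nunique() == 1:
            warnings.warn(f"zero variance in {x!r} or {y!r}: correlation undefined")
            return np.nan, np.nan, len(common)
        r, p = func(common[x], common[y])
        return float(r), float(p), len(common)

    rows = []
    r, p, n = one(metrics)
    rows.append({"group": "all", "r": r, "p": p, "n": n})
    if by_group:
        for g in BMI_GROUPS:
            r, p, n = one(metrics[metrics["bmi_group"] == g])
            rows.append({"group": g, "r": r, "p": p, "n": n})
    out = pd.DataFrame(rows)
    return AnalysisResult(name=f"{method}_{x}_{y}", table=out,
                          extras={"r": out.loc[0, "r"], "p": out.loc[0, "p"]})


def _check_full_rank(design: pd.DataFrame) -> None:
    X = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        for j in range(1, X.shape[1]):
            sub = X[:, :j]
            beta, *_ = np.linalg.lstsq(sub, X[:, j], rcond=None)
            if np.allclose(sub @ beta, X[:, j], atol=1e-8):
                collinear.append(design.columns[j])
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {collinear}")


def fit_interaction_model(
    metrics: pd.DataFrame,
    frequency: str = "pct_days_measured",
    outcome: str = "weight_change_kg",
    adjusted: bool = False,
) -> AnalysisResult:
    """OLS of weight change on frequency x BMI group (reference: normal weight).

    The adjusted variant adds sex, age, initial BMI and follow-up duration.
    """
    df = metrics.copy()
    df["bmi_group"] = pd.Categorical(df["bmi_group"], categories=BMI_GROUPS)
    formula = f"{outcome} ~ {frequency} * C(bmi_group, Treatment('normal'))"
    if adjusted:
        formula += " + C(sex) + age + bmi + follow_up_days"
    model = smf.ols(formula, data=df)
    _check_full_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    fit = model.fit()
    return AnalysisResult(name="interaction_ols", params=_coef_table(fit), model=fit,
                          extras={"formula": formula, "n": int(fit.nobs)})


def _lme_data(pairs: pd.DataFrame, metrics: pd.DataFrame | None, adjusted: bool) -> pd.DataFrame:
    df = pairs.loc[~pairs["excluded"]].copy()
    counts = df.groupby("user_id")["gap_days"].transform("size")
    df = df[counts >= 2]
    if adjusted:
        if metrics is None:
            raise ValueError("adjusted pair-level models need the user metrics table for covariates")
        cov = metrics.set_index("user_id")[["sex", "age", "bmi", "bmi_group"]]
        df = df.join(cov, on="user_id", how="inner")
    elif metrics is not None:
        df = df.join(metrics.set_index("user_id")[["bmi_group"]], on="user_id", how="left")
    return df


def fit_temporal_lme(
    pairs: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    predictor: str = "gap",
    adjusted: bool = False,
    bmi_interaction: bool = False,
    reml: bool = True,
    random_effects: str = "slope",
) -> AnalysisResult:
    """Mixed model of weight change per day on the gap between measurements.

    ``predictor='gap'`` uses the day gap as a continuous fixed effect;
    ``predictor='category'`` uses the frequency category (reference: daily),
    optionally interacted with BMI group.  Subjects get a random intercept
    plus a random slope on the gap (``random_effects='slope'``); singular
    random-effects fits fall back to an intercept-only structure with a
    warning, and ``random_effects='none'`` collapses to OLS.
    """
    df = _lme_data(pairs, metrics, adjusted)
    if predictor == "gap":
        fixed = "change_per_day_kg ~ gap_days"
    elif predictor == "category":
        df["freq_category"] = pd.Categorical(df["freq_category"], categories=FREQ_CATEGORIES)
        fixed = "change_per_day_kg ~ C(freq_category, Treatment('daily'))"
        if bmi_interaction:
            df["bmi_group"] = pd.Categorical(df["bmi_group"], categories=BMI_GROUPS)
            fixed = "change_per_day_kg ~ C(freq_category, Treatment('daily')) * C(bmi_group, Treatment('normal'))"
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    if adjusted:
        fixed += " + C(sex) + age + bmi + C(weekday) + C(tod_combo)"

    if random_effects == "none" or df["change_per_day_kg"].std() == 0:
        # a constant outcome has zero fixed effects and zero random variances;
        # MixedLM cannot profile a zero scale, so the OLS limit is exact here
        fit = smf.ols(fixed, data=df).fit()
        return AnalysisResult(name="temporal_ols", params=_coef_table(fit), model=fit,
                              extras={"formula": fixed, "n": int(fit.nobs),
                                      "degenerate": df["change_per_day_kg"].std() == 0})

    re_formula = "~gap_days" if (random_effects == "slope" and predictor == "gap") else "1"
    if random_effects == "slope" and predictor == "category":
        re_formula = "1"  # slope on a category set is not identified; intercept only

    def _fit(re_form):
        model = smf.mixedlm(fixed, data=df, groups=df["user_id"], re_formula=re_form)
        # boundary fits (zero variance) can report converged with wild SEs;
        # reject anything with non-finite or absurd fixed-effect SEs
        se_cap = 1e3 * max(float(np.std(model.endog)), 1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell", "cg"):
                try:
                    fit = model.fit(reml=reml, method=method, maxiter=500)
                except np.linalg.LinAlgError:
                    continue
                if fit.converged and np.all(np.isfinite(fit.bse_fe)) and np.all(fit.bse_fe < se_cap):
                    return fit
        return None

    fell_back = False
    fit = _fit(re_formula)
    if fit is not None and re_formula != "1":
        cov = np.asarray(fit.cov_re, dtype=float)
        if np.linalg.cond(cov) > 1e10 or np.any(np.diag(cov) <= 0):
            fit = None  # singular random-effects covariance
    if fit is None and re_formula != "1":
        logger.warning(
            "fit_temporal_lme: singular or non-converged random-slope fit; "
            "falling back to random intercept only"
        )
        warnings.warn("singular random-effects covariance; using intercept-only random effects")
        fit = _fit("1")
        fell_back = True
    if fit is None:
        raise RuntimeError("mixed model did not converge under any optimizer")
    params = _coef_table(fit)
    return AnalysisResult(
        name=f"temporal_lme_{predictor}",
        params=params,
        model=fit,
        extras={"formula": fixed, "re_formula": "1" if fell_back else re_formula,
                "n": int(fit.nobs), "reml": reml,
                "n_users": df["user_id"].nunique(), "fell_back": fell_back},
    )


def break_analysis(metrics: pd.DataFrame) -> AnalysisResult:
    """Break table (users with >=1 break) plus duration-gain Spearman correlations."""
    brk = metrics[metrics["n_breaks"] >= 1]
    if len(brk) == 0:
        return AnalysisResult(name="break_analysis", table=pd.DataFrame(),
                              extras={"n_with_break": 0})
    groups = [brk.loc[brk["bmi_group"] == g] for g in BMI_GROUPS]
    ok = _testable(groups)

    rows = []
    for label, col in [
        ("number of breaks, median (IQR)", "n_breaks"),
        ("break duration (days), median (IQR)", "mean_break_days"),
        ("weight change (kg), median (IQR)", "mean_break_gain_kg"),
        ("weight change (%), median (IQR)", "mean_break_gain_pct"),
    ]:
        row = {"characteristic": label, "all": _median_iqr(brk[col]),
               **{g: _median_iqr(sub[col]) if len(sub) else "" for g, sub in zip(BMI_GROUPS, groups)}}
        if ok:
            stat, p = stats.kruskal(*[sub[col].dropna() for sub in groups if len(sub)])
            row.update({"test": "kruskal", "statistic": stat, "p": p})
        else:
            row.update({"test": "n/a", "statistic": np.nan, "p": np.nan})
        rows.append(row)

    rho = correlate(brk, x="mean_break_days", y="mean_break_gain_kg", method="spearman")
    return AnalysisResult(
        name="break_analysis",
        table=pd.DataFrame(rows),
        extras={"n_with_break": len(brk), "prevalence_pct": 100.0 * len(brk) / len(metrics),
                "spearman": rho.table},
    )
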