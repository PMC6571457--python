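"""Hypothesis-testing layer: heterogeneity versus behaviour and breeding success.

All explanatory variables are standardized to mean 0, SD 1 before fitting, so
estimates are per-SD of colony-mean heterogeneity.  The test statistic follows
the response type: F tests (nested-model ANOVA) for Gaussian linear regressions
and quasi-binomial GLMs, a chi-square likelihood-ratio test for the Gaussian
mixed model of pairwise overlap (focal bird as random intercept, ML fits).
No multiple-testing correction is applied across the response set; reports
carry a note to that effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SeparationError

logger = logging.getLogger(__name__)

MULTIPLE_TESTING_NOTE = (
    "p-values are reported per response without multiple-testing correction")


@dataclass
class RegressionResult:
    """One fitted heterogeneity effect: estimate on the standardized-predictor scale."""

    response: str
    estimate: float
    se: float
    statistic: float
    stat_name: str           # "F" or "chi2"
    df_num: float
    df_den: float            # NaN for chi-square tests
    p: float
    r2: float = np.nan
    family: str = "gaussian"
    note: str = ""

    def summary_row(self) -> dict:
        return {
            "response": self.response, "estimate": self.estimate, "se": self.se,
            "stat": self.statistic, "stat_name": self.stat_name,
            "df_num": self.df_num, "df_den": self.df_den, "p": self.p,
            "r2": self.r2, "family": self.family, "note": self.note,
        }


def standardize_predictor(x) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD); errors on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("predictor has zero variance")
    return (x - x.mean()) / sd


def colony_mean_H(h_table: pd.DataFrame) -> pd.Series:
    """Unweighted mean heterogeneity per colony across years."""
    return h_table.groupby("colony_id")["H"].mean().rename("H_colony_mean")


def _ols_f(y: np.ndarray, z: np.ndarray, response: str, family: str = "gaussian",
           r2: bool = True) -> RegressionResult:
    import statsmodels.api as sm

    x = sm.add_constant(z)
    fit = sm.OLS(y, x).fit()
    reduced = sm.OLS(y, np.ones_like(y)).fit()
    if fit.ssr < 1e-14:  # exact fit: F degenerates to infinity (or 0 if no effect)
        est = float(fit.params[1])
        f = np.inf if abs(est) > 1e-14 else 0.0
        p = 0.0 if f == np.inf else 1.0
        return RegressionResult(response=response, estimate=est, se=float(fit.bse[1]),
                                statistic=f, stat_name="F", df_num=1.0,
                                df_den=float(fit.df_resid), p=p,
                                r2=float(fit.rsquared), family=family)
    f, p, _ = fit.compare_f_test(reduced)
    return RegressionResult(
        response=response, estimate=float(fit.params[1]), se=float(fit.bse[1]),
        statistic=float(f), stat_name="F", df_num=1.0, df_den=float(fit.df_resid),
        p=float(p), r2=float(fit.rsquared) if r2 else np.nan, family=family)


def lm_trip_metrics(cy_table: pd.DataFrame,
                    metrics=("mean_duration_hr", "mean_total_km", "mean_max_km"),
                    h_col: str = "H_colony_mean") -> dict:
    """OLS of log trip metrics on standardized colony-mean heterogeneity.

    One regression per metric over colony-years; metrics are log-transformed
    (they are positive, right-skewed durations and distances), so estimates are
    on the log scale per SD of heterogeneity.
    """
    if len(cy_table) < 3:
        raise ValueError("need at least 3 colony-years")
    z = standardize_predictor(cy_table[h_col].to_numpy())
    out = {}
    for metric in metrics:
        y = cy_table[metric].to_numpy(dtype=float)
        if np.any(y <= 0):
            bad = cy_table.index[y <= 0][0]
            raise ValueError(f"metric {metric!r} non-positive at row {bad}; log undefined")
        out[metric] = _ols_f(np.log(y), z, response=metric)
    return out


def glm_time_budget(bird_table: pd.DataFrame,
                    states=("p_rest", "p_forage", "p_transit"),
                    h_col: str = "H_colony_mean") -> dict:
    """Quasi-binomial (logit link) regressions of per-bird time budgets.

    The dispersion parameter is estimated from the Pearson chi-square of the
    full model, and the heterogeneity effect is tested with the quasi-binomial
    F test: the scaled deviance drop between nested models against
    ``F(1, n - 2)``.
    """
    import statsmodels.api as sm

    z = standardize_predictor(bird_table[h_col].to_numpy())
    x = sm.add_constant(z)
    out = {}
    for state in states:
        y = bird_table[state].to_numpy(dtype=float)
        if np.all(y == 0) or np.all(y == 1):
            raise SeparationError(f"time-budget response {state!r} is degenerate")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.GLM(y, x, family=sm.families.Binomial()).fit()
            reduced = sm.GLM(y, np.ones_like(y), family=sm.families.Binomial()).fit()
        dispersion = full.pearson_chi2 / full.df_resid
        if dispersion <= 0 or (full.deviance == 0 and reduced.deviance == 0):
            f = 0.0
            p = 1.0
        else:
            f = float((reduced.deviance - full.deviance) / dispersion)
            f = max(f, 0.0)
            p = float(sps.f.sf(f, 1, full.df_resid))
        out[state] = RegressionResult(
            response=state, estimate=float(full.params[1]), se=float(full.bse[1]),
            statistic=f, stat_name="F", df_num=1.0, df_den=float(full.df_resid),
            p=p, family="quasi-binomial",
            note=f"dispersion={dispersion:.3f}")
    return out


def lm_core_area(bird_table: pd.DataFrame, area_col: str = "core_area_km2",
                 h_col: str = "H_colony_mean") -> RegressionResult:
    """OLS of per-bird 50% core foraging area on standardized heterogeneity."""
    z = standardize_predictor(bird_table[h_col].to_numpy())
    y = bird_table[area_col].to_numpy(dtype=float)
    res = _ols_f(y, z, response="core_area_km2")
    return res


def lmm_overlap(overlap_table: pd.DataFrame, h_col: str = "H_colony_mean",
                ba_col: str = "ba", focal_col: str = "focal") -> RegressionResult:
    """Gaussian mixed model of pairwise overlap with a focal-bird random intercept.

    Fitted by maximum likelihood; the heterogeneity effect is tested with a
    chi-square likelihood-ratio test against the nested intercept-only model.
    If the random-intercept variance is singular (or the fit fails), the model
    falls back to OLS with a warning recorded in the result's note.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    n_focal = overlap_table[focal_col].nunique()
    per_focal = overlap_table.groupby(focal_col).size()
    if n_focal < 2 or (per_focal >= 2).sum() < 2:
        raise ValueError("need at least 2 focal birds with at least 2 records")
    z = standardize_predictor(overlap_table[h_col].to_numpy())
    y = overlap_table[ba_col].to_numpy(dtype=float)
    groups = overlap_table[focal_col].to_numpy()
    x = sm.add_constant(z)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = MixedLM(y, x, groups=groups).fit(reml=False)
            reduced = MixedLM(y, np.ones_like(y), groups=groups).fit(reml=False)
        re_var = float(np.asarray(full.cov_re)[0, 0])
        singular = not np.isfinite(re_var) or re_var < 1e-10
        chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
        if not singular:
            return RegressionResult(
                response="ba_overlap", estimate=float(full.fe_params[1]),
                se=float(full.bse_fe[1]), statistic=float(chi2), stat_name="chi2",
                df_num=1.0, df_den=np.nan, p=float(sps.chi2.sf(chi2, 1)),
                family="gaussian-lmm",
                note=f"random-intercept SD={np.sqrt(re_var):.4f}")
        logger.warning("singular random-intercept variance; falling back to OLS")
    except Exception as exc:
        logger.warning("mixed model failed (%s); falling back to OLS", exc)
    res = _ols_f(y, z, response="ba_overlap")
    res.note = "OLS fallback (singular or failed mixed model)"
    return res


@dataclass
class BreedingSuccessResult:
    regression: RegressionResult
    percent_decline: float
    leave_one_out: pd.DataFrame | None = None


def lm_breeding_success(success_table: pd.DataFrame, h_col: str = "H_colony_mean",
                        success_col: str = "success",
                        leave_one_out: bool = False) -> BreedingSuccessResult:
    """OLS of colony-year breeding success on standardized heterogeneity.

    Also reports the percent decline in fitted success across the observed
    heterogeneity range, ``(yhat(min H) - yhat(max H)) / yhat(min H) * 100``
    (undefined and flagged when the fitted value at minimum heterogeneity is
    non-positive), and optionally refits leaving out one colony at a time.
    """
    if len(success_table) < 3:
        raise ValueError("need at least 3 colony-years of breeding success")
    z = standardize_predictor(success_table[h_col].to_numpy())
    y = success_table[success_col].to_numpy(dtype=float)
    reg = _ols_f(y, z, response="breeding_success")
    intercept = y.mean()  # z is centred, so the OLS intercept is the response mean
    yhat_min = intercept + reg.estimate * z.min()
    yhat_max = intercept + reg.estimate * z.max()
    if abs(reg.estimate) < 1e-14:
        decline = 0.0
    elif yhat_min <= 0:
        decline = np.nan
        reg.note = (reg.note + "; " if reg.note else "") + \
            "percent decline undefined (fitted success non-positive at minimum H)"
    else:
        decline = (yhat_min - yhat_max) / yhat_min * 100.0
    loo = None
    if leave_one_out:
        rows = []
        for colony in success_table["colony_id"].unique():
            sub = success_table[success_table["colony_id"] != colony]
            if len(sub) < 3 or sub[h_col].nunique() < 2:
                continue
            sub_res = lm_breeding_success(sub, h_col=h_col, success_col=success_col)
            rows.append({"left_out": colony, "estimate": sub_res.regression.estimate,
                         "p": sub_res.regression.p})
        loo = pd.DataFrame(rows)
    return BreedingSuccessResult(regression=reg, percent_decline=float(decline)
                                 if not np.isnan(decline) else np.nan,
                                 leave_one_out=loo)


@dataclass
class ConfoundScreen:
    results: list = field(default_factory=list)
    any_significant: bool = False
    alpha: float = 0.05


def confound_screen(success_table: pd.DataFrame | None = None,
                    colony_covariates: pd.DataFrame | None = None,
                    metric_means: pd.DataFrame | None = None,
                    h_col: str = "H_colony_mean", alpha: float = 0.05) -> ConfoundScreen:
    """Screen candidate confounds of the heterogeneity-success relationship.

    One OLS per candidate: breeding success against each colony covariate
    (colony size, breeders within radius, ...), and heterogeneity against each
    single-metric environmental mean.  An empty input yields an empty screen.
    """
    results = []
    if success_table is not None and colony_covariates is not None:
        merged = success_table.merge(colony_covariates, on="colony_id")
        for col in colony_covariates.columns:
            if col == "colony_id":
                continue
            z = standardize_predictor(merged[col].to_numpy())
            res = _ols_f(merged["success"].to_numpy(dtype=float), z,
                         response=f"success~{col}")
            results.append(res)
    if metric_means is not None:
        value_cols = [c for c in metric_means.columns
                      if c not in (h_col, "colony_id", "year")]
        for col in value_cols:
            z = standardize_predictor(metric_means[col].to_numpy())
            res = _ols_f(metric_means[h_col].to_numpy(dtype=float), z,
                         response=f"H~{col}")
            results.append(res)
    any_sig = any(r.p < alpha for r in results)
    if any_sig:
        logger.warning("confound screen: at least one candidate significant at alpha=%.2f",
                       alpha)
    return ConfoundScreen(results=results, any_significant=any_sig, alpha=alpha)


def results_table(results: dict) -> pd.DataFrame:
    """Flatten a mapping of RegressionResult into one summary DataFrame."""
    rows = [r.summary_row() for r in results.values()]
    df = pd.DataFrame(rows)
    df.attrs["note"] = MULTIPLE_TESTING_NOTE
    return df
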