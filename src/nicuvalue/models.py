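"""Risk adjustment: mixed models, ICC, and indirect standardization.

Two patient-level models with a random hospital intercept quantify how
much of resource use is explained by patients versus hospitals:

* a logistic model for the odds of a resource-intensive stay (reported
  as odds ratios against reference demographic levels), and
* a linear model on log-transformed total CTT cost, whose variance
  components give the intraclass correlation
  ``ICC = sigma_h^2 / (sigma_h^2 + sigma_e^2)`` — the share of
  covariate-adjusted cost variation attributable to hospitals.

Hospital-level "adjusted" exposure proportions and mean costs come from
indirect standardization: expected outcomes under a pooled
fixed-effects-only model, then ``adjusted = (observed / expected) x
pooled mean``.  With an intercept-only model this reduces to the
observed value, so the adjustment is testable against a null generator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

logger = logging.getLogger("nicuvalue")

__all__ = [
    "RiskModelResult",
    "DEMOGRAPHIC_COVARIATES",
    "REFERENCE_LEVELS",
    "fit_resource_intensity_model",
    "fit_cost_model",
    "compute_icc",
    "adjusted_hospital_rates",
]

#: Demographic covariates entering the risk models (plus the NICU-SOI score).
DEMOGRAPHIC_COVARIATES = [
    "sex",
    "ga_category",
    "bw_category",
    "race_ethnicity",
    "admission_source",
    "age_at_admission_days",
    "insurance",
    "income_quartile",
    "disposition",
]

#: Reference level of each categorical covariate.
REFERENCE_LEVELS = {
    "sex": "female",
    "ga_category": ">31",
    "bw_category": ">1499",
    "race_ethnicity": "non_hispanic_white",
    "admission_source": "inborn",
    "age_at_admission_days": 0,
    "insurance": "commercial",
    "income_quartile": 4,
    "disposition": "home",
}


@dataclass
class RiskModelResult:
    """Fixed effects with 95% intervals plus variance components.

    ``params`` has columns term/estimate/ci_low/ci_high on the scale named
    by ``scale`` ("odds_ratio" or "coefficient").
    """

    params: pd.DataFrame
    scale: str
    sigma_h2: float
    sigma_e2: float
    reference_levels: dict

    @property
    def icc(self) -> float:
        return compute_icc(self.sigma_h2, self.sigma_e2)


def compute_icc(sigma_h2: float, sigma_e2: float) -> float:
    """Share of total variance attributable to between-hospital variation."""
    if sigma_h2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_h2 + sigma_e2
    return float(sigma_h2 / total) if total > 0 else 0.0


def _covariate_terms(df: pd.DataFrame, covariates: list[str]) -> list[str]:
    """Patsy terms for covariates, skipping those with < 2 observed levels."""
    terms = []
    for col in covariates:
        if col not in df.columns or df[col].nunique() < 2:
            continue
        if col == "nicu_soi" or pd.api.types.is_float_dtype(df[col]):
            terms.append(col)
            continue
        ref = REFERENCE_LEVELS.get(col)
        if ref is not None and ref in set(df[col]):
            terms.append(f"C({col}, Treatment({ref!r}))")
        else:
            terms.append(f"C({col})")
    return terms


def _formula(outcome: str, df: pd.DataFrame, covariates: list[str]) -> str:
    terms = _covariate_terms(df, covariates)
    rhs = " + ".join(terms) if terms else "1"
    return f"{outcome} ~ {rhs}"


def fit_resource_intensity_model(
    cohort: pd.DataFrame,
    outcome: str = "resource_intensive",
    covariates: list[str] | None = None,
    include_soi: bool = True,
) -> RiskModelResult:
    """Random-intercept logistic model for resource-intensive stays.

    Fit by variational Bayes (posterior means/SDs); odds ratios are
    ``exp(mean +/- 1.96 SD)`` against the reference levels.  Single-class
    outcomes or non-convergence raise diagnostic errors; single-hospital
    data falls back to a plain logistic fit with sigma_h^2 at the zero
    boundary (warned).
    """
    covs = list(covariates) if covariates is not None else list(
        DEMOGRAPHIC_COVARIATES)
    if include_soi and "nicu_soi" in cohort.columns and "nicu_soi" not in covs:
        covs.append("nicu_soi")
    y = cohort[outcome].astype(int)
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has a single class; "
                         "logistic model is not identifiable")
    df = cohort.assign(_y=y)
    formula = _formula("_y", df, covs)

    if df["hospital_id"].nunique() < 2:
        logger.warning("single hospital in data; hospital-effect variance "
                       "reported at the 0 boundary")
        fit = smf.glm(formula, data=df, family=sm.families.Binomial()).fit()
        est, lo, hi = fit.params, fit.conf_int()[0], fit.conf_int()[1]
        sigma_h2 = 0.0
    else:
        model = BinomialBayesMixedGLM.from_formula(
            formula, {"hospital": "0 + C(hospital_id)"}, df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit_vb()
        names = model.exog_names
        est = pd.Series(fit.fe_mean, index=names)
        lo = est - 1.96 * pd.Series(fit.fe_sd, index=names)
        hi = est + 1.96 * pd.Series(fit.fe_sd, index=names)
        if not np.all(np.isfinite(fit.fe_mean)):
            raise RuntimeError(
                "logistic mixed model produced non-finite estimates "
                "(possible separation); inspect covariates")
        # vcp_mean holds log-SD of the hospital random intercept
        sigma_h2 = float(np.exp(2.0 * fit.vcp_mean[0]))

    params = pd.DataFrame({
        "term": est.index,
        "estimate": np.exp(est.to_numpy()),
        "ci_low": np.exp(np.asarray(lo)),
        "ci_high": np.exp(np.asarray(hi)),
    })
    return RiskModelResult(params=params, scale="odds_ratio",
                           sigma_h2=sigma_h2,
                           sigma_e2=float(np.pi ** 2 / 3),
                           reference_levels=dict(REFERENCE_LEVELS))


def fit_cost_model(
    cohort: pd.DataFrame,
    cost_col: str = "total_ctt_cost",
    covariates: list[str] | None = None,
    include_soi: bool = True,
) -> RiskModelResult:
    """Linear mixed model on log(cost + 1) with a random hospital intercept.

    The +1 offset admits zero-cost stays; the additive log scale is what
    makes the hospital/residual variance split (hence the ICC)
    interpretable.
    """
    covs = list(covariates) if covariates is not None else list(
        DEMOGRAPHIC_COVARIATES)
    if include_soi and "nicu_soi" in cohort.columns and "nicu_soi" not in covs:
        covs.append("nicu_soi")
    df = cohort.assign(_logcost=np.log1p(cohort[cost_col].astype(float)))
    formula = _formula("_logcost", df, covs)

    if df["hospital_id"].nunique() < 2:
        logger.warning("single hospital in data; hospital-effect variance "
                       "reported at the 0 boundary")
        fit = smf.ols(formula, data=df).fit()
        sigma_h2, sigma_e2 = 0.0, float(fit.mse_resid)
        est, lo, hi = fit.params, fit.conf_int()[0], fit.conf_int()[1]
    else:
        model = smf.mixedlm(formula, data=df, groups=df["hospital_id"])
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (None, "lbfgs", "powell"):
                try:
                    kwargs = {} if method is None else {"method": method}
                    candidate = model.fit(reml=True, **kwargs)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if candidate.converged:
                    fit = candidate
                    break
        if fit is None:
            raise RuntimeError("linear mixed model did not converge; "
                               "inspect covariates and sample size")
        sigma_h2 = float(fit.cov_re.iloc[0, 0])
        sigma_e2 = float(fit.scale)
        ci = fit.conf_int()
        fe = [t for t in fit.params.index if t != "Group Var"]
        est, lo, hi = fit.params[fe], ci.loc[fe, 0], ci.loc[fe, 1]

    params = pd.DataFrame({
        "term": est.index,
        "estimate": est.to_numpy(dtype=float),
        "ci_low": np.asarray(lo, dtype=float),
        "ci_high": np.asarray(hi, dtype=float),
    })
    return RiskModelResult(params=params, scale="coefficient",
                           sigma_h2=sigma_h2, sigma_e2=sigma_e2,
                           reference_levels=dict(REFERENCE_LEVELS))


def adjusted_hospital_rates(
    df: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    binary: bool | None = None,
) -> pd.DataFrame:
    """Indirectly standardized hospital-level means of ``outcome``.

    A pooled fixed-effects-only model (logistic for binary outcomes,
    linear otherwise) supplies each patient's expected outcome; per
    hospital, ``adjusted = observed_sum / expected_sum x pooled mean``.
    Hospitals with zero expected outcome are dropped with a warning.
    With no covariates (or a constant outcome) the adjusted value equals
    the observed hospital mean.
    """
    y = df[outcome].astype(float)
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    covs = [c for c in (covariates or []) if c in df.columns]
    pooled_mean = float(y.mean())

    if not covs or y.nunique() < 2:
        expected = np.full(len(df), pooled_mean)
    else:
        work = df.assign(_y=y)
        formula = _formula("_y", work, covs)
        family = sm.families.Binomial() if binary else sm.families.Gaussian()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.glm(formula, data=work, family=family).fit()
            expected = np.asarray(fit.fittedvalues)

    g = pd.DataFrame({
        "hospital_id": df["hospital_id"].to_numpy(),
        "_obs": y.to_numpy(),
        "_exp": expected,
    }).groupby("hospital_id", sort=True).agg(
        n=("_obs", "size"), observed=("_obs", "sum"), expected=("_exp", "sum"))
    zero = np.isclose(g["expected"], 0.0, atol=1e-8)
    if zero.any():
        logger.warning("dropping hospital(s) with zero expected outcome: %s",
                       list(g.index[zero]))
        g = g[~zero]
    out = pd.DataFrame({
        "hospital_id": g.index,
        "n": g["n"].to_numpy(),
        "observed_mean": (g["observed"] / g["n"]).to_numpy(),
        "expected_mean": (g["expected"] / g["n"]).to_numpy(),
        "oe_ratio": (g["observed"] / g["expected"]).to_numpy(),
        "adjusted": (g["observed"] / g["expected"] * pooled_mean).to_numpy(),
    }).reset_index(drop=True)
    return out
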