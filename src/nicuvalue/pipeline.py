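"""End-to-end pipeline: simulate -> cohort -> cost -> adjust -> score.

Each stage reads and writes documented CSV artifacts in a working
directory, so stages can be re-run independently and every artifact is
reproducible from (inputs, config, seed).  The stage functions are thin
orchestration over the library modules; use those directly for anything
programmatic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import costing, io, models, variability
from .cohort import CohortConfig, apply_exclusions, restrict_to_nicu_days
from .severity import compute_nicu_soi
from .simulate import SimConfig, default_ctt_map, generate

logger = logging.getLogger("nicuvalue")

__all__ = [
    "RunConfig",
    "stage_simulate",
    "stage_build_cohort",
    "stage_cost",
    "stage_adjust",
    "stage_score",
    "run_all",
]


class RunConfig(BaseModel):
    """Pipeline constants; defaults are the framework's published choices."""

    workdir: str = "."
    seed: int = 0
    sim: SimConfig = Field(default_factory=SimConfig)
    min_hospital_volume: int = 100
    resource_intensive_quantile: float = 0.90
    billing_pattern_upper: float = 4.0
    billing_pattern_lower: float = 0.25
    winsor_lower_pct: float = 5.0
    winsor_upper_pct: float = 95.0
    anomaly_codes: list[str] | None = None
    max_los_days: int = 400
    fit_risk_models: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(min_hospital_volume=self.min_hospital_volume,
                      max_los_days=self.max_los_days)
        if self.anomaly_codes is not None:
            kwargs["anomaly_codes"] = frozenset(self.anomaly_codes)
        return CohortConfig(**kwargs)


def _dir(cfg: RunConfig) -> Path:
    d = Path(cfg.workdir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(cfg: RunConfig) -> None:
    """Generate encounters.csv, billing.csv, ctt_map.csv, ground_truth.json."""
    d = _dir(cfg)
    sim = cfg.sim.model_copy(update={"seed": cfg.seed})
    encounters, billing, truth = generate(sim)
    io.write_encounters(encounters, d / "encounters.csv")
    io.write_billing(billing, d / "billing.csv")
    io.write_ctt_map(default_ctt_map(sim), d / "ctt_map.csv")
    truth.to_json(d / "ground_truth.json")
    logger.info("simulated %d encounters, %d billing lines at %d hospitals "
                "(seed %d)", len(encounters), len(billing), sim.n_hospitals,
                cfg.seed)


def stage_build_cohort(cfg: RunConfig) -> None:
    """Apply the exclusion cascade: cohort.csv, exclusion_log.csv."""
    d = _dir(cfg)
    encounters = io.read_encounters(d / "encounters.csv")
    cohort, log = apply_exclusions(encounters, cfg.cohort_config())
    io.write_encounters(cohort, d / "cohort.csv")
    log.to_frame().to_csv(d / "exclusion_log.csv", index=False)
    logger.info("cohort: %d of %d encounters retained across %d hospitals",
                len(cohort), len(encounters), cohort["hospital_id"].nunique())


def stage_cost(cfg: RunConfig) -> None:
    """Standardize costs and aggregate: cost_index.csv,
    encounter_ctt_costs.csv, category_totals.csv, resource_flags.csv."""
    d = _dir(cfg)
    encounters = io.read_encounters(d / "encounters.csv")
    cohort = io.read_encounters(d / "cohort.csv")
    ctt_map = io.read_ctt_map(d / "ctt_map.csv")
    wage = d / "wage_index.csv"
    infl = d / "inflation_index.csv"
    tables = io.read_index_tables(wage if wage.exists() else None,
                                  infl if infl.exists() else None)
    billing = io.read_billing(d / "billing.csv", ctt_map, encounters)
    nicu = restrict_to_nicu_days(billing)
    index = costing.build_cost_index(nicu, encounters, tables)
    index.rename_axis("billing_item").reset_index().to_csv(
        d / "cost_index.csv", index=False)
    costed = costing.standardize_costs(nicu, index, tables)
    enc_costs, totals = costing.aggregate_ctt(costed, cohort)
    enc_costs.to_csv(d / "encounter_ctt_costs.csv", index=False)
    totals.to_csv(d / "category_totals.csv", index=False)
    per_enc = (enc_costs.groupby("encounter_id")["cost"].sum()
               .rename("total_ctt_cost").reset_index())
    flags = costing.flag_resource_intensive(
        per_enc, cfg.resource_intensive_quantile)
    flags.to_csv(d / "resource_flags.csv", index=False)
    logger.info("costed %d NICU-day lines; %d resource-intensive stays",
                len(costed), int(flags["resource_intensive"].sum()))


def _scored_cohort(d: Path, cfg: RunConfig) -> pd.DataFrame:
    """Cohort with NICU-SOI, total cost, and resource-intensity flag."""
    encounters = io.read_encounters(d / "encounters.csv")
    cohort = io.read_encounters(d / "cohort.csv")
    sev = compute_nicu_soi(encounters, cfg.winsor_lower_pct,
                           cfg.winsor_upper_pct)
    sev.to_frame().to_csv(d / "severity_table.csv", index=False)
    cohort = cohort.assign(nicu_soi=sev.score(cohort).to_numpy())
    flags = pd.read_csv(d / "resource_flags.csv",
                        dtype={"encounter_id": str})
    return cohort.merge(flags, on="encounter_id", how="left")


def stage_adjust(cfg: RunConfig) -> None:
    """Severity score, risk models, and adjusted hospital estimates."""
    d = _dir(cfg)
    cohort = _scored_cohort(d, cfg)
    covs = models.DEMOGRAPHIC_COVARIATES + ["nicu_soi"]

    if cfg.fit_risk_models:
        rows = []
        ri = models.fit_resource_intensity_model(cohort)
        rows.append(ri.params.assign(model="resource_intensive",
                                     scale=ri.scale))
        cm = models.fit_cost_model(cohort)
        rows.append(cm.params.assign(model="log_total_cost", scale=cm.scale))
        rows.append(pd.DataFrame({
            "term": ["sigma_h2", "sigma_e2", "icc"],
            "estimate": [cm.sigma_h2, cm.sigma_e2, cm.icc],
            "ci_low": np.nan, "ci_high": np.nan,
            "model": "log_total_cost", "scale": "variance"}))
        pd.concat(rows, ignore_index=True).to_csv(
            d / "risk_model_summary.csv", index=False)
        logger.info("cost-model ICC = %.3f", cm.icc)

    enc_costs = pd.read_csv(d / "encounter_ctt_costs.csv",
                            dtype={"encounter_id": str})
    frames = []
    for cat, g in enc_costs.groupby("ctt_category", sort=True):
        merged = cohort.merge(g, on="encounter_id", how="inner")
        adj_exp = models.adjusted_hospital_rates(
            merged, "exposed", covariates=covs)
        frames.append(adj_exp.assign(ctt_category=cat, quantity="exposure"))
        exposed = merged[merged["exposed"]]
        if exposed["hospital_id"].nunique() >= 2:
            adj_cost = models.adjusted_hospital_rates(
                exposed, "cost", covariates=covs, binary=False)
            frames.append(adj_cost.assign(ctt_category=cat, quantity="cost"))
    pd.concat(frames, ignore_index=True).to_csv(
        d / "adjusted_hospital_estimates.csv", index=False)


def stage_score(cfg: RunConfig) -> None:
    """Variability statistics, prioritization, and report exports."""
    d = _dir(cfg)
    cohort = io.read_encounters(d / "cohort.csv")
    totals = pd.read_csv(d / "category_totals.csv")
    adj = pd.read_csv(d / "adjusted_hospital_estimates.csv",
                      dtype={"hospital_id": str})
    enc_costs = pd.read_csv(d / "encounter_ctt_costs.csv",
                            dtype={"encounter_id": str})

    sizes = cohort["hospital_id"].value_counts().sort_index()
    hosp_exp = {c: g[["hospital_id", "adjusted"]]
                for c, g in adj[adj["quantity"] == "exposure"]
                .groupby("ctt_category")}
    hosp_cost = {c: g.set_index("hospital_id")["adjusted"]
                 for c, g in adj[adj["quantity"] == "cost"]
                 .groupby("ctt_category")}
    rates = totals.set_index("ctt_category")["pct_exposed"] / 100.0
    summary = variability.summarize_categories(
        totals, hosp_exp, hosp_cost, sizes, rates,
        cfg.billing_pattern_upper, cfg.billing_pattern_lower)
    # hospital-level descriptive spread columns (report analog)
    med_rows = []
    for cat in summary["ctt_category"]:
        prop = hosp_exp[cat].set_index("hospital_id")["adjusted"]
        cost = hosp_cost.get(cat, pd.Series(dtype=float))
        med_rows.append({
            "ctt_category": cat,
            "median_hospital_exposure_pct": 100 * prop.median(),
            "q1_hospital_exposure_pct": 100 * prop.quantile(0.25),
            "q3_hospital_exposure_pct": 100 * prop.quantile(0.75),
            "median_hospital_cost_per_exposed": cost.median(),
            "q1_hospital_cost_per_exposed": cost.quantile(0.25),
            "q3_hospital_cost_per_exposed": cost.quantile(0.75),
        })
    summary = summary.merge(pd.DataFrame(med_rows), on="ctt_category")
    summary.round(6).to_csv(d / "ctt_summary.csv", index=False)
    summary[["ctt_category", "exposure_variability",
             "utilization_variability"]].round(6).to_csv(
        d / "variability.csv", index=False)
    summary[["ctt_category", "total_cost", "variability_index",
             "pct_exposed"]].round(6).to_csv(d / "bubble_chart.csv",
                                             index=False)

    # hospital outlier report on additively adjusted patient-level costs
    cohort_cov = _scored_cohort(d, cfg)
    billing_groups = _category_groups(d)
    per_pat = enc_costs.merge(
        cohort_cov[["encounter_id", "hospital_id"] +
                   models.DEMOGRAPHIC_COVARIATES + ["nicu_soi"]],
        on="encounter_id")
    per_pat["billing_group"] = per_pat["ctt_category"].map(billing_groups)
    frames = [_adjusted_patient_costs(per_pat, "total")]
    for grp, g in per_pat.groupby("billing_group", sort=True):
        frames.append(_adjusted_patient_costs(g, str(grp)))
    pd.concat(frames, ignore_index=True).round(6).to_csv(
        d / "hospital_outliers.csv", index=False)
    logger.info("scored %d categories", len(summary))


def _category_groups(d: Path) -> dict[str, str]:
    m = io.read_ctt_map(d / "ctt_map.csv")
    return {cat: m.group[item] for item, cat in m.category.items()}


def _adjusted_patient_costs(per_pat: pd.DataFrame, label: str) -> pd.DataFrame:
    """Outlier report for one billing group (or the total)."""
    covs = models.DEMOGRAPHIC_COVARIATES + ["nicu_soi"]
    pat = (per_pat.groupby(["encounter_id", "hospital_id"] + covs,
                           as_index=False)["cost"].sum())
    # additive patient-level adjustment keeps the distribution shape for
    # median/quartile comparison
    import warnings

    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    terms = models._covariate_terms(pat, covs)
    if terms:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.glm("cost ~ " + " + ".join(terms), data=pat,
                          family=sm.families.Gaussian()).fit()
        expected = np.asarray(fit.fittedvalues)
    else:
        expected = np.full(len(pat), pat["cost"].mean())
    pat = pat.assign(
        adjusted_cost=pat["cost"] - expected + pat["cost"].mean())
    rep = variability.detect_outlier_hospitals(
        pat.rename(columns={"adjusted_cost": "cost_adj"}),
        cost_col="cost_adj")
    rep["group"] = label
    return rep


_STAGES = [stage_simulate, stage_build_cohort, stage_cost, stage_adjust,
           stage_score]


def run_all(cfg: RunConfig) -> None:
    """Chain every stage in order in the configured working directory."""
    for stage in _STAGES:
        stage(cfg)
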