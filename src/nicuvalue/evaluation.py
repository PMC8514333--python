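"""Recovery experiments on simulated systems.

Convenience wrappers that run the analysis chain in memory on generated
data — label billing, restrict to NICU days, build the cost index,
standardize, aggregate — and then measure how well the estimators recover
the generator's planted parameters (ICC, exposure and utilization
variability).  Scenario configurations here deliberately switch off the
exclusion-cascade nuisances (anomalies, late admissions, data errors) so
the planted values are the only signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import costing
from .cohort import restrict_to_nicu_days
from .io import label_billing
from .models import adjusted_hospital_rates, fit_cost_model
from .simulate import DEFAULT_CATEGORIES, GroundTruth, SimConfig, default_ctt_map, generate
from .variability import exposure_variability, utilization_variability

__all__ = [
    "simulate_costed",
    "recover_icc",
    "observed_category_stats",
    "variability_scenario",
]


def simulate_costed(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a system and return standardized per-encounter CTT costs.

    Returns ``(encounters, encounter_costs, truth)`` where
    ``encounter_costs`` has one row per encounter x category with
    standardized cost, exposure flag and exposed-day count (all
    encounters; no exclusion cascade).
    """
    encounters, billing, truth = generate(config)
    billing = label_billing(billing, default_ctt_map(config))
    nicu = restrict_to_nicu_days(billing)
    index = costing.build_cost_index(nicu, encounters)
    costed = costing.standardize_costs(nicu, index)
    enc_costs, _ = costing.aggregate_ctt(costed, encounters)
    return encounters, enc_costs, truth


def recover_icc(config: SimConfig, covariates: list[str] | None = None) -> float:
    """Fitted ICC of log total CTT cost on one generated system."""
    encounters, enc_costs, _ = simulate_costed(config)
    per = (enc_costs.groupby("encounter_id")["cost"].sum()
           .rename("total_ctt_cost").reset_index())
    df = encounters.merge(per, on="encounter_id")
    result = fit_cost_model(df, covariates=covariates or [], include_soi=False)
    return result.icc


def observed_category_stats(
    encounters: pd.DataFrame, enc_costs: pd.DataFrame
) -> pd.DataFrame:
    """Per-category EV and UV with intercept-only (observed) adjustment."""
    merged = enc_costs.merge(encounters[["encounter_id", "hospital_id"]],
                             on="encounter_id")
    sizes = encounters["hospital_id"].value_counts().sort_index()
    rows = []
    for cat, g in merged.groupby("ctt_category", sort=True):
        adj = adjusted_hospital_rates(
            g.assign(exposed=g["exposed"].astype(float)), "exposed")
        prop = adj.set_index("hospital_id")["adjusted"]
        ev = exposure_variability(prop, sizes, float(g["exposed"].mean()))
        mean_costs = (g[g["exposed"]].groupby("hospital_id")["cost"].mean())
        uv = utilization_variability(mean_costs)
        rows.append((cat, ev, uv))
    return pd.DataFrame(rows, columns=["ctt_category", "exposure_variability",
                                       "utilization_variability"])


def variability_scenario(
    seed: int,
    exposure_re_sd: float,
    utilization_re_sd: float,
    n_hospitals: int = 40,
    patients_per_hospital: int = 650,
) -> SimConfig:
    """Scenario config with uniform planted tau/omega across categories.

    Billing-day density is thinned (statistics are day-count invariant)
    and cascade nuisances disabled.
    """
    cats = {name: p.model_copy(update={
        "exposure_re_sd": exposure_re_sd,
        "utilization_re_sd": utilization_re_sd,
        "day_rate": 0.05,
    }) for name, p in DEFAULT_CATEGORIES.items()}
    return SimConfig(
        n_hospitals=n_hospitals, patients_per_hospital=patients_per_hospital,
        seed=seed, categories=cats, cost_icc_target=0.0,
        anomaly_rate=0.0, late_admission_rate=0.0, previable_rate=0.0,
        data_error_rate=0.0, non_nicu_day_rate=0.0, code_only_rate=0.0)
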