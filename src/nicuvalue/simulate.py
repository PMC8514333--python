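"""Synthetic multi-hospital NICU claims generator with planted ground truth.

The generator emulates the statistical structure of an administrative
children's-hospital claims extract: ~40 hospitals, hundreds of NICU stays
per hospital, and for each clinician-driven test/treatment (CTT) category

* patient *exposure* drawn Bernoulli on the logit scale with a hospital
  random intercept (SD ``exposure_re_sd``),
* for exposed patients a log-normal *true cost* with a per-category
  hospital multiplicative effect (SD ``utilization_re_sd``), a hospital
  log-cost effect shared across categories that plants a target
  intraclass correlation in log total cost, and a patient-level
  log-normal factor shared across categories,
* billing lines that spread each patient-category cost across random NICU
  days, with hospital-specific multiplicative charge markups separating
  *charges* from *true costs*.

Every random-effect draw is recorded in :class:`GroundTruth`, so each
downstream statistic (exposure variability, utilization variability, ICC)
has a recoverable planted value.  One RNG stream per hospital is derived
from the master seed, so output is reproducible independent of iteration
order; a fixed seed yields byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .io import CTTMap
from .schemas import bw_category, ga_category

__all__ = [
    "CategoryParams",
    "SimConfig",
    "GroundTruth",
    "plant_cost_icc",
    "generate",
    "default_ctt_map",
    "DEFAULT_CATEGORIES",
]

#: Anomaly diagnosis codes the generator plants (and the cohort stage
#: excludes by default).  Synthetic stand-ins, not a curated clinical list.
PLANTED_ANOMALY_CODES = ("Q24.8", "Q24.9", "Q33.0", "Q61.9")
#: Codes marking VLBW/VP status when discrete GA/BW fields are blanked.
PLANTED_VLBW_VP_CODES = ("P07.0", "P07.1", "P07.2", "P07.3")
#: Filler diagnosis codes common in preterm stays.
_FILLER_CODES = ("P22.0", "P27.1", "P59.9", "P05.1", "H35.1")

# Approximate mean/SD of birth weight (g) by gestational week, used both to
# simulate BW given GA and by the default data-error screen downstream.
BW_BY_GA = {
    20: (380, 70), 21: (440, 80), 22: (500, 90), 23: (580, 100), 24: (660, 110),
    25: (750, 120), 26: (850, 140), 27: (980, 160), 28: (1100, 180),
    29: (1250, 200), 30: (1400, 220), 31: (1600, 250), 32: (1800, 280),
    33: (2000, 300), 34: (2250, 330), 35: (2500, 360), 36: (2750, 390),
    37: (3300, 450), 38: (3400, 450), 39: (3500, 450), 40: (3550, 450),
    41: (3600, 450), 42: (3600, 450), 43: (3600, 450), 44: (3600, 450),
    45: (3600, 450),
}

# Demographic marginals mirroring a published 40-hospital VLBW/VP cohort.
TABLE1_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.516, "female": 0.483, "unknown": 0.001},
    "ga_bin": {
        "22": 0.006, "23-24": 0.106, "25-26": 0.153, "27-28": 0.202,
        "29-30": 0.266, "31": 0.179, ">31": 0.064, "unknown": 0.024,
    },
    "race_ethnicity": {
        "non_hispanic_white": 0.428, "non_hispanic_black": 0.235,
        "hispanic": 0.159, "asian": 0.033, "other": 0.145,
    },
    "admission_source": {"inborn": 0.291, "outborn": 0.631, "other": 0.078},
    "insurance": {
        "commercial": 0.371, "government": 0.599, "self_pay": 0.011,
        "other": 0.019,
    },
    "income_quartile": {"1": 0.287, "2": 0.262, "3": 0.229, "4": 0.200},
    "disposition": {"home": 0.724, "transfer": 0.178, "mortality": 0.090,
                    "other": 0.008},
    "age_at_admission": {"0": 0.953, "1": 0.047},
}


class CategoryParams(BaseModel):
    """Planted parameters for one simulated CTT category."""

    billing_group: str
    base_exposure_logit: float
    exposure_re_sd: float = Field(ge=0)
    mean_cost_exposed: float = Field(gt=0)
    utilization_re_sd: float = Field(ge=0)
    #: probability that each NICU day beyond the first carries a charge line
    day_rate: float = Field(default=0.2, ge=0, le=1)
    n_items: int = Field(default=3, ge=1)


#: Default simulated categories: scales chosen to resemble the cost and
#: exposure profile of common NICU tests and treatments.
DEFAULT_CATEGORIES: dict[str, CategoryParams] = {
    "parenteral_nutrition": CategoryParams(
        billing_group="pharmaceutical", base_exposure_logit=2.2,
        exposure_re_sd=0.35, mean_cost_exposed=2500.0,
        utilization_re_sd=0.45, day_rate=0.30),
    "hematology": CategoryParams(
        billing_group="laboratory", base_exposure_logit=2.8,
        exposure_re_sd=0.30, mean_cost_exposed=300.0,
        utilization_re_sd=0.35, day_rate=0.25),
    "chemistries": CategoryParams(
        billing_group="laboratory", base_exposure_logit=2.9,
        exposure_re_sd=0.25, mean_cost_exposed=1000.0,
        utilization_re_sd=0.30, day_rate=0.30),
    "chest_radiographs": CategoryParams(
        billing_group="imaging", base_exposure_logit=1.8,
        exposure_re_sd=0.30, mean_cost_exposed=600.0,
        utilization_re_sd=0.25, day_rate=0.15),
    "antibiotics": CategoryParams(
        billing_group="pharmaceutical", base_exposure_logit=1.5,
        exposure_re_sd=0.40, mean_cost_exposed=150.0,
        utilization_re_sd=0.30, day_rate=0.17),
    "echocardiograms": CategoryParams(
        billing_group="imaging", base_exposure_logit=-0.5,
        exposure_re_sd=0.35, mean_cost_exposed=1400.0,
        utilization_re_sd=0.20, day_rate=0.05),
}


class SimConfig(BaseModel):
    """Full configuration of the synthetic cohort generator.

    Defaults emulate the study conditions of a 40-hospital VLBW/VP cohort:
    650 patients per hospital, six CTT categories, right-skewed costs with
    a planted between-hospital share of log-total-cost variance of 0.277.
    """

    n_hospitals: int = Field(default=40, gt=0)
    patients_per_hospital: int | list[int] = 650
    seed: int = 0
    categories: dict[str, CategoryParams] = Field(
        default_factory=lambda: dict(DEFAULT_CATEGORIES))
    #: spread of a patient-category cost across its charge days (CV of the
    #: day-level shares)
    within_patient_cost_cv: float = Field(default=0.6, gt=0)
    #: SD of the patient-level log-normal cost factor shared across
    #: categories; this is the residual log-total-cost variance sqrt
    patient_cost_log_sd: float = Field(default=0.9, ge=0)
    #: log-scale SD of hospital charge markups over true cost
    charge_markup_sd: float = Field(default=0.25, ge=0)
    #: planted share of between-hospital variance in log total cost
    cost_icc_target: float = Field(default=0.277, ge=0, lt=1)
    demographics: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_MARGINALS.items()})
    anomaly_rate: float = Field(default=0.03, ge=0, le=1)
    late_admission_rate: float = Field(default=0.02, ge=0, le=1)
    previable_rate: float = Field(default=0.01, ge=0, le=1)
    data_error_rate: float = Field(default=0.005, ge=0, le=1)
    #: fraction of encounters with trailing non-NICU (e.g. PICU) days
    non_nicu_day_rate: float = Field(default=0.10, ge=0, le=1)
    #: fraction with discrete GA/BW blanked, VLBW/VP carried by code only
    code_only_rate: float = Field(default=0.02, ge=0, le=1)
    mortality_rate: float = Field(default=0.09, ge=0, le=1)
    #: when True, exposure and cost depend on gestational age (<28 weeks),
    #: so risk adjustment has real work to do; default independent
    confounded: bool = False

    @field_validator("patients_per_hospital")
    @classmethod
    def _positive_counts(cls, v):
        counts = [v] if isinstance(v, int) else list(v)
        if any(c <= 0 for c in counts):
            raise ValueError("patients_per_hospital must be positive")
        return v

    @model_validator(mode="after")
    def _lengths(self):
        if isinstance(self.patients_per_hospital, list):
            if len(self.patients_per_hospital) != self.n_hospitals:
                raise ValueError(
                    "patients_per_hospital list length must equal n_hospitals")
        return self

    def hospital_sizes(self) -> list[int]:
        if isinstance(self.patients_per_hospital, int):
            return [self.patients_per_hospital] * self.n_hospitals
        return list(self.patients_per_hospital)

    def hospital_ids(self) -> list[str]:
        return [f"H{i + 1:02d}" for i in range(self.n_hospitals)]

    @classmethod
    def icc_scenario(cls, seed: int, icc: float = 0.277, n_hospitals: int = 40,
                     patients_per_hospital: int = 650) -> "SimConfig":
        """Configuration for the ICC recovery scenario.

        Exposure is near-universal and the per-category hospital effects
        are zeroed, so the between-hospital share of log-total-cost
        variance equals the planted target exactly.
        """
        cats = {}
        for name, p in DEFAULT_CATEGORIES.items():
            cats[name] = p.model_copy(update={
                "base_exposure_logit": 8.0, "exposure_re_sd": 0.0,
                "utilization_re_sd": 0.0, "day_rate": 0.05})
        return cls(
            n_hospitals=n_hospitals, patients_per_hospital=patients_per_hospital,
            seed=seed, categories=cats, cost_icc_target=icc,
            anomaly_rate=0.0, late_admission_rate=0.0, previable_rate=0.0,
            data_error_rate=0.0, non_nicu_day_rate=0.0, code_only_rate=0.0)


@dataclass
class GroundTruth:
    """Planted parameters and bookkeeping stored alongside generated data.

    All generator distributional choices are synthetic stand-ins for an
    administrative claims source that states none; treat recovered values
    as tests of the estimators, not as reproductions of any real cohort.
    """

    config: dict
    category_params: dict[str, dict]
    expected_exposure: dict[str, float]
    hospital_effects: pd.DataFrame  # hospital_id, category, u (logit), v (log-cost)
    hospital_factors: pd.DataFrame  # hospital_id, a (shared log-cost), markup
    sigma_h2: float
    sigma_e2: float
    icc_target: float
    line_counts: dict[str, int] = dc_field(default_factory=dict)
    charge_nicu: dict[str, float] = dc_field(default_factory=dict)
    charge_other: dict[str, float] = dc_field(default_factory=dict)
    item_unit_costs: dict[str, float] = dc_field(default_factory=dict)
    #: per-encounter planted exposure flags (encounter_id x category)
    exposure: pd.DataFrame | None = None
    #: per-encounter planted true NICU-day cost (encounter_id x category)
    true_cost: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "category_params": self.category_params,
            "expected_exposure": self.expected_exposure,
            "hospital_effects": self.hospital_effects.to_dict(orient="list"),
            "hospital_factors": self.hospital_factors.to_dict(orient="list"),
            "sigma_h2": self.sigma_h2,
            "sigma_e2": self.sigma_e2,
            "icc_target": self.icc_target,
            "line_counts": self.line_counts,
            "charge_nicu": self.charge_nicu,
            "charge_other": self.charge_other,
            "item_unit_costs": self.item_unit_costs,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _hospital_streams(config: SimConfig) -> list[list[np.random.SeedSequence]]:
    """Five deterministic sub-streams per hospital from the master seed."""
    root = np.random.SeedSequence(config.seed)
    return [child.spawn(5) for child in root.spawn(config.n_hospitals)]


def plant_cost_icc(config: SimConfig) -> tuple[dict[str, float], float, float]:
    """Draw per-hospital additive log-cost effects hitting the target ICC.

    With residual log-total-cost variance sigma_e^2 (the square of
    ``patient_cost_log_sd``) and target share rho, the hospital-effect
    variance solves sigma_h^2 = rho / (1 - rho) * sigma_e^2.  Returns
    (effects by hospital id, sigma_h^2, sigma_e^2).
    """
    rho = config.cost_icc_target
    if not 0 <= rho < 1:
        raise ValueError("cost_icc_target must lie in [0, 1)")
    sigma_e2 = config.patient_cost_log_sd ** 2
    sigma_h2 = rho / (1.0 - rho) * sigma_e2
    streams = _hospital_streams(config)
    effects = {}
    for hid, subs in zip(config.hospital_ids(), streams):
        rng = np.random.default_rng(subs[3])
        effects[hid] = float(rng.normal(0.0, np.sqrt(sigma_h2))) if sigma_h2 > 0 else 0.0
    return effects, sigma_h2, sigma_e2


def _hospital_markups(config: SimConfig) -> dict[str, float]:
    """Log-normal charge markups, re-centred to exact unit median.

    Re-centring makes median-based cost standardization cancel markups
    exactly rather than only in expectation.
    """
    streams = _hospital_streams(config)
    logs = []
    for subs in streams:
        rng = np.random.default_rng(subs[4])
        logs.append(rng.normal(0.0, config.charge_markup_sd) if
                    config.charge_markup_sd > 0 else 0.0)
    markups = np.exp(np.asarray(logs))
    markups = markups / np.median(markups)
    return dict(zip(config.hospital_ids(), markups))


def _item_name(category: str, k: int) -> str:
    return f"{category.upper()}-{k + 1}"


def default_ctt_map(config: SimConfig) -> CTTMap:
    """CTT map covering every billing item the generator can emit."""
    cat: dict[str, str] = {}
    grp: dict[str, str] = {}
    for name, p in config.categories.items():
        for k in range(p.n_items):
            item = _item_name(name, k)
            cat[item] = name
            grp[item] = p.billing_group
    return CTTMap(category=cat, group=grp)


def _expected_exposure(base: float, tau: float) -> float:
    """E[logit^-1(base + tau Z)], Z ~ N(0,1), by Gauss-Hermite quadrature."""
    if tau == 0:
        return float(1.0 / (1.0 + np.exp(-base)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    p = 1.0 / (1.0 + np.exp(-(base + tau * nodes)))
    return float(np.sum(weights * p) / np.sum(weights))


def _categorical(rng: np.random.Generator, marginal: dict[str, float],
                 n: int) -> np.ndarray:
    levels = list(marginal)
    probs = np.asarray([marginal[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(levels, size=n, p=probs)


def _mean_los(ga: np.ndarray) -> np.ndarray:
    """Mean NICU length of stay (days) as a decreasing function of GA."""
    return 6.0 + 120.0 * np.exp(-0.28 * (ga - 23.0))


_DRG_BY_BW_BIN = {
    "400-499": "591", "500-749": "591", "750-999": "593",
    "1000-1249": "602", "1250-1499": "607", ">1499": "609", "unknown": "609",
}


def _simulate_hospital_encounters(
    hid: str, n: int, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    demo = config.demographics
    sex = _categorical(rng, demo["sex"], n)
    ga_bin = _categorical(rng, demo["ga_bin"], n)
    # draw a week uniformly inside the bin; ">31" spans 32-36 completed weeks
    ga = np.full(n, np.nan)
    for bin_name, (lo, hi) in {
        "22": (22, 22), "23-24": (23, 24), "25-26": (25, 26),
        "27-28": (27, 28), "29-30": (29, 30), "31": (31, 31), ">31": (32, 36),
    }.items():
        m = ga_bin == bin_name
        ga[m] = rng.integers(lo, hi + 1, size=int(m.sum()))

    bw = np.full(n, np.nan)
    known_ga = ~np.isnan(ga)
    mean_bw = np.array([BW_BY_GA[int(g)][0] if not np.isnan(g) else np.nan
                        for g in ga])
    sd_bw = np.array([BW_BY_GA[int(g)][1] if not np.isnan(g) else np.nan
                      for g in ga])
    bw[known_ga] = np.maximum(
        320.0, rng.normal(mean_bw[known_ga], sd_bw[known_ga]))
    # unknown GA: draw BW from a VLBW-weighted marginal
    n_miss = int((~known_ga).sum())
    if n_miss:
        bw[~known_ga] = rng.uniform(450, 1499, size=n_miss)
    bw = np.round(bw)

    # a small fraction of BW missing outright
    bw[rng.random(n) < 0.006] = np.nan

    age = _categorical(rng, demo["age_at_admission"], n).astype(int)
    late = rng.random(n) < config.late_admission_rate
    age[late] = rng.integers(2, 31, size=int(late.sum()))

    previable = rng.random(n) < config.previable_rate
    half = rng.random(n) < 0.5
    ga[previable & half] = 21.0
    bw[previable & ~half] = 380.0

    los_mean = np.where(np.isnan(ga), 25.0, _mean_los(np.nan_to_num(ga, nan=30.0)))
    sigma = np.sqrt(np.log(1 + 0.4 ** 2))
    los = np.maximum(
        1, np.round(np.exp(rng.normal(np.log(los_mean) - sigma ** 2 / 2, sigma)))
    ).astype(int)

    err = rng.random(n) < config.data_error_rate
    err_half = rng.random(n) < 0.5
    los[err & err_half] = 450
    implausible = err & ~err_half & known_ga
    bw[implausible] = np.array(
        [BW_BY_GA[int(g)][0] + 6 * BW_BY_GA[int(g)][1] for g in ga[implausible]]
    ) if implausible.any() else bw[implausible]

    codes = [";".join(rng.choice(_FILLER_CODES, size=2, replace=False))
             for _ in range(n)]
    anomalous = rng.random(n) < config.anomaly_rate
    for i in np.flatnonzero(anomalous):
        codes[i] += ";" + rng.choice(PLANTED_ANOMALY_CODES)

    code_only = rng.random(n) < config.code_only_rate
    for i in np.flatnonzero(code_only):
        vlbw_vp = (not np.isnan(bw[i]) and bw[i] < 1500) or (
            not np.isnan(ga[i]) and ga[i] < 32)
        ga[i] = np.nan
        bw[i] = np.nan
        if vlbw_vp:
            codes[i] += ";" + rng.choice(PLANTED_VLBW_VP_CODES)

    bw_bins = [bw_category(b if not np.isnan(b) else None) for b in bw]
    df = pd.DataFrame({
        "encounter_id": [f"{hid}-{i + 1:05d}" for i in range(n)],
        "hospital_id": hid,
        "sex": sex,
        "gestational_age_weeks": ga,
        "birth_weight_g": bw,
        "ga_category": [ga_category(g if not np.isnan(g) else None) for g in ga],
        "bw_category": bw_bins,
        "race_ethnicity": _categorical(rng, demo["race_ethnicity"], n),
        "admission_source": _categorical(rng, demo["admission_source"], n),
        "age_at_admission_days": age,
        "insurance": _categorical(rng, demo["insurance"], n),
        "income_quartile": _categorical(rng, demo["income_quartile"], n).astype(int),
        "disposition": _categorical(rng, demo["disposition"], n),
        "apr_drg": [_DRG_BY_BW_BIN[b] for b in bw_bins],
        "nicu_days": los,
        "diagnosis_codes": codes,
        "year": rng.integers(2012, 2020, size=n),
    })
    # trailing non-NICU (e.g. PICU) days after the NICU stay
    extra = np.where(rng.random(n) < config.non_nicu_day_rate,
                     rng.integers(1, 4, size=n), 0)
    df["_non_nicu_days"] = extra
    return df


def _simulate_hospital_billing(
    enc: pd.DataFrame, config: SimConfig, rng: np.random.Generator,
    u: dict[str, float], v: dict[str, float], a: float, markup: float,
    unit_costs: dict[str, float],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Billing lines for one hospital plus planted exposure/true-cost tables."""
    n = len(enc)
    eta = rng.normal(0.0, config.patient_cost_log_sd, size=n) \
        if config.patient_cost_log_sd > 0 else np.zeros(n)
    low_ga = np.nan_to_num(enc["gestational_age_weeks"].to_numpy(), nan=30.0) < 28

    frames = []
    exp_cols = {}
    cost_cols = {}
    k_shape = 1.0 / config.within_patient_cost_cv ** 2
    nicu_days = enc["nicu_days"].to_numpy()
    non_nicu = enc["_non_nicu_days"].to_numpy()
    years = enc["year"].to_numpy()
    ids = enc["encounter_id"].to_numpy()

    for cat, p in config.categories.items():
        logit = p.base_exposure_logit + u[cat]
        logit = logit + (0.7 * low_ga if config.confounded else 0.0)
        prob = 1.0 / (1.0 + np.exp(-logit))
        exposed = rng.random(n) < prob
        total = np.zeros(n)
        scale = 1.3 if config.confounded else 1.0
        total[exposed] = (
            p.mean_cost_exposed * np.exp(v[cat] + a + eta[exposed])
            * np.where(low_ga[exposed], scale, 1.0)
        )
        exp_cols[cat] = exposed
        cost_cols[cat] = total

        idx = np.flatnonzero(exposed)
        if idx.size == 0:
            continue
        n_lines = 1 + rng.binomial(np.maximum(nicu_days[idx] - 1, 0), p.day_rate)
        rep = np.repeat(idx, n_lines)
        shares = rng.gamma(k_shape, 1.0, size=rep.size)
        # normalise shares within each patient so the total is conserved
        sums = np.bincount(rep, weights=shares, minlength=n)
        line_true = total[rep] * shares / sums[rep]
        day = (rng.random(rep.size) * nicu_days[rep]).astype(int)
        item_k = rng.integers(0, p.n_items, size=rep.size)
        items = np.array([_item_name(cat, k) for k in range(p.n_items)])[item_k]
        ucost = np.array([unit_costs[_item_name(cat, k)]
                          for k in range(p.n_items)])[item_k]
        frames.append(pd.DataFrame({
            "encounter_id": ids[rep],
            "day_index": day,
            "billing_item": items,
            "charge": line_true * markup,
            "units": line_true / ucost,
            "nicu_day_flag": True,
            "year": years[rep],
        }))

        # extra lines on trailing non-NICU days for exposed patients
        nn = idx[(non_nicu[idx] > 0) & (rng.random(idx.size) < 0.3)]
        if nn.size:
            t = 0.1 * p.mean_cost_exposed
            item0 = _item_name(cat, 0)
            frames.append(pd.DataFrame({
                "encounter_id": ids[nn],
                "day_index": nicu_days[nn]
                + (rng.random(nn.size) * non_nicu[nn]).astype(int),
                "billing_item": item0,
                "charge": t * markup,
                "units": t / unit_costs[item0],
                "nicu_day_flag": False,
                "year": years[nn],
            }))

    billing = (pd.concat(frames, ignore_index=True) if frames else
               pd.DataFrame(columns=["encounter_id", "day_index", "billing_item",
                                     "charge", "units", "nicu_day_flag", "year"]))
    exposure = pd.DataFrame(exp_cols, index=ids)
    true_cost = pd.DataFrame(cost_cols, index=ids)
    return billing, exposure, true_cost


def generate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (encounters, billing, ground truth) for a simulated system.

    The encounter count equals the sum of per-hospital patient counts; the
    billing table carries raw *charges* (true cost times the hospital
    markup), not standardized costs.
    """
    streams = _hospital_streams(config)
    a_effects, sigma_h2, sigma_e2 = plant_cost_icc(config)
    markups = _hospital_markups(config)
    ctt_map = default_ctt_map(config)
    unit_costs = {}
    for cat, p in config.categories.items():
        for k in range(p.n_items):
            unit_costs[_item_name(cat, k)] = p.mean_cost_exposed / (10.0 * (k + 1))

    enc_frames, bill_frames, exp_frames, cost_frames = [], [], [], []
    eff_rows = []
    sizes = config.hospital_sizes()
    for hid, n, subs in zip(config.hospital_ids(), sizes, streams):
        rng_demo = np.random.default_rng(subs[0])
        rng_exp = np.random.default_rng(subs[1])
        rng_cost = np.random.default_rng(subs[2])
        enc = _simulate_hospital_encounters(hid, n, config, rng_demo)
        u = {c: (float(rng_exp.normal(0, p.exposure_re_sd))
                 if p.exposure_re_sd > 0 else 0.0)
             for c, p in config.categories.items()}
        v = {c: (float(rng_cost.normal(0, p.utilization_re_sd))
                 if p.utilization_re_sd > 0 else 0.0)
             for c, p in config.categories.items()}
        billing, exposure, true_cost = _simulate_hospital_billing(
            enc, config, rng_cost, u, v, a_effects[hid], markups[hid], unit_costs)
        for c in config.categories:
            eff_rows.append((hid, c, u[c], v[c]))
        enc_frames.append(enc)
        bill_frames.append(billing)
        exp_frames.append(exposure)
        cost_frames.append(true_cost)

    encounters = pd.concat(enc_frames, ignore_index=True).drop(
        columns="_non_nicu_days")
    billing = pd.concat(bill_frames, ignore_index=True)

    labeled = billing.assign(
        ctt_category=billing["billing_item"].map(ctt_map.category))
    by_cat = labeled.groupby("ctt_category", sort=True)
    truth = GroundTruth(
        config=json.loads(config.model_dump_json()),
        category_params={c: p.model_dump() for c, p in config.categories.items()},
        expected_exposure={
            c: _expected_exposure(p.base_exposure_logit, p.exposure_re_sd)
            for c, p in config.categories.items()},
        hospital_effects=pd.DataFrame(
            eff_rows, columns=["hospital_id", "category", "u", "v"]),
        hospital_factors=pd.DataFrame({
            "hospital_id": config.hospital_ids(),
            "a": [a_effects[h] for h in config.hospital_ids()],
            "markup": [markups[h] for h in config.hospital_ids()]}),
        sigma_h2=sigma_h2,
        sigma_e2=sigma_e2,
        icc_target=config.cost_icc_target,
        line_counts={c: int(g.shape[0]) for c, g in by_cat},
        charge_nicu={c: float(g.loc[g["nicu_day_flag"], "charge"].sum())
                     for c, g in by_cat},
        charge_other={c: float(g.loc[~g["nicu_day_flag"], "charge"].sum())
                      for c, g in by_cat},
        item_unit_costs=unit_costs,
        exposure=pd.concat(exp_frames),
        true_cost=pd.concat(cost_frames),
    )
    return encounters, billing, truth
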