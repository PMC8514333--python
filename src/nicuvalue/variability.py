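"""Inter-hospital variability statistics and the prioritization score.

For each CTT category:

* **Exposure variability (EV)** — standardize each hospital's adjusted
  exposure proportion by its binomial sampling SE,
  ``z_h = (p_h - p) / sqrt(p (1 - p) / n_h)``, and take the sample SD of
  those standard distances.  Under pure sampling from a common population
  EV is about 1; larger values mean real between-hospital spread.
* **Utilization variability (UV)** — the coefficient of variation of the
  adjusted hospital mean costs among exposed patients.
* **Variability index (VI)** — the Euclidean distance from the origin of
  (EV, UV) after dividing each by its across-category SD.
* **Prioritization score (PS)** — the same standardized distance over
  three equally weighted components: total adjusted cost, proportion of
  patients exposed, and VI.

Hospitals whose exposure rate is more than four times or less than a
quarter of the population rate are excluded from a category's
variability calculation (billing-pattern artifacts rather than practice
variation).  All SDs use the n-1 denominator; boundary comparisons are
strict throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("nicuvalue")

__all__ = [
    "billing_pattern_filter",
    "exposure_variability",
    "utilization_variability",
    "standardized_distance",
    "variability_index",
    "prioritization_score",
    "rank_categories",
    "detect_outlier_hospitals",
    "summarize_categories",
]


def billing_pattern_filter(
    rates: pd.Series,
    population_rate: float,
    upper: float = 4.0,
    lower: float = 0.25,
) -> pd.Index:
    """Hospitals kept for a category's variability calculation.

    Excluded iff rate > 4p or rate < p/4 (strict); boundary values stay.
    A zero population rate means the category cannot be assessed.
    """
    if population_rate <= 0:
        raise ValueError("population exposure rate must be > 0")
    keep = ~((rates > upper * population_rate) |
             (rates < lower * population_rate))
    return rates.index[keep]


def exposure_variability(
    proportions: pd.Series,
    sizes: pd.Series,
    population_rate: float,
) -> float:
    """Sample SD of binomial standard distances of hospital proportions.

    ``proportions`` are adjusted hospital exposure proportions, ``sizes``
    the hospital cohort sizes entering the sampling SE.
    """
    if len(proportions) < 2:
        raise ValueError("need at least 2 hospitals for exposure variability")
    if not 0 < population_rate < 1:
        raise ValueError("population exposure rate must lie strictly in (0, 1)")
    p = np.asarray(proportions, dtype=float)
    n = np.asarray(sizes.loc[proportions.index], dtype=float)
    z = (p - population_rate) / np.sqrt(
        population_rate * (1.0 - population_rate) / n)
    return float(np.std(z, ddof=1))


def utilization_variability(mean_costs: pd.Series) -> float:
    """Coefficient of variation of adjusted hospital mean costs (exposed)."""
    if len(mean_costs) < 2:
        raise ValueError("need at least 2 hospitals for utilization variability")
    m = np.asarray(mean_costs, dtype=float)
    mean = m.mean()
    if mean <= 0:
        raise ValueError("mean of hospital mean costs must be > 0")
    return float(np.std(m, ddof=1) / mean)


def standardized_distance(components: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Euclidean distance from the origin with each axis divided by its SD.

    A degenerate axis (SD = 0) contributes nothing and is warned about,
    so small simulated tables with a constant component stay computable.
    """
    comp = np.atleast_2d(np.asarray(components, dtype=float))
    s = np.asarray(sds, dtype=float)
    scaled = np.zeros_like(comp)
    for j, sd in enumerate(s):
        if sd > 0:
            scaled[:, j] = comp[:, j] / sd
        elif np.any(comp[:, j] != 0):
            logger.warning(
                "component %d has zero across-category SD; it contributes 0 "
                "to the standardized distance", j)
    return np.sqrt((scaled ** 2).sum(axis=1))


def variability_index(ev: pd.Series, uv: pd.Series) -> pd.Series:
    """VI per category from EV and UV (SDs computed across categories)."""
    comp = np.column_stack([ev.to_numpy(float), uv.to_numpy(float)])
    sds = comp.std(axis=0, ddof=1) if len(ev) > 1 else np.zeros(2)
    return pd.Series(standardized_distance(comp, sds), index=ev.index,
                     name="variability_index")


def prioritization_score(
    cost: pd.Series, exposed: pd.Series, vi: pd.Series
) -> pd.Series:
    """PS per category: standardized distance over (cost, exposure, VI)."""
    comp = np.column_stack([cost.to_numpy(float), exposed.to_numpy(float),
                            vi.to_numpy(float)])
    sds = comp.std(axis=0, ddof=1) if len(cost) > 1 else np.zeros(3)
    return pd.Series(standardized_distance(comp, sds), index=cost.index,
                     name="prioritization_score")


def rank_categories(summary: pd.DataFrame) -> pd.DataFrame:
    """Attach descending competition ranks (ties share the smaller rank).

    Ranks cost, exposure, variability index, and prioritization score.
    """
    out = summary.copy()
    for col, rank_col in [
        ("total_cost", "cost_rank"),
        ("pct_exposed", "exposure_rank"),
        ("variability_index", "variability_rank"),
        ("prioritization_score", "priority_rank"),
    ]:
        if col in out.columns:
            out[rank_col] = rankdata(-out[col].to_numpy(float),
                                     method="min").astype(int)
    return out


def detect_outlier_hospitals(
    patient_costs: pd.DataFrame,
    cost_col: str = "cost",
    group_col: str | None = None,
) -> pd.DataFrame:
    """High/low-cost outlier hospitals by quartile comparison.

    A hospital is a high (low) outlier when its median adjusted
    per-patient cost lies strictly above (below) the population third
    (first) quartile of the patient-level distribution.  When
    ``group_col`` is given the comparison runs within each billing group.
    """
    def _one(df: pd.DataFrame, label: str) -> pd.DataFrame:
        if df["hospital_id"].nunique() < 4:
            raise ValueError("need at least 4 hospitals for outlier detection")
        q1, q3 = np.percentile(df[cost_col].to_numpy(float), [25, 75])
        med = df.groupby("hospital_id", sort=True)[cost_col].median()
        status = np.where(med > q3, "high", np.where(med < q1, "low", "none"))
        return pd.DataFrame({
            "group": label,
            "hospital_id": med.index,
            "median_cost": med.to_numpy(),
            "q1": q1,
            "q3": q3,
            "outlier": status,
        })

    frames = [_one(patient_costs, "total")]
    if group_col is not None:
        for label, g in patient_costs.groupby(group_col, sort=True):
            frames.append(_one(g, str(label)))
    return pd.concat(frames, ignore_index=True)


def summarize_categories(
    category_totals: pd.DataFrame,
    hospital_exposure: dict[str, pd.DataFrame],
    hospital_costs: dict[str, pd.Series],
    hospital_sizes: pd.Series,
    population_rates: pd.Series,
    upper: float = 4.0,
    lower: float = 0.25,
) -> pd.DataFrame:
    """Full category summary: EV, UV, VI, PS and ranks.

    ``hospital_exposure[cat]`` holds adjusted hospital exposure
    proportions (column ``adjusted``, indexed rows ``hospital_id``);
    ``hospital_costs[cat]`` the adjusted hospital mean costs among
    exposed patients.  Categories whose population rate is 0 are skipped
    with a warning.
    """
    rows = []
    for cat in category_totals["ctt_category"]:
        p_bar = float(population_rates[cat])
        if p_bar <= 0:
            logger.warning("category %s has zero population exposure; skipped",
                           cat)
            continue
        prop = hospital_exposure[cat].set_index("hospital_id")["adjusted"]
        kept = billing_pattern_filter(prop, p_bar, upper, lower)
        costs = hospital_costs[cat]
        kept_cost = costs.index.intersection(kept)
        ev = exposure_variability(prop.loc[kept], hospital_sizes, p_bar)
        uv = utilization_variability(costs.loc[kept_cost])
        rows.append((cat, ev, uv, len(kept)))
    var = pd.DataFrame(
        rows, columns=["ctt_category", "exposure_variability",
                       "utilization_variability", "n_hospitals_included"]
    ).set_index("ctt_category")
    var["variability_index"] = variability_index(
        var["exposure_variability"], var["utilization_variability"])

    summary = category_totals.merge(var.reset_index(), on="ctt_category",
                                    how="inner")
    summary["prioritization_score"] = prioritization_score(
        summary["total_cost"], summary["pct_exposed"],
        summary["variability_index"]).to_numpy()
    summary = rank_categories(summary)
    return summary.sort_values("priority_rank", kind="mergesort").reset_index(
        drop=True)
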