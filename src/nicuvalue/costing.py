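"""Charge-to-cost standardization and CTT aggregation.

Hospital charges are a poor between-hospital comparator because each
hospital applies its own markup over true resource cost.  The remedy is a
*cost index*: for every billing item, take each hospital's median unit
cost (charge per unit, after regional wage-index division) and then the
median of those hospital medians.  Standardized line cost is then
``units x index[item] x inflation(year)`` — the hospital's own charge
level no longer enters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import IndexTables

__all__ = [
    "build_cost_index",
    "standardize_costs",
    "aggregate_ctt",
    "flag_resource_intensive",
]


def build_cost_index(
    billing: pd.DataFrame,
    encounters: pd.DataFrame,
    tables: IndexTables | None = None,
) -> pd.Series:
    """Median-of-hospital-medians standardized unit cost per billing item.

    ``encounters`` supplies the hospital id of each billing line.  The
    even-count median is the midpoint of the two central values.
    """
    tables = tables or IndexTables()
    hosp = billing["encounter_id"].map(
        encounters.set_index("encounter_id")["hospital_id"])
    wage = hosp.map(tables.wage).astype(float)
    units = billing["units"].astype(float)
    if (units <= 0).any():
        bad = billing.loc[units <= 0, "billing_item"].unique()
        raise ValueError(f"non-positive units for item(s): {sorted(bad)[:10]}")
    unit_cost = billing["charge"].astype(float) / wage / units
    per_hospital = (
        pd.DataFrame({"billing_item": billing["billing_item"],
                      "hospital_id": hosp, "unit_cost": unit_cost})
        .groupby(["billing_item", "hospital_id"], sort=True)["unit_cost"]
        .median()
    )
    index = per_hospital.groupby("billing_item").median()
    index.name = "standardized_unit_cost"
    return index


def standardize_costs(
    billing: pd.DataFrame,
    index: pd.Series,
    tables: IndexTables | None = None,
) -> pd.DataFrame:
    """Attach a ``cost`` column of standardized, inflation-adjusted costs.

    Requires the index to cover every billing item.  If the billing table
    has a ``year`` column and the inflation table is non-identity, a year
    missing from the table is an error.
    """
    tables = tables or IndexTables()
    missing = set(billing["billing_item"]) - set(index.index)
    if missing:
        raise KeyError(
            f"cost index does not cover item(s): {sorted(missing)[:10]}")
    unit = billing["billing_item"].map(index).astype(float)
    if "year" in billing.columns and tables.inflation_index:
        infl = billing["year"].map(
            lambda y: tables.inflation(int(y))).astype(float)
    else:
        infl = 1.0
    out = billing.copy()
    out["cost"] = billing["units"].astype(float) * unit * infl
    return out


def aggregate_ctt(
    costed: pd.DataFrame,
    cohort: pd.DataFrame,
    categories: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-encounter per-category costs/exposure and per-category totals.

    ``costed`` must already be restricted to NICU days and labeled with
    ``ctt_category``; only cohort encounters are aggregated.  Exposure is
    at least one line in the category on at least one NICU day.  Returns
    ``(encounter_costs, category_totals)`` where category totals carry the
    cumulative percent of the all-category total, descending by cost.
    """
    ids = cohort["encounter_id"]
    lines = costed[costed["encounter_id"].isin(set(ids))]
    cats = categories if categories is not None else sorted(
        c for c in lines["ctt_category"].unique())

    grouped = lines.groupby(["encounter_id", "ctt_category"]).agg(
        cost=("cost", "sum"),
        exposed_days=("day_index", "nunique"),
        n_lines=("cost", "size"),
    ).reset_index()
    full = pd.MultiIndex.from_product([ids, cats],
                                      names=["encounter_id", "ctt_category"])
    enc = (grouped.set_index(["encounter_id", "ctt_category"])
           .reindex(full, fill_value=0).reset_index())
    enc["exposed"] = enc["n_lines"] > 0
    enc = enc.drop(columns="n_lines")

    totals = (enc.groupby("ctt_category")
              .agg(total_cost=("cost", "sum"),
                   n_exposed=("exposed", "sum"))
              .reindex(cats, fill_value=0)
              .reset_index())
    totals["n_exposed"] = totals["n_exposed"].astype(int)
    totals["pct_exposed"] = 100.0 * totals["n_exposed"] / len(ids)
    totals = totals.sort_values(
        "total_cost", ascending=False, kind="mergesort").reset_index(drop=True)
    grand = totals["total_cost"].sum()
    totals["cumulative_pct_cost"] = (
        100.0 * totals["total_cost"].cumsum() / grand if grand > 0 else 0.0)
    return enc, totals


def flag_resource_intensive(
    encounter_totals: pd.DataFrame,
    quantile: float = 0.90,
) -> pd.DataFrame:
    """Flag stays in the top decile of total CTT-related cost.

    Rank-based rule: sort ascending by (cost, encounter id); the bottom
    ``floor(q * N)`` stays are mild/moderate, the remaining
    ``N - floor(q * N)`` are resource-intensive.  Ties at the boundary
    break by stable encounter-id order.
    """
    if len(encounter_totals) < 10:
        raise ValueError("need at least 10 encounters to define the top decile")
    df = encounter_totals[["encounter_id", "total_ctt_cost"]].copy()
    order = df.sort_values(
        ["total_ctt_cost", "encounter_id"], kind="mergesort").index
    n = len(df)
    cut = int(np.floor(quantile * n))
    flags = pd.Series(False, index=df.index)
    flags.loc[order[cut:]] = True
    df["resource_intensive"] = flags
    return df
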