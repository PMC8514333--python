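"""Column schemas, categorical levels, and table validation.

Every pipeline stage exchanges plain pandas DataFrames whose columns follow
the schemas defined here.  Two tables carry the raw data:

* the *encounter* table — one row per NICU stay (demographics, gestational
  age, birth weight, APR-DRG, NICU length of stay, disposition), and
* the *billing* table — one row per charge line (encounter, day of stay,
  billing item, charge, units, NICU-bed-charge flag).

Validation is strict: a missing column raises :class:`SchemaError` naming
the column, and a row violating an invariant raises
:class:`RowValidationError` citing the offending row numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RowValidationError",
    "ENCOUNTER_COLUMNS",
    "BILLING_COLUMNS",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "ADMISSION_SOURCE_LEVELS",
    "INSURANCE_LEVELS",
    "DISPOSITION_LEVELS",
    "BILLING_GROUPS",
    "GA_CATEGORIES",
    "BW_CATEGORIES",
    "ga_category",
    "bw_category",
    "validate_encounters",
    "validate_billing",
]


class SchemaError(ValueError):
    """A table is structurally malformed (missing/extra required columns)."""


class RowValidationError(ValueError):
    """One or more rows violate a field invariant; message cites row numbers."""


#: Required columns of the encounter table, in canonical order.
ENCOUNTER_COLUMNS = [
    "encounter_id",
    "hospital_id",
    "sex",
    "gestational_age_weeks",
    "birth_weight_g",
    "ga_category",
    "bw_category",
    "race_ethnicity",
    "admission_source",
    "age_at_admission_days",
    "insurance",
    "income_quartile",
    "disposition",
    "apr_drg",
    "nicu_days",
    "diagnosis_codes",
]

#: Required columns of the billing table.  ``year`` (calendar year of the
#: charge, used for inflation adjustment) is optional; absent means the
#: identity inflation table applies.
BILLING_COLUMNS = [
    "encounter_id",
    "day_index",
    "billing_item",
    "charge",
    "units",
    "nicu_day_flag",
]

SEX_LEVELS = ("male", "female", "unknown")
RACE_LEVELS = (
    "non_hispanic_white",
    "non_hispanic_black",
    "hispanic",
    "asian",
    "other",
)
ADMISSION_SOURCE_LEVELS = ("inborn", "outborn", "other")
INSURANCE_LEVELS = ("commercial", "government", "self_pay", "other")
DISPOSITION_LEVELS = ("home", "transfer", "mortality", "other")
BILLING_GROUPS = ("pharmaceutical", "laboratory", "imaging", "other")

#: Ordinal gestational-age bins (completed weeks).
GA_CATEGORIES = ("22", "23-24", "25-26", "27-28", "29-30", "31", ">31", "unknown")
#: Ordinal birth-weight bins (grams).
BW_CATEGORIES = (
    "400-499",
    "500-749",
    "750-999",
    "1000-1249",
    "1250-1499",
    ">1499",
    "unknown",
)


def ga_category(ga_weeks) -> str:
    """Bin a gestational age in completed weeks into its ordinal category."""
    if ga_weeks is None or (isinstance(ga_weeks, float) and np.isnan(ga_weeks)):
        return "unknown"
    ga = int(ga_weeks)
    if ga <= 22:
        return "22"
    if ga <= 24:
        return "23-24"
    if ga <= 26:
        return "25-26"
    if ga <= 28:
        return "27-28"
    if ga <= 30:
        return "29-30"
    if ga == 31:
        return "31"
    return ">31"


def bw_category(bw_g) -> str:
    """Bin a birth weight in grams into its ordinal category."""
    if bw_g is None or (isinstance(bw_g, float) and np.isnan(bw_g)):
        return "unknown"
    bw = float(bw_g)
    if bw < 500:
        return "400-499"
    if bw < 750:
        return "500-749"
    if bw < 1000:
        return "750-999"
    if bw < 1250:
        return "1000-1249"
    if bw < 1500:
        return "1250-1499"
    return ">1499"


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table} table is missing required column(s): {', '.join(missing)}"
        )


def _fail_rows(mask: pd.Series, message: str) -> None:
    if mask.any():
        rows = [int(r) for r in np.flatnonzero(mask.to_numpy())[:20]]
        raise RowValidationError(f"{message}; offending row number(s): {rows}")


def validate_encounters(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an encounter table against the schema and field invariants.

    Returns the input (unchanged) so the call composes with readers.
    """
    _require_columns(df, ENCOUNTER_COLUMNS, "encounter")
    _fail_rows(df["encounter_id"].isna(), "encounter_id must be present")
    if df["encounter_id"].duplicated().any():
        dupes = df.loc[df["encounter_id"].duplicated(), "encounter_id"].head(5)
        raise RowValidationError(
            f"duplicate encounter_id values: {list(dupes.astype(str))}"
        )
    nicu = pd.to_numeric(df["nicu_days"], errors="coerce")
    _fail_rows(nicu.isna() | (nicu < 1), "nicu_days must be an integer >= 1")
    age = pd.to_numeric(df["age_at_admission_days"], errors="coerce")
    _fail_rows(age.isna() | (age < 0), "age_at_admission_days must be >= 0")
    ga = pd.to_numeric(df["gestational_age_weeks"], errors="coerce")
    _fail_rows(
        ga.notna() & ((ga < 20) | (ga > 45)),
        "gestational_age_weeks, when present, must lie in [20, 45]",
    )
    bw = pd.to_numeric(df["birth_weight_g"], errors="coerce")
    _fail_rows(bw.notna() & (bw <= 0), "birth_weight_g, when present, must be > 0")
    for col, levels in [
        ("sex", SEX_LEVELS),
        ("race_ethnicity", RACE_LEVELS),
        ("admission_source", ADMISSION_SOURCE_LEVELS),
        ("insurance", INSURANCE_LEVELS),
        ("disposition", DISPOSITION_LEVELS),
    ]:
        _fail_rows(~df[col].isin(levels), f"{col} must be one of {levels}")
    q = pd.to_numeric(df["income_quartile"], errors="coerce")
    _fail_rows(q.isna() | ~q.isin([1, 2, 3, 4]), "income_quartile must be 1-4")
    return df


def validate_billing(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a billing table against the schema and field invariants."""
    _require_columns(df, BILLING_COLUMNS, "billing")
    charge = pd.to_numeric(df["charge"], errors="coerce")
    _fail_rows(charge.isna() | (charge < 0), "charge must be >= 0")
    units = pd.to_numeric(df["units"], errors="coerce")
    _fail_rows(units.isna() | (units <= 0), "units must be > 0")
    day = pd.to_numeric(df["day_index"], errors="coerce")
    _fail_rows(day.isna() | (day < 0), "day_index must be >= 0")
    return df
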