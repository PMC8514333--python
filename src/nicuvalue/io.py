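"""Delimited-file readers and writers for the pipeline's tabular artifacts.

All artifacts are comma-delimited UTF-8 with a header row; missing values
are empty fields.  Currency is kept at full float precision internally and
rounded to cents only in report outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .schemas import (
    BILLING_GROUPS,
    RowValidationError,
    SchemaError,
    validate_billing,
    validate_encounters,
)

logger = logging.getLogger("nicuvalue")

__all__ = [
    "CTTMap",
    "IndexTables",
    "read_encounters",
    "write_encounters",
    "read_billing",
    "write_billing",
    "read_ctt_map",
    "write_ctt_map",
    "read_index_tables",
]

_ENCOUNTER_DTYPES = {
    "encounter_id": str,
    "hospital_id": str,
    "apr_drg": str,
    "diagnosis_codes": str,
}


@dataclass(frozen=True)
class CTTMap:
    """Mapping billing item -> (CTT category, billing group).

    Items not present in the map route to category ``"other"`` / group
    ``"other"``; :func:`read_billing` logs how many lines that affected.
    """

    category: dict[str, str]
    group: dict[str, str]

    def lookup(self, item: str) -> tuple[str, str]:
        return self.category.get(item, "other"), self.group.get(item, "other")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CTTMap":
        for col in ("billing_item", "ctt_category", "billing_group"):
            if col not in df.columns:
                raise SchemaError(f"ctt_map table is missing required column(s): {col}")
        bad = ~df["billing_group"].isin(BILLING_GROUPS)
        if bad.any():
            raise RowValidationError(
                f"billing_group must be one of {BILLING_GROUPS}; "
                f"got {sorted(df.loc[bad, 'billing_group'].unique())}"
            )
        return cls(
            category=dict(zip(df["billing_item"], df["ctt_category"])),
            group=dict(zip(df["billing_item"], df["billing_group"])),
        )

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.category)
        return pd.DataFrame(
            {
                "billing_item": items,
                "ctt_category": [self.category[i] for i in items],
                "billing_group": [self.group[i] for i in items],
            }
        )


@dataclass(frozen=True)
class IndexTables:
    """Regional wage index and inflation index, identity when absent.

    ``wage_index`` maps hospital id -> positive multiplier (charges are
    divided by it before unit-cost estimation); ``inflation_index`` maps
    calendar year -> positive multiplier to reference-year dollars.
    """

    wage_index: dict[str, float] = field(default_factory=dict)
    inflation_index: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.wage_index.values()):
            raise ValueError("wage_index multipliers must be > 0")
        if any(v <= 0 for v in self.inflation_index.values()):
            raise ValueError("inflation_index multipliers must be > 0")

    def wage(self, hospital_id: str) -> float:
        return self.wage_index.get(hospital_id, 1.0)

    def inflation(self, year: int) -> float:
        if not self.inflation_index:
            return 1.0
        if int(year) not in self.inflation_index:
            raise KeyError(f"no inflation multiplier for calendar year {year}")
        return self.inflation_index[int(year)]


def read_encounters(path: str | Path) -> pd.DataFrame:
    """Read and validate an encounter table (one row per NICU stay)."""
    df = pd.read_csv(path, dtype=_ENCOUNTER_DTYPES, keep_default_na=True)
    if "diagnosis_codes" in df.columns:
        df["diagnosis_codes"] = df["diagnosis_codes"].fillna("")
    validate_encounters(df)
    df["nicu_days"] = df["nicu_days"].astype(int)
    df["age_at_admission_days"] = df["age_at_admission_days"].astype(int)
    df["income_quartile"] = df["income_quartile"].astype(int)
    return df


def write_encounters(df: pd.DataFrame, path: str | Path) -> None:
    validate_encounters(df)
    df.to_csv(path, index=False)


def read_billing(
    path: str | Path,
    ctt_map: CTTMap,
    encounters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read a billing table and label each line with its CTT category/group.

    Unmapped billing items route to category/group ``"other"`` (the count is
    logged).  If ``encounters`` is given, billing lines must resolve against
    it: orphan encounter ids raise an error listing the offenders.
    """
    df = pd.read_csv(path, dtype={"encounter_id": str, "billing_item": str})
    validate_billing(df)
    df = label_billing(df, ctt_map)
    if encounters is not None:
        known = set(encounters["encounter_id"])
        orphans = sorted(set(df["encounter_id"]) - known)
        if orphans:
            raise RowValidationError(
                f"billing lines reference {len(orphans)} unknown encounter id(s): "
                f"{orphans[:10]}"
            )
    return df


def label_billing(df: pd.DataFrame, ctt_map: CTTMap) -> pd.DataFrame:
    """Attach ``ctt_category`` and ``billing_group`` columns via the map."""
    df = df.copy()
    df["ctt_category"] = df["billing_item"].map(ctt_map.category).fillna("other")
    df["billing_group"] = df["billing_item"].map(ctt_map.group).fillna("other")
    n_unmapped = int((~df["billing_item"].isin(ctt_map.category)).sum())
    if n_unmapped:
        logger.warning(
            "%d billing line(s) had unmapped items and were routed to 'other'",
            n_unmapped,
        )
    return df


def write_billing(df: pd.DataFrame, path: str | Path) -> None:
    validate_billing(df)
    df.to_csv(path, index=False)


def read_ctt_map(path: str | Path) -> CTTMap:
    return CTTMap.from_frame(pd.read_csv(path, dtype=str))


def write_ctt_map(ctt_map: CTTMap, path: str | Path) -> None:
    ctt_map.to_frame().to_csv(path, index=False)


def read_index_tables(
    wage_path: str | Path | None = None,
    inflation_path: str | Path | None = None,
) -> IndexTables:
    """Read wage/inflation index tables; either may be absent (identity)."""
    wage: dict[str, float] = {}
    infl: dict[int, float] = {}
    if wage_path is not None:
        w = pd.read_csv(wage_path, dtype={"hospital_id": str})
        wage = dict(zip(w["hospital_id"], w["wage_index"].astype(float)))
    if inflation_path is not None:
        i = pd.read_csv(inflation_path)
        infl = dict(zip(i["year"].astype(int), i["multiplier"].astype(float)))
    return IndexTables(wage_index=wage, inflation_index=infl)
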