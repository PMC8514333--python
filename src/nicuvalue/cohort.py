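"""Cohort construction: inclusion/exclusion cascade and NICU-day restriction.

The analytic population is very-low-birth-weight (<1500 g) and/or very
preterm (<32 weeks) infants.  Encounters pass through a fixed-order
cascade; each encounter is counted at its first failing rule, so the
exclusion log reads like a study flow diagram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import BW_BY_GA

logger = logging.getLogger("nicuvalue")

__all__ = [
    "ExclusionLog",
    "CohortConfig",
    "classify_vlbw_vp",
    "apply_exclusions",
    "restrict_to_nicu_days",
    "DEFAULT_ANOMALY_CODES",
    "DEFAULT_VLBW_VP_CODES",
]

#: Default congenital-anomaly exclusion codes.  A documented placeholder:
#: the clinical list is consensus-curated and must be supplied in config
#: for real analyses.
DEFAULT_ANOMALY_CODES = frozenset({"Q24.8", "Q24.9", "Q33.0", "Q61.9"})

#: Diagnosis-code fallback marking VLBW/VP when discrete GA/BW are absent.
#: Placeholder list (preterm/low-birth-weight code family).
DEFAULT_VLBW_VP_CODES = frozenset({"P07.0", "P07.1", "P07.2", "P07.3"})


@dataclass
class CohortConfig:
    """Tunable constants of the exclusion cascade."""

    anomaly_codes: frozenset[str] = DEFAULT_ANOMALY_CODES
    vlbw_vp_codes: frozenset[str] = DEFAULT_VLBW_VP_CODES
    min_hospital_volume: int = 100
    max_admission_age_days: int = 1
    #: data-entry-error screens (overridable): stays longer than this are
    #: treated as implausible
    max_los_days: int = 400
    #: BW more than this many SDs above the GA-specific mean is implausible
    bw_z_limit: float = 4.0


@dataclass
class ExclusionLog:
    """Ordered record of (rule, n excluded, n remaining) steps."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, rule: str, n_excluded: int, n_remaining: int) -> None:
        self.steps.append((rule, int(n_excluded), int(n_remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["rule", "n_excluded", "n_remaining"])


def _code_set(codes: str) -> set[str]:
    if not isinstance(codes, str) or not codes:
        return set()
    return {c.strip() for c in codes.split(";") if c.strip()}


def classify_vlbw_vp(
    encounters: pd.DataFrame,
    vlbw_vp_codes: frozenset[str] = DEFAULT_VLBW_VP_CODES,
) -> pd.Series:
    """True where a stay is VLBW (<1500 g) and/or VP (<32 weeks).

    Discrete birth weight / gestational age fields are used when present;
    otherwise a diagnosis-code fallback applies.  Rows with neither
    discrete fields nor qualifying codes classify False (logged).
    """
    bw = pd.to_numeric(encounters["birth_weight_g"], errors="coerce")
    ga = pd.to_numeric(encounters["gestational_age_weeks"], errors="coerce")
    by_discrete = (bw < 1500) | (ga < 32)
    no_discrete = bw.isna() & ga.isna()
    by_code = encounters["diagnosis_codes"].map(
        lambda s: bool(_code_set(s) & vlbw_vp_codes)).astype(bool)
    out = by_discrete.fillna(False) | (no_discrete & by_code)
    n_unknown = int((no_discrete & ~by_code).sum())
    if n_unknown:
        logger.info(
            "%d encounter(s) had neither discrete GA/BW nor qualifying codes; "
            "classified as not VLBW/VP", n_unknown)
    return out


def _implausible_bw(encounters: pd.DataFrame, z_limit: float) -> pd.Series:
    bw = pd.to_numeric(encounters["birth_weight_g"], errors="coerce")
    ga = pd.to_numeric(encounters["gestational_age_weeks"], errors="coerce")
    lim = ga.map(lambda g: BW_BY_GA[int(g)][0] + z_limit * BW_BY_GA[int(g)][1]
                 if not np.isnan(g) else np.inf).astype(float)
    return (bw > lim).fillna(False)


def apply_exclusions(
    encounters: pd.DataFrame,
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion cascade; return (cohort, flow-diagram log).

    Fixed order: (1) not VLBW/VP; (2) pre-viable (GA < 22 weeks or
    BW < 400 g); (3) admitted after 1 day of age; (4) congenital-anomaly
    code; (5) data-entry-error screens; (6) hospitals left with fewer than
    ``min_hospital_volume`` patients, removed with all their encounters.
    """
    cfg = config or CohortConfig()
    log = ExclusionLog()
    df = encounters
    n0 = len(df)

    keep = classify_vlbw_vp(df, cfg.vlbw_vp_codes)
    df = df[keep]
    log.add("not VLBW/VP", n0 - len(df), len(df))

    bw = pd.to_numeric(df["birth_weight_g"], errors="coerce")
    ga = pd.to_numeric(df["gestational_age_weeks"], errors="coerce")
    previable = (ga < 22).fillna(False) | (bw < 400).fillna(False)
    n = len(df)
    df = df[~previable]
    log.add("GA < 22 weeks or BW < 400 g", n - len(df), len(df))

    n = len(df)
    df = df[df["age_at_admission_days"] <= cfg.max_admission_age_days]
    log.add("admitted after 1 day of age", n - len(df), len(df))

    n = len(df)
    anomalous = df["diagnosis_codes"].map(
        lambda s: bool(_code_set(s) & cfg.anomaly_codes)).astype(bool)
    df = df[~anomalous]
    log.add("congenital anomaly code", n - len(df), len(df))

    n = len(df)
    errors = (df["nicu_days"] > cfg.max_los_days) | _implausible_bw(
        df, cfg.bw_z_limit)
    df = df[~errors]
    log.add("data-entry-error screens", n - len(df), len(df))

    n = len(df)
    counts = df["hospital_id"].value_counts()
    small = counts[counts < cfg.min_hospital_volume].index
    df = df[~df["hospital_id"].isin(small)]
    log.add(f"hospital volume < {cfg.min_hospital_volume}", n - len(df), len(df))

    if df.empty:
        raise ValueError("empty cohort: every encounter was excluded")
    return df.reset_index(drop=True), log


def restrict_to_nicu_days(billing: pd.DataFrame) -> pd.DataFrame:
    """Keep only billing lines on days with a NICU bed charge.

    Costs incurred in other units (e.g. a PICU stretch) are dropped so
    that utilization reflects NICU care only.
    """
    return billing[billing["nicu_day_flag"].astype(bool)].reset_index(drop=True)
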