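"""Length-of-stay-based severity of illness (NICU-SOI relative weights).

Severity is proxied by case-mix: each APR-DRG's relative weight is the
ratio of its mean NICU length of stay to the overall mean, computed on a
reference population with in-hospital deaths removed and LOS Winsorized
so extreme stays do not dominate the means.  A stay scoring above 1 sits
in a case-mix group with longer-than-average NICU stays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("nicuvalue")

__all__ = ["winsorize", "SeverityTable", "compute_nicu_soi"]


def winsorize(values, lower_pct: float = 5, upper_pct: float = 95) -> np.ndarray:
    """Replace values beyond nearest-rank percentiles with the cut values.

    The cut for percentile p is the ceil(p/100 * n)-th order statistic
    (1-based), a deterministic convention with no interpolation.  Length
    and order are preserved.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot Winsorize an empty sequence")
    srt = np.sort(x)
    lo = srt[max(int(np.ceil(lower_pct / 100.0 * x.size)), 1) - 1]
    hi = srt[max(int(np.ceil(upper_pct / 100.0 * x.size)), 1) - 1]
    return np.clip(x, lo, hi)


@dataclass
class SeverityTable:
    """APR-DRG -> relative weight, with the reference overall mean LOS."""

    weights: dict[str, float]
    overall_mean_los: float

    def score(self, encounters: pd.DataFrame) -> pd.Series:
        """NICU-SOI score per encounter by APR-DRG lookup.

        Groups absent from the reference population score 1 (average
        severity) with a warning.
        """
        unknown = sorted(set(encounters["apr_drg"]) - set(self.weights))
        if unknown:
            logger.warning(
                "APR-DRG group(s) %s absent from severity reference; "
                "assigned weight 1", unknown[:10])
        return encounters["apr_drg"].map(self.weights).fillna(1.0).rename(
            "nicu_soi")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "apr_drg": list(self.weights),
            "relative_weight": list(self.weights.values()),
            "overall_mean_los": self.overall_mean_los,
        })


def compute_nicu_soi(
    reference: pd.DataFrame,
    lower_pct: float = 5,
    upper_pct: float = 95,
) -> SeverityTable:
    """Estimate NICU-SOI relative weights from a reference population.

    Mortalities are dropped, NICU LOS is Winsorized across the remaining
    reference population, and weight(g) = mean LOS in APR-DRG g divided
    by the overall mean LOS.  A group containing only mortalities gets no
    weight (scoring falls back to 1 with a warning).
    """
    ref = reference[reference["disposition"] != "mortality"]
    dropped_groups = set(reference["apr_drg"]) - set(ref["apr_drg"])
    if dropped_groups:
        logger.warning(
            "APR-DRG group(s) %s contain only mortalities; no weight estimated",
            sorted(dropped_groups))
    if ref.empty:
        raise ValueError("severity reference population is empty after "
                         "excluding mortalities")
    los = winsorize(ref["nicu_days"].to_numpy(), lower_pct, upper_pct)
    overall = float(np.mean(los))
    means = pd.Series(los, index=ref["apr_drg"].to_numpy()).groupby(level=0).mean()
    return SeverityTable(weights=(means / overall).to_dict(),
                         overall_mean_los=overall)
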