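"""Published 36-category CTT prioritization summary.

A packaged copy of the prioritization table reported for a 40-hospital
US children's-hospital cohort of VLBW/VP infants (2012-2019): adjusted
cost, exposed counts, variability index, prioritization score, and ranks
for each of 36 clinician-driven test/treatment categories.  It serves as
an input for cross-checking the package's ranking and share arithmetic
and for worked examples; the underlying patient-level data are
proprietary and are not shipped or reconstructed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_published_ctt_reference", "cost_shares"]


def load_published_ctt_reference() -> pd.DataFrame:
    """Load the published 36-category prioritization summary table."""
    with resources.files("nicuvalue.data").joinpath(
            "published_ctt_reference.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def cost_shares(table: pd.DataFrame, by_rank: str, top: int) -> tuple[float, float]:
    """(combined cost, percent of the all-category cost) of the top rows.

    ``by_rank`` names a rank column (e.g. ``cost_rank`` or
    ``priority_rank``); the ``top`` best-ranked categories are summed.
    """
    total = float(table["adjusted_cost_usd"].sum())
    sel = table[table[by_rank] <= top]
    combined = float(sel["adjusted_cost_usd"].sum())
    return combined, 100.0 * combined / total
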