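"""Re-rank the published 36-category summary and report cost shares.

Loads the packaged prioritization table from a published 40-hospital
VLBW/VP cohort, re-derives the cost ranks with the package's competition
ranking, and prints the combined cost and share of the all-category total
for the top-3 costliest and top-10 prioritized categories.  The shares
show how concentrated NICU test/treatment spending is: a handful of
categories carries most of the modifiable cost.
"""

from nicuvalue.reference import cost_shares, load_published_ctt_reference
from nicuvalue.variability import rank_categories

table = load_published_ctt_reference()
ranked = rank_categories(table.rename(columns={"adjusted_cost_usd": "total_cost"}))
agree = (ranked["cost_rank"] == table["cost_rank"]).all()
print(f"re-derived cost ranks match the published ranks: {agree}")

for label, col, top in [("top 3 by cost", "cost_rank", 3),
                        ("top 10 by prioritization score", "priority_rank", 10),
                        ("single costliest category", "cost_rank", 1)]:
    combined, share = cost_shares(table, col, top)
    print(f"{label}: ${combined:,.0f} ({share:.1f}% of all-category cost)")
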