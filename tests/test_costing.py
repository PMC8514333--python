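"""Cost index, standardization, aggregation, resource-intensive decile."""

import numpy as np
import pandas as pd
import pytest

from nicuvalue.costing import (
    aggregate_ctt,
    build_cost_index,
    flag_resource_intensive,
    standardize_costs,
)
from nicuvalue.io import IndexTables, label_billing
from nicuvalue.simulate import default_ctt_map

from conftest import encounter_frame


def _billing(rows):
    return pd.DataFrame(rows, columns=[
        "encounter_id", "day_index", "billing_item", "charge", "units",
        "nicu_day_flag"])


def _encounters(hospital_of):
    return encounter_frame([{"encounter_id": e, "hospital_id": h}
                            for e, h in hospital_of.items()])


def test_cost_index_is_median_of_hospital_medians():
    # hospital-level median unit costs {10, 20, 30} -> 20
    bill = _billing([
        ("E1", 0, "A", 10.0, 1.0, True),
        ("E2", 0, "A", 20.0, 1.0, True),
        ("E3", 0, "A", 30.0, 1.0, True),
        # hospital H1 has several lines; its median is taken first
        ("E1", 1, "A", 1000.0, 100.0, True),
    ])
    enc = _encounters({"E1": "H1", "E2": "H2", "E3": "H3"})
    index = build_cost_index(bill, enc)
    assert index["A"] == 20.0


def test_cost_index_single_hospital_and_even_count_midpoint():
    bill = _billing([
        ("E1", 0, "B", 7.0, 1.0, True),
        ("E1", 0, "C", 10.0, 1.0, True),
        ("E2", 0, "C", 20.0, 1.0, True),
    ])
    enc = _encounters({"E1": "H1", "E2": "H2"})
    index = build_cost_index(bill, enc)
    assert index["B"] == 7.0      # median of one hospital
    assert index["C"] == 15.0     # midpoint convention for even counts


def test_wage_index_divides_charges_before_medians():
    bill = _billing([
        ("E1", 0, "A", 20.0, 1.0, True),
        ("E2", 0, "A", 10.0, 1.0, True),
    ])
    enc = _encounters({"E1": "H1", "E2": "H2"})
    tables = IndexTables(wage_index={"H1": 2.0})
    index = build_cost_index(bill, enc, tables)
    assert index["A"] == 10.0     # H1's 20 deflates to 10


def test_standardize_costs_identity_and_inflation():
    bill = _billing([("E1", 0, "A", 999.0, 2.0, True)])
    bill["year"] = 2015
    index = pd.Series({"A": 20.0})
    out = standardize_costs(bill, index)
    assert out.loc[0, "cost"] == 40.0     # units x unit cost, charge ignored
    infl = IndexTables(inflation_index={2015: 1.1})
    bill2 = _billing([("E1", 0, "A", 0.0, 5.0, True)]).assign(year=2015)
    out2 = standardize_costs(bill2, pd.Series({"A": 20.0}), infl)
    assert out2.loc[0, "cost"] == pytest.approx(110.0)
    with pytest.raises(KeyError, match="2014"):
        standardize_costs(bill2.assign(year=2014), pd.Series({"A": 20.0}), infl)
    with pytest.raises(KeyError, match="cost index"):
        standardize_costs(bill, pd.Series({"B": 1.0}))


def test_identical_utilization_identical_cost_despite_markups():
    """Hospitals billing the same items/units get the same standardized
    costs whatever their markup (here x1 vs x3)."""
    rows = []
    for h, markup in [("H1", 1.0), ("H2", 3.0)]:
        e = f"E{h}"
        rows += [(e, 0, "A", 10.0 * markup, 1.0, True),
                 (e, 1, "B", 30.0 * markup, 2.0, True)]
    bill = _billing(rows)
    enc = _encounters({"EH1": "H1", "EH2": "H2"})
    index = build_cost_index(bill, enc)
    out = standardize_costs(bill, index)
    c1 = out[out["encounter_id"] == "EH1"]["cost"].to_numpy()
    c2 = out[out["encounter_id"] == "EH2"]["cost"].to_numpy()
    assert np.allclose(c1, c2)


def test_standardized_costs_recover_generator_true_costs(small_system):
    """Median-of-medians standardization cancels the hospital markups
    exactly: per-encounter category costs equal the planted true costs."""
    cfg, encounters, billing, truth = small_system
    lab = label_billing(billing, default_ctt_map(cfg))
    nicu = lab[lab["nicu_day_flag"]]
    index = build_cost_index(nicu, encounters)
    costed = standardize_costs(nicu, index)
    enc_costs, totals = aggregate_ctt(costed, encounters)
    wide = enc_costs.pivot(index="encounter_id", columns="ctt_category",
                           values="cost")
    for cat in cfg.categories:
        got = wide[cat].reindex(truth.true_cost.index).fillna(0).to_numpy()
        assert np.allclose(got, truth.true_cost[cat].to_numpy(), rtol=1e-9)
    # cost conservation: per-category totals sum to the line total
    assert totals["total_cost"].sum() == pytest.approx(
        costed["cost"].sum(), rel=1e-12)


def test_aggregate_ctt_small_example_and_empty_category():
    costed = _billing([
        ("E1", 0, "a1", 0, 1.0, True),
        ("E1", 1, "a1", 0, 1.0, True),
        ("E1", 1, "b1", 0, 1.0, True),
    ]).assign(ctt_category=["A", "A", "B"], cost=[10.0, 10.0, 5.0])
    cohort = encounter_frame([{"encounter_id": "E1"}])
    enc_costs, totals = aggregate_ctt(costed, cohort, categories=["A", "B", "C"])
    t = totals.set_index("ctt_category")
    assert t.loc["A", "total_cost"] == 20.0 and t.loc["A", "n_exposed"] == 1
    assert t.loc["B", "total_cost"] == 5.0
    assert t.loc["C", "total_cost"] == 0.0 and t.loc["C", "n_exposed"] == 0
    row = enc_costs.set_index("ctt_category")
    assert row.loc["A", "exposed_days"] == 2
    assert bool(row.loc["C", "exposed"]) is False
    assert t["cumulative_pct_cost"].iloc[-1] == pytest.approx(100.0)


def _flags(costs, quantile=0.90):
    df = pd.DataFrame({"encounter_id": [f"E{i:05d}" for i in range(len(costs))],
                       "total_ctt_cost": costs})
    return flag_resource_intensive(df, quantile)


def test_top_decile_rank_rule_examples():
    out = _flags(list(range(1, 101)))
    flagged = set(out.loc[out["resource_intensive"], "total_ctt_cost"])
    assert flagged == set(range(91, 101))
    # ten equal costs: the rank rule still flags exactly one (last by id)
    out = _flags([5.0] * 10)
    assert out["resource_intensive"].sum() == 1
    assert out.loc[out["resource_intensive"], "encounter_id"].iloc[0] == "E00009"


@pytest.mark.parametrize("n", [10, 11, 19, 100, 101, 9999])
def test_flag_count_is_n_minus_floor(n):
    rng = np.random.default_rng(n)
    out = _flags(rng.exponential(size=n))
    assert out["resource_intensive"].sum() == n - int(np.floor(0.9 * n))


def test_too_few_encounters_rejected():
    with pytest.raises(ValueError):
        _flags([1.0] * 9)
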