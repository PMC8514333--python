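"""Variability statistics, prioritization score, ranks, outliers —
checked against hand arithmetic and brute-force recomputations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nicuvalue.variability import (
    billing_pattern_filter,
    detect_outlier_hospitals,
    exposure_variability,
    prioritization_score,
    rank_categories,
    standardized_distance,
    utilization_variability,
    variability_index,
)


def test_billing_pattern_filter_strict_boundaries():
    rates = pd.Series({"H1": 0.9, "H2": 0.05, "H3": 0.3})
    kept = billing_pattern_filter(rates, 0.2)
    assert set(kept) == {"H2", "H3"}      # 0.9 > 0.8 out; 0.05 == p/4 stays
    rates = pd.Series({"H1": 0.8, "H2": 0.2})
    assert set(billing_pattern_filter(rates, 0.2)) == {"H1", "H2"}  # 4p kept
    assert set(billing_pattern_filter(pd.Series({"H1": 0.2}), 0.2)) == {"H1"}
    with pytest.raises(ValueError):
        billing_pattern_filter(rates, 0.0)


def test_exposure_variability_hand_example():
    """p = {0.5, 0.6, 0.7} at n = 100, population 0.6: the standard
    distances are {-2.0412, 0, 2.0412} and their SD is 2.0412."""
    props = pd.Series({"H1": 0.5, "H2": 0.6, "H3": 0.7})
    sizes = pd.Series({"H1": 100, "H2": 100, "H3": 100})
    ev = exposure_variability(props, sizes, 0.6)
    assert ev == pytest.approx(0.1 / math.sqrt(0.24 / 100), abs=1e-4)
    assert ev == pytest.approx(2.0412, abs=1e-4)


def test_exposure_variability_degenerate_cases():
    sizes = pd.Series({"H1": 50, "H2": 50})
    assert exposure_variability(pd.Series({"H1": 0.3, "H2": 0.3}), sizes,
                                0.3) == 0.0
    with pytest.raises(ValueError):
        exposure_variability(pd.Series({"H1": 0.3}), sizes, 0.3)
    with pytest.raises(ValueError):
        exposure_variability(pd.Series({"H1": 0.3, "H2": 0.4}), sizes, 1.0)


def test_utilization_variability_cv():
    m = pd.Series({"H1": 100.0, "H2": 200.0, "H3": 300.0})
    assert utilization_variability(m) == pytest.approx(0.5)
    assert utilization_variability(2 * m) == pytest.approx(0.5)  # scale-free
    assert utilization_variability(pd.Series({"H1": 5.0, "H2": 5.0})) == 0.0
    with pytest.raises(ValueError):
        utilization_variability(pd.Series({"H1": -2.0, "H2": 0.0}))


def test_variability_index_hand_example():
    ev = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})       # SD = 1
    uv = pd.Series({"a": 0.2, "b": 0.4, "c": 0.6})       # SD = 0.2
    vi = variability_index(ev, uv)
    assert vi["c"] == pytest.approx(math.sqrt(9 + 9), abs=1e-9)
    # order invariance
    perm = ["b", "c", "a"]
    vi2 = variability_index(ev[perm], uv[perm])
    assert vi2["c"] == pytest.approx(vi["c"], abs=1e-12)


def test_prioritization_score_hand_example():
    cost = pd.Series({"a": 10.0, "b": 20.0, "c": 30.0})  # SD = 10
    exp = pd.Series({"a": 0.2, "b": 0.4, "c": 0.6})      # SD = 0.2
    vi = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})       # SD = 1
    ps = prioritization_score(cost, exp, vi)
    assert ps["c"] == pytest.approx(math.sqrt(27), abs=1e-9)
    assert ps["a"] == pytest.approx(math.sqrt(3), abs=1e-9)


def test_zero_components_give_zero_distance_and_degenerate_sd_guard(caplog):
    comp = np.zeros((2, 2))
    assert np.all(standardized_distance(comp, np.array([1.0, 1.0])) == 0.0)
    # constant nonzero component with zero SD contributes nothing, warned
    import logging
    with caplog.at_level(logging.WARNING, logger="nicuvalue"):
        d = standardized_distance(np.array([[3.0, 1.0], [3.0, 2.0]]),
                                  np.array([0.0, 1.0]))
    assert d == pytest.approx([1.0, 2.0])
    assert "zero across-category SD" in caplog.text


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.5, 20.0))
def test_scores_match_brute_force_on_random_tables(seed, cost_scale):
    """VI, PS and all ranks agree with first-principles recomputation on
    random 36-category tables; PS is invariant to rescaling any single
    component."""
    rng = np.random.default_rng(seed)
    k = 36
    table = pd.DataFrame({
        "ctt_category": [f"c{i}" for i in range(k)],
        "total_cost": rng.exponential(1e6, k),
        "pct_exposed": rng.uniform(1, 99, k),
        "exposure_variability": rng.uniform(0.5, 4, k),
        "utilization_variability": rng.uniform(0.05, 1.5, k),
    })
    vi = variability_index(table["exposure_variability"],
                           table["utilization_variability"])
    ps = prioritization_score(table["total_cost"], table["pct_exposed"], vi)

    def sd(x):
        m = sum(x) / len(x)
        return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))

    s_ev = sd(list(table["exposure_variability"]))
    s_uv = sd(list(table["utilization_variability"]))
    for i in range(k):
        expect = math.hypot(table["exposure_variability"][i] / s_ev,
                            table["utilization_variability"][i] / s_uv)
        assert vi.iloc[i] == pytest.approx(expect, abs=1e-12)
    s_c, s_e, s_vi = (sd(list(table["total_cost"])),
                      sd(list(table["pct_exposed"])), sd(list(vi)))
    for i in range(k):
        expect = math.sqrt((table["total_cost"][i] / s_c) ** 2
                           + (table["pct_exposed"][i] / s_e) ** 2
                           + (vi.iloc[i] / s_vi) ** 2)
        assert ps.iloc[i] == pytest.approx(expect, abs=1e-12)

    # rescaling one component across all categories leaves PS unchanged
    ps_scaled = prioritization_score(cost_scale * table["total_cost"],
                                     table["pct_exposed"], vi)
    assert np.allclose(ps_scaled, ps, atol=1e-9)

    ranked = rank_categories(table.assign(variability_index=vi.to_numpy(),
                                          prioritization_score=ps.to_numpy()))
    for col, rank_col in [("total_cost", "cost_rank"),
                          ("prioritization_score", "priority_rank")]:
        vals = list(ranked[col])
        naive = [1 + sum(1 for o in vals if o > v) for v in vals]
        assert list(ranked[rank_col]) == naive


def test_rank_tie_convention():
    t = pd.DataFrame({"ctt_category": ["a", "b", "c"],
                      "prioritization_score": [5.0, 3.0, 5.0]})
    out = rank_categories(t)
    assert list(out["priority_rank"]) == [1, 3, 1]
    single = rank_categories(pd.DataFrame({"ctt_category": ["a"],
                                           "total_cost": [7.0]}))
    assert list(single["cost_rank"]) == [1]


def test_outlier_hospitals_quartile_rule():
    rng = np.random.default_rng(5)
    hospitals = [f"H{i}" for i in range(8)]
    rows = []
    for h in hospitals:
        shift = {"H0": -40.0, "H7": 40.0}.get(h, 0.0)
        for c in rng.normal(50 + shift, 1.0, size=25):
            rows.append({"hospital_id": h, "cost": c})
    df = pd.DataFrame(rows)
    rep = detect_outlier_hospitals(df).set_index("hospital_id")
    q1, q3 = np.percentile(df["cost"], [25, 75])
    for h in hospitals:
        med = df.loc[df["hospital_id"] == h, "cost"].median()
        expect = "high" if med > q3 else ("low" if med < q1 else "none")
        assert rep.loc[h, "outlier"] == expect
    assert rep.loc["H0", "outlier"] == "low"
    assert rep.loc["H7", "outlier"] == "high"


def test_outlier_boundary_is_strict_and_identical_hospitals_are_none():
    df = pd.DataFrame({"hospital_id": np.repeat([f"H{i}" for i in range(4)], 3),
                       "cost": [7.0] * 12})
    rep = detect_outlier_hospitals(df)
    assert (rep["outlier"] == "none").all()   # median == Q1 == Q3 -> none
    with pytest.raises(ValueError):
        detect_outlier_hospitals(df[df["hospital_id"] != "H0"])
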