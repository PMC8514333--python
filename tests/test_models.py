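"""Mixed models, ICC, and indirect standardization."""

import logging

import numpy as np
import pandas as pd
import pytest

from nicuvalue.models import (
    adjusted_hospital_rates,
    compute_icc,
    fit_cost_model,
    fit_resource_intensity_model,
)


def _logistic_data(seed, n_h=40, n_per=650, beta_male=0.5, tau=0.3,
                   base=-1.0):
    rng = np.random.default_rng(seed)
    frames = []
    for h in range(n_h):
        u = rng.normal(0, tau) if tau > 0 else 0.0
        male = rng.random(n_per) < 0.5
        p = 1.0 / (1.0 + np.exp(-(base + beta_male * male + u)))
        frames.append(pd.DataFrame({
            "hospital_id": f"H{h:02d}",
            "sex": np.where(male, "male", "female"),
            "resource_intensive": rng.random(n_per) < p,
        }))
    return pd.concat(frames, ignore_index=True)


def _cost_data(seed, n_h=40, n_per=200, sigma_h=1.0, sigma_e=np.sqrt(3.0)):
    rng = np.random.default_rng(seed)
    frames = []
    for h in range(n_h):
        a = rng.normal(0, sigma_h) if sigma_h > 0 else 0.0
        log_cost = 7.0 + a + rng.normal(0, sigma_e, size=n_per)
        frames.append(pd.DataFrame({
            "hospital_id": f"H{h:02d}",
            "total_ctt_cost": np.expm1(log_cost),
        }))
    return pd.concat(frames, ignore_index=True)


def test_icc_closed_form():
    assert compute_icc(1.0, 3.0) == 0.25
    assert compute_icc(0.0, 2.0) == 0.0
    assert compute_icc(0.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        compute_icc(-1.0, 1.0)


def test_cost_model_without_clustering_finds_near_zero_icc():
    df = _cost_data(0, n_h=20, n_per=100, sigma_h=0.0, sigma_e=1.0)
    result = fit_cost_model(df, covariates=[])
    assert result.icc <= 0.02


def test_cost_model_recovers_planted_variance_split():
    """sigma_h^2 = 1, sigma_e^2 = 3 planted directly on the log scale."""
    df = _cost_data(1)
    result = fit_cost_model(df, covariates=[])
    assert result.icc == pytest.approx(0.25, abs=0.08)
    assert result.sigma_h2 == pytest.approx(1.0, rel=0.5)


def test_cost_model_single_hospital_zero_boundary(caplog):
    df = _cost_data(2, n_h=1, n_per=50, sigma_h=0.0, sigma_e=1.0)
    with caplog.at_level(logging.WARNING, logger="nicuvalue"):
        result = fit_cost_model(df, covariates=[])
    assert result.sigma_h2 == 0.0
    assert "single hospital" in caplog.text


def test_logistic_model_recovers_planted_log_odds_ratio():
    """Planted male log-OR 0.5 at n = 26,000 recovered within 0.15."""
    df = _logistic_data(0)
    result = fit_resource_intensity_model(df, covariates=["sex"],
                                          include_soi=False)
    term = result.params[result.params["term"].str.contains("male")]
    assert np.log(term["estimate"].iloc[0]) == pytest.approx(0.5, abs=0.15)
    assert result.scale == "odds_ratio"


def test_logistic_model_null_interval_coverage():
    """Under a null effect the 95% interval covers OR = 1 in >= 90% of
    20 replicates."""
    covered = 0
    for s in range(20):
        df = _logistic_data(100 + s, n_per=100, beta_male=0.0)
        result = fit_resource_intensity_model(df, covariates=["sex"],
                                              include_soi=False)
        term = result.params[result.params["term"].str.contains("male")]
        covered += bool(term["ci_low"].iloc[0] <= 1.0 <= term["ci_high"].iloc[0])
    assert covered >= 18


def test_logistic_model_single_class_outcome_is_error():
    df = _logistic_data(3, n_h=2, n_per=20)
    df["resource_intensive"] = False
    with pytest.raises(ValueError, match="single class"):
        fit_resource_intensity_model(df, covariates=["sex"], include_soi=False)


def test_logistic_model_single_hospital_zero_boundary(caplog):
    df = _logistic_data(4, n_h=1, n_per=200)
    with caplog.at_level(logging.WARNING, logger="nicuvalue"):
        result = fit_resource_intensity_model(df, covariates=["sex"],
                                              include_soi=False)
    assert result.sigma_h2 == 0.0


def _standardization_data():
    """Two hospitals, binary covariate strata with exposure rates 0.2/0.6.

    Pooled: 100 covariate-0 patients with 20 exposed, 100 covariate-1 with
    60 exposed (mean 0.4).  H1 observes 30 exposures on a 50/50 mix.
    """
    rows = []
    def block(hospital, cov, n, n_exposed):
        for i in range(n):
            rows.append({"hospital_id": hospital, "cov": str(cov),
                         "exposed": float(i < n_exposed)})
    block("H1", 0, 50, 10)
    block("H1", 1, 50, 20)
    block("H2", 0, 50, 10)
    block("H2", 1, 50, 40)
    return pd.DataFrame(rows)


def test_indirect_standardization_hand_example():
    df = _standardization_data()
    out = adjusted_hospital_rates(df, "exposed", covariates=["cov"])
    h1 = out.set_index("hospital_id").loc["H1"]
    # E = 50 x 0.2 + 50 x 0.6 = 40; adjusted = 30/40 x 0.4 = 0.30
    assert h1["expected_mean"] == pytest.approx(0.40)
    assert h1["oe_ratio"] == pytest.approx(0.75)
    assert h1["adjusted"] == pytest.approx(0.30)
    # a hospital whose case mix equals the pooled mix: adjusted = observed
    h2 = out.set_index("hospital_id").loc["H2"]
    assert h2["adjusted"] == pytest.approx(h2["observed_mean"])


def test_intercept_only_adjustment_returns_observed():
    df = _standardization_data()
    out = adjusted_hospital_rates(df, "exposed")
    assert np.allclose(out["adjusted"], out["observed_mean"])


def test_adjustment_is_calibration_preserving():
    """Expected-count-weighted mean of adjusted values equals the pooled
    mean whenever all hospitals are retained."""
    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "hospital_id": rng.choice([f"H{i}" for i in range(8)], size=2000),
        "cov": rng.choice(["a", "b", "c"], size=2000),
    })
    p = df["cov"].map({"a": 0.2, "b": 0.5, "c": 0.7})
    df["exposed"] = (rng.random(2000) < p).astype(float)
    out = adjusted_hospital_rates(df, "exposed", covariates=["cov"])
    weighted = np.average(out["adjusted"],
                          weights=out["expected_mean"] * out["n"])
    assert weighted == pytest.approx(df["exposed"].mean(), abs=1e-6)


def test_zero_expected_hospital_dropped_with_warning(caplog):
    df = pd.DataFrame({
        "hospital_id": ["H1"] * 4 + ["H2"] * 4,
        "cov": ["a"] * 4 + ["b"] * 4,
        "cost": [0.0] * 4 + [10.0, 10.0, 12.0, 8.0],
    })
    with caplog.at_level(logging.WARNING, logger="nicuvalue"):
        out = adjusted_hospital_rates(df, "cost", covariates=["cov"],
                                      binary=False)
    assert list(out["hospital_id"]) == ["H2"]
    assert "zero expected" in caplog.text
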