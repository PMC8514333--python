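"""Shared fixtures: a small simulated hospital system and row builders."""

from __future__ import annotations

import pandas as pd
import pytest

from nicuvalue.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_hospitals=6, patients_per_hospital=120, seed=11)


@pytest.fixture(scope="session")
def small_system(small_config):
    """(config, encounters, billing, truth) for a 6-hospital system."""
    encounters, billing, truth = generate(small_config)
    return small_config, encounters, billing, truth


def make_encounter(**overrides) -> dict:
    """One fully valid encounter row; override any field."""
    row = {
        "encounter_id": "E1",
        "hospital_id": "H1",
        "sex": "female",
        "gestational_age_weeks": 28,
        "birth_weight_g": 1100,
        "ga_category": "27-28",
        "bw_category": "1000-1249",
        "race_ethnicity": "non_hispanic_white",
        "admission_source": "inborn",
        "age_at_admission_days": 0,
        "insurance": "commercial",
        "income_quartile": 2,
        "disposition": "home",
        "apr_drg": "602",
        "nicu_days": 30,
        "diagnosis_codes": "P22.0",
    }
    row.update(overrides)
    return row


def encounter_frame(rows: list[dict]) -> pd.DataFrame:
    out = []
    for i, r in enumerate(rows):
        row = make_encounter(encounter_id=f"E{i + 1}")
        row.update(r)
        out.append(row)
    return pd.DataFrame(out)
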