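import numpy as np
import pandas as pd
import pytest

from selectqba.synth import ExposureSpec, SimulationConfig, simulate_study


def make_persons(rows: list[dict]) -> pd.DataFrame:
    """Small persons table with sensible defaults per row."""
    defaults = {
        "underlying_cause_icd10": "X72",
        "death_date": pd.Timestamp("2010-06-15"),
        "sex": "male",
        "age_years": 45.0,
        "death_year": 2010,
        "marital_status": "married/partner",
        "education": "some college",
        "urbanicity": "large metro",
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"person_id": f"p{i:04d}", **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic study (cases + selected controls) shared by tests."""
    cfg = SimulationConfig(
        n_cases=2000,
        n_controls_target=1000,
        control_pool_multiplier=2.0,
        exposure_specs=[
            ExposureSpec("suicidal ideation/attempt", 0.05, 3.0, selection_rr=1.5),
            ExposureSpec("mental illness", 0.10, 2.0),
            ExposureSpec("chronic disease", 0.20, 1.0),
        ],
        seed=11,
    )
    return cfg, simulate_study(cfg)
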