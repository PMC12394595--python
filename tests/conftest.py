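import numpy as np
import pandas as pd
import pytest

from screenhet.cohort import COLUMN_ORDER, Cohort
from screenhet.simulate import nelson_like_config, simulate_cohort


def make_records(n=6, **overrides) -> pd.DataFrame:
    """A small fully-populated, invariant-satisfying record table."""
    base = {
        "id": [f"P{i:03d}" for i in range(n)],
        "trial": "TOY",
        "arm": ["CT", "control"] * (n // 2) + ["CT"] * (n % 2),
        "center": "C1",
        "age": 60.0,
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "race_ethnicity": "white",
        "education": 3.0,
        "bmi": 26.0,
        "smoking_status": "current",
        "cigs_per_day": 20.0,
        "years_smoked": 40.0,
        "pack_years": 40.0,
        "years_quit": 0.0,
        "copd": False,
        "emphysema": False,
        "personal_cancer_history": False,
        "family_lc_history": False,
        "followup_years": 10.0,
        "lc_diagnosis": False,
        "lc_diagnosis_time": np.nan,
        "histology": "none",
        "stage_group": "none",
        "detection_mode": "none",
        "lc_death": False,
        "lc_death_time": np.nan,
    }
    df = pd.DataFrame({c: base[c] for c in COLUMN_ORDER} | {"id": base["id"]})
    df = df[list(COLUMN_ORDER)]
    for col, vals in overrides.items():
        df[col] = vals
    for col in ("copd", "emphysema", "personal_cancer_history",
                "family_lc_history", "lc_diagnosis", "lc_death"):
        df[col] = df[col].astype("boolean")
    return df


def make_cohort(n=6, followup_cap=10.0, **overrides) -> Cohort:
    return Cohort(make_records(n, **overrides), trial="TOY",
                  followup_cap=followup_cap)


@pytest.fixture(scope="session")
def nelson_small():
    """One NELSON-like simulated trial (session-cached for speed)."""
    return simulate_cohort(nelson_like_config(n_per_arm=1500, seed=7))


@pytest.fixture(scope="session")
def nelson_mid():
    """A larger NELSON-like trial for model-level checks."""
    return simulate_cohort(nelson_like_config(n_per_arm=5000, seed=11))
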