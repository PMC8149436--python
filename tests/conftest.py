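import numpy as np
import pandas as pd
import pytest

from lbwpath import apply_missingness, build_default_config, generate_cohort

SCHEMA_DEFAULTS = {
    "year": 2011,
    "quarter": 1,
    "maternal_age": 25.0,
    "age_band": "20-29",
    "residence": "urban",
    "education_none": 0,
    "has_partner": 1,
    "wealth_band": "poorer",
    "birth_order_band": "2-4",
    "multiple_birth": 0,
    "prior_loss": 0,
    "child_sex": "male",
    "facility_delivery": 1,
    "facility_sector": "public",
    "birth_weight_kg": 3.0,
    "stillbirth": 0,
    "death_day": np.nan,
}


def make_births(n, stillbirths=0, day01=0, day26=0, day727=0, **overrides):
    """Schema-complete cohort table with the requested death structure."""
    df = pd.DataFrame({k: [v] * n for k, v in SCHEMA_DEFAULTS.items()})
    for k, v in overrides.items():
        df[k] = v
    i = 0
    df.loc[: stillbirths - 1, "stillbirth"] = 1 if stillbirths else df["stillbirth"]
    i += stillbirths
    for count, day in [(day01, 0), (day26, 3), (day727, 10)]:
        if count:
            df.loc[i : i + count - 1, "death_day"] = float(day)
            i += count
    return df


@pytest.fixture(scope="session")
def default_config():
    return build_default_config()


@pytest.fixture(scope="session")
def cohort_10k(default_config):
    """One fully observed default cohort at the study size."""
    return generate_cohort(default_config, seed=42)


@pytest.fixture(scope="session")
def masked_cohort(default_config, cohort_10k):
    return apply_missingness(cohort_10k, default_config, seed=43)


@pytest.fixture(scope="session")
def small_config(default_config):
    cfg = build_default_config(n_births=3000)
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=7)
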