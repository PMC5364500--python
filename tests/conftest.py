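import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def builtin_specs():
    from cvdrisk import builtin_recalibrated_specs
    return builtin_recalibrated_specs()


def make_cohort(n=200, seed=0, sex=None, event_rate=0.2, followup_max=6.0):
    """Small hand-rolled cohort with plausible covariates and outcomes,
    independent of the package's generator."""
    rng = np.random.default_rng(seed)
    sexes = np.array([sex] * n) if sex else rng.choice(["male", "female"], n)
    t_event = rng.exponential(-followup_max / np.log(1 - event_rate), n)
    cvd = t_event <= followup_max
    df = pd.DataFrame({
        "id": [f"H{i:05d}" for i in range(n)],
        "sex": sexes,
        "age": rng.uniform(40, 65, n).round(1),
        "total_cholesterol": rng.uniform(3.0, 7.0, n).round(2),
        "hdl": rng.uniform(0.7, 2.0, n).round(2),
        "glucose": rng.uniform(4.0, 8.0, n).round(2),
        "sbp": rng.uniform(95, 185, n).round(0),
        "bmi": rng.uniform(18, 35, n).round(1),
        "bp_treated": rng.integers(0, 2, n),
        "current_smoker": rng.integers(0, 2, n),
        "diabetes": rng.integers(0, 2, n),
        "followup_years": np.where(cvd, t_event, followup_max).round(4),
        "cvd_death": cvd.astype(int),
    })
    df["followup_years"] = np.maximum(df["followup_years"], 0.01)
    df["all_cause_death"] = df["cvd_death"]
    return df


@pytest.fixture
def small_cohort():
    return make_cohort(n=200, seed=42)


@pytest.fixture
def male_cohort():
    return make_cohort(n=300, seed=7, sex="male")
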