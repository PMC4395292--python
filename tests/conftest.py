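import numpy as np
import pandas as pd
import pytest

from medsuppress.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One moderately sized synthetic cohort shared across read-only tests."""
    config = SyntheticConfig(n=2000, seed=11)
    df, panel = simulate_cohort(config)
    return config, df, panel


@pytest.fixture()
def tiny_table():
    """Hand-written 6-row phenotype table covering classifier edge cases."""
    return pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(1, 7)],
            "age": [30.0, 45, 17, 60, 50, 40],
            "sex": [0.0, 1, 0, 1, 0, 1],
            "current_smoker": [False, False, False, True, False, False],
            "sbp": [118.0, 128, 120, 135, 140, 110],
            "dbp": [75.0, 80, 70, 88, 92, 70],
            "total_chol": [180.0, 200, 190, 210, 220, 170],
            "hdl": [55.0, 38, 60, 45, 39, 62],
            "ldl": [100.0, 120, 110, 130, 140, 90],
            "triglycerides": [120.0, 160, 100, 150, 180, 90],
            "bmi": [22.0, 27, 21, 25.0, 30, 20],
            "waist": [80.0, 85, 75, 92, 95, 70],
            "glucose_fasting": [90.0, 105, 85, 100, 126, 80],
            "insulin_fasting": [6.0, 12, 5, 10, 15, 4],
            "adiponectin": [8.0, 5, 9, 6, 4, 12],
            "on_htn_med": [False] * 6,
            "on_dm_med": [False, False, False, False, True, False],
            "on_lipid_med": [False] * 6,
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
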