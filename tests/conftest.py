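import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_cohort(los, survived, age=None, sex=None, order=None,
                label="test") -> pd.DataFrame:
    """Build a canonical in-memory cohort table from plain lists."""
    n = len(los)
    df = pd.DataFrame({
        "patient_id": pd.array([f"P{i:04d}" for i in range(n)], dtype="string"),
        "admission_id": pd.array([f"A{i:04d}" for i in range(n)], dtype="string"),
        "admission_order": pd.array(order if order is not None else [1] * n,
                                    dtype="Int64"),
        "age_years": np.asarray(age if age is not None else [60.0] * n,
                                dtype=float),
        "sex": pd.array(sex if sex is not None else ["male"] * n,
                        dtype="string"),
        "icu_los_days": np.asarray(los, dtype=float),
        "survived_to_discharge": pd.array(survived, dtype="boolean"),
    })
    df.attrs["label"] = label
    return df


@pytest.fixture
def small_cohort():
    return make_cohort(los=[1.0, 2.0, 3.0, 5.0],
                       survived=[True, True, False, True])


@pytest.fixture
def csv_cohort(tmp_path):
    """A valid 3-row cohort CSV on disk with default headers."""
    path = tmp_path / "cohort.csv"
    path.write_text(
        "patient_id,admission_id,admission_order,age_years,sex,"
        "icu_los_days,survived_to_discharge\n"
        "p1,a1,1,64.0,male,1.9,1\n"
        "p2,a2,1,70.5,female,0.8,0\n"
        "p3,a3,1,55.0,male,4.2,true\n")
    return path
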