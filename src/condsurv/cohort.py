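"""Reading, validating, and filtering admission-level cohort tables.

A cohort is a :class:`pandas.DataFrame` with one row per ICU admission and the
canonical columns

=======================  =======================================================
``patient_id``           opaque identifier (string)
``admission_id``         opaque identifier (string)
``admission_order``      1 = the patient's first ICU admission (nullable int)
``age_years``            age at ICU admission, years (float)
``sex``                  ``male`` / ``female`` / ``other`` (string, may be NA)
``icu_los_days``         ICU length of stay in days, fractional allowed (float)
``survived_to_discharge`` vital status at *hospital* discharge (nullable bool)
=======================  =======================================================

Inclusion criteria follow the source cohorts: adults (age >= 18) at their
first (index) ICU admission with a recorded vital status at hospital
discharge.  Criteria are applied sequentially (age, then index admission,
then missing data) so that every excluded record is attributed to exactly
one criterion and the exclusion report counts sum to the raw count.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import CohortValidationError, EmptyCohortError, SchemaError

#: Canonical column names expected by every downstream operation.
COLUMNS = (
    "patient_id",
    "admission_id",
    "admission_order",
    "age_years",
    "sex",
    "icu_los_days",
    "survived_to_discharge",
)

#: Columns a table must provide (admission_order and sex are optional).
REQUIRED_COLUMNS = (
    "patient_id",
    "admission_id",
    "age_years",
    "icu_los_days",
    "survived_to_discharge",
)

_TRUE_TOKENS = {"1", "true", "t", "yes", "y", "alive", "survived"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", "dead", "died", "deceased"}

_SEX_MAP = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "2": "female",
}


@dataclasses.dataclass(frozen=True)
class ExclusionReport:
    """Flow-chart accounting of records removed by each inclusion criterion.

    ``pct_excluded_missing`` uses the included-plus-missing denominator
    (``100 * n_excluded_missing / (n_included + n_excluded_missing)``),
    the convention under which the source cohorts' printed percentages
    reproduce, rounded to one decimal.
    """

    n_raw: int
    n_excluded_age: int
    n_excluded_not_index: int
    n_excluded_missing: int
    n_included: int

    def __post_init__(self) -> None:
        total = (self.n_included + self.n_excluded_age
                 + self.n_excluded_not_index + self.n_excluded_missing)
        if total != self.n_raw:
            raise ValueError(
                f"exclusion counts sum to {total}, expected n_raw={self.n_raw}")

    @property
    def pct_excluded_missing(self) -> float:
        denom = self.n_included + self.n_excluded_missing
        if denom == 0:
            return 0.0
        return round(100.0 * self.n_excluded_missing / denom, 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pct_excluded_missing"] = self.pct_excluded_missing
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics for a (filtered) cohort.

    Continuous variables are summarised as median and IQR (25th/75th
    percentiles, linear interpolation); binary variables as percentages.
    """

    n: int
    median_age: float
    iqr_age: tuple[float, float]
    pct_male: float
    median_los: float
    iqr_los: tuple[float, float]
    pct_survived: float
    label: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iqr_age"] = list(self.iqr_age)
        d["iqr_los"] = list(self.iqr_los)
        return d


def _parse_vital_status(values: pd.Series) -> pd.Series:
    """Map a raw vital-status column to nullable booleans.

    Unparseable or empty entries become ``pd.NA`` (missing), never an error:
    missingness is an exclusion criterion, not a schema violation.
    """
    def one(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, np.integer, float, np.floating)):
            if v == 1:
                return True
            if v == 0:
                return False
            return pd.NA
        s = str(v).strip().lower()
        if s in _TRUE_TOKENS:
            return True
        if s in _FALSE_TOKENS:
            return False
        return pd.NA

    return values.map(one).astype("boolean")


def _parse_sex(values: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v):
            return pd.NA
        s = str(v).strip().lower()
        return _SEX_MAP.get(s, "other")

    return values.map(one).astype("string")


def read_cohort(path: str | Path,
                column_map: Mapping[str, str] | None = None,
                label: str | None = None) -> pd.DataFrame:
    """Read an admission-level CSV into the canonical cohort table.

    Parameters
    ----------
    path
        CSV file (RFC-4180, UTF-8, header row required).
    column_map
        Optional mapping from *source* column names to canonical field
        names, for files whose headers differ from the defaults.
    label
        Cohort name stored in ``df.attrs["label"]`` (defaults to the
        file stem).

    Raises
    ------
    SchemaError
        if a required (mapped) column is absent.
    CohortValidationError
        if any row has negative LOS or negative age; the message cites the
        zero-based row index.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}")
    return validate_cohort(raw, label=label if label is not None else path.stem)


def validate_cohort(raw: pd.DataFrame, label: str = "") -> pd.DataFrame:
    """Coerce a raw table to canonical dtypes and enforce record invariants."""
    df = pd.DataFrame(index=pd.RangeIndex(len(raw)))
    df["patient_id"] = raw["patient_id"].astype("string").values
    df["admission_id"] = raw["admission_id"].astype("string").values
    if "admission_order" in raw.columns:
        order = pd.to_numeric(raw["admission_order"], errors="coerce")
        df["admission_order"] = order.round().astype("Int64").values
    else:
        df["admission_order"] = pd.array([pd.NA] * len(raw), dtype="Int64")
    df["age_years"] = pd.to_numeric(raw["age_years"], errors="coerce").values
    if "sex" in raw.columns:
        df["sex"] = _parse_sex(raw["sex"]).values
    else:
        df["sex"] = pd.array([pd.NA] * len(raw), dtype="string")
    df["icu_los_days"] = pd.to_numeric(raw["icu_los_days"], errors="coerce").values
    df["survived_to_discharge"] = _parse_vital_status(
        raw["survived_to_discharge"]).values

    for col, name in (("icu_los_days", "ICU length of stay"),
                      ("age_years", "age")):
        bad = np.where(df[col].values < 0)[0]
        if bad.size:
            raise CohortValidationError(
                f"negative {name} at row {bad[0]}: {df[col].iloc[bad[0]]!r}")

    dup = df.duplicated(subset=["patient_id", "admission_id"])
    if dup.any():
        raise CohortValidationError(
            f"duplicate (patient_id, admission_id) at row {int(np.flatnonzero(dup)[0])}")

    df.attrs["label"] = label
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical cohort table back to CSV (round-trips through
    :func:`read_cohort` for finite values)."""
    out = cohort.copy()
    # booleans as 1/0/empty so the file is dialect-stable
    sv = out["survived_to_discharge"]
    out["survived_to_discharge"] = sv.map(
        lambda v: "" if pd.isna(v) else ("1" if v else "0"))
    out.to_csv(path, index=False)


def apply_inclusion_criteria(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the inclusion criteria sequentially with full accounting.

    Order of exclusion (each record counted once, under the first criterion
    it fails):

    1. age under 18 at ICU admission;
    2. not the patient's index (first) ICU admission — by ``admission_order``
       where present, otherwise the record with the lexicographically
       smallest ``admission_id`` per patient is kept;
    3. missing vital status at hospital discharge, missing age, or missing
       length of stay.

    Records with missing sex are retained (sex is descriptive only).

    Returns the filtered cohort and an :class:`ExclusionReport`.

    Raises
    ------
    EmptyCohortError
        if the raw table has no rows.
    """
    if len(raw) == 0:
        raise EmptyCohortError("raw cohort table has no records")

    n_raw = len(raw)
    df = raw

    # 1. adults only; records with missing age are not attributable here
    # (they fall under the missing-data criterion below)
    age = df["age_years"]
    fail_age = (age < 18).fillna(False).astype(bool)
    n_age = int(fail_age.sum())
    df = df[~fail_age]

    # 2. index admission
    order = df["admission_order"]
    if order.notna().any():
        fail_index = order.notna() & (order != 1)
    else:
        first_id = df.groupby("patient_id")["admission_id"].transform("min")
        fail_index = df["admission_id"] != first_id
    fail_index = fail_index.astype(bool)
    n_index = int(fail_index.sum())
    df = df[~fail_index]

    # 3. missing data on analysis variables
    fail_missing = (df["survived_to_discharge"].isna()
                    | df["age_years"].isna()
                    | df["icu_los_days"].isna())
    n_missing = int(fail_missing.sum())
    df = df[~fail_missing]

    included = df.reset_index(drop=True).copy()
    included.attrs["label"] = raw.attrs.get("label", "")
    report = ExclusionReport(
        n_raw=n_raw,
        n_excluded_age=n_age,
        n_excluded_not_index=n_index,
        n_excluded_missing=n_missing,
        n_included=len(included),
    )
    return included, report


def summarize_cohort(cohort: pd.DataFrame, label: str | None = None) -> CohortSummary:
    """Median/IQR of age and LOS, percentage male, percentage surviving, n."""
    if len(cohort) == 0:
        raise EmptyCohortError("cannot summarise an empty cohort")
    age = cohort["age_years"].to_numpy(dtype=float)
    los = cohort["icu_los_days"].to_numpy(dtype=float)
    sex = cohort["sex"]
    surv = cohort["survived_to_discharge"]
    q_age = np.percentile(age, [25, 50, 75])
    q_los = np.percentile(los, [25, 50, 75])
    return CohortSummary(
        n=len(cohort),
        median_age=float(q_age[1]),
        iqr_age=(float(q_age[0]), float(q_age[2])),
        pct_male=float(100.0 * (sex == "male").sum() / len(cohort)),
        median_los=float(q_los[1]),
        iqr_los=(float(q_los[0]), float(q_los[2])),
        pct_survived=float(100.0 * (surv == True).sum() / len(cohort)),  # noqa: E712
        label=label if label is not None else cohort.attrs.get("label", ""),
    )
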