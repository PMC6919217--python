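"""Cohort reading, validation, inclusion criteria, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from condsurv.cohort import (apply_inclusion_criteria, read_cohort,
                             summarize_cohort, validate_cohort, write_cohort)
from condsurv.exceptions import (CohortValidationError, EmptyCohortError,
                                 SchemaError)

from conftest import make_cohort


class TestReadCohort:
    def test_parses_three_row_csv(self, csv_cohort):
        df = read_cohort(csv_cohort)
        assert len(df) == 3
        assert df["age_years"].tolist() == [64.0, 70.5, 55.0]
        assert df["icu_los_days"].tolist() == [1.9, 0.8, 4.2]
        assert df["survived_to_discharge"].tolist() == [True, False, True]
        assert df.attrs["label"] == "cohort"

    def test_empty_vital_status_becomes_missing(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,admission_id,age_years,icu_los_days,"
                     "survived_to_discharge\np1,a1,60,2.0,\np2,a2,61,1.0,1\n")
        df = read_cohort(p)
        assert df["survived_to_discharge"].isna().tolist() == [True, False]

    def test_unparseable_vital_status_becomes_missing(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,admission_id,age_years,icu_los_days,"
                     "survived_to_discharge\np1,a1,60,2.0,unknown\n")
        assert read_cohort(p)["survived_to_discharge"].isna().all()

    def test_negative_los_raises_with_row_index(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,admission_id,age_years,icu_los_days,"
                     "survived_to_discharge\np1,a1,60,2.0,1\np2,a2,61,-1,0\n")
        with pytest.raises(CohortValidationError, match="row 1"):
            read_cohort(p)

    def test_missing_column_raises_schema_error_naming_it(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,admission_id,age_years,icu_los_days\n"
                     "p1,a1,60,2.0\n")
        with pytest.raises(SchemaError, match="survived_to_discharge"):
            read_cohort(p)

    def test_column_map_renames_source_headers(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("pid,aid,age,los,dead_or_alive\np1,a1,60,2.0,1\n")
        df = read_cohort(p, column_map={
            "pid": "patient_id", "aid": "admission_id", "age": "age_years",
            "los": "icu_los_days", "dead_or_alive": "survived_to_discharge"})
        assert df["survived_to_discharge"].tolist() == [True]

    def test_duplicate_patient_admission_pair_rejected(self):
        df = make_cohort([1, 2], [True, True])
        df["admission_id"] = pd.array(["A1", "A1"], dtype="string")
        df["patient_id"] = pd.array(["P1", "P1"], dtype="string")
        with pytest.raises(CohortValidationError, match="duplicate"):
            validate_cohort(df)

    def test_csv_round_trip_preserves_fields(self, tmp_path):
        df = make_cohort(los=[1.25, 0.0, 4.75], survived=[True, None, False],
                         age=[18.0, 91.5, 64.0],
                         sex=["male", "female", None])
        out = tmp_path / "rt.csv"
        write_cohort(df, out)
        back = read_cohort(out)
        for col in ("patient_id", "admission_id", "age_years", "icu_los_days"):
            assert back[col].tolist() == df[col].tolist()
        assert back["survived_to_discharge"].fillna(False).tolist() == \
            df["survived_to_discharge"].fillna(False).tolist()
        assert back["survived_to_discharge"].isna().tolist() == \
            df["survived_to_discharge"].isna().tolist()


class TestInclusionCriteria:
    def test_age_boundary_is_inclusive_at_18(self):
        df = make_cohort([1, 1, 1], [True] * 3, age=[17.9, 18.0, 80.0])
        kept, rep = apply_inclusion_criteria(df)
        assert rep.n_excluded_age == 1
        assert rep.n_included == 2
        assert kept["age_years"].min() == 18.0

    def test_only_index_admission_retained(self):
        df = make_cohort([1, 2, 3], [True] * 3, order=[1, 2, 3])
        df["patient_id"] = pd.array(["P1"] * 3, dtype="string")
        kept, rep = apply_inclusion_criteria(df)
        assert len(kept) == 1
        assert kept["admission_order"].tolist() == [1]
        assert rep.n_excluded_not_index == 2

    def test_missing_order_falls_back_to_smallest_admission_id(self):
        df = make_cohort([1, 2], [True, True], order=[None, None])
        df["patient_id"] = pd.array(["P1", "P1"], dtype="string")
        df["admission_id"] = pd.array(["A2", "A1"], dtype="string")
        kept, _ = apply_inclusion_criteria(df)
        assert kept["admission_id"].tolist() == ["A1"]

    def test_missing_vital_status_excluded_and_pct_uses_included_plus_missing(self):
        # 8 complete + 2 missing -> 20.0% on the included+missing denominator
        df = make_cohort([1] * 10, [True] * 8 + [None, None])
        kept, rep = apply_inclusion_criteria(df)
        assert len(kept) == 8
        assert rep.n_excluded_missing == 2
        assert rep.pct_excluded_missing == 20.0

    def test_missing_sex_does_not_exclude(self):
        df = make_cohort([1, 2], [True, True], sex=[None, "male"])
        kept, _ = apply_inclusion_criteria(df)
        assert len(kept) == 2

    def test_counts_attributed_to_first_failing_criterion(self):
        # under-age record with missing status counts under age, not missing
        df = make_cohort([1, 1], [None, True], age=[10.0, 60.0])
        _, rep = apply_inclusion_criteria(df)
        assert rep.n_excluded_age == 1
        assert rep.n_excluded_missing == 0

    def test_empty_table_raises(self):
        with pytest.raises(EmptyCohortError):
            apply_inclusion_criteria(make_cohort([], []))

    @given(st.lists(st.tuples(
        st.floats(min_value=0, max_value=110, allow_nan=False),
        st.floats(min_value=0, max_value=60, allow_nan=False),
        st.sampled_from([True, False, None]),
        st.integers(min_value=1, max_value=3)), min_size=1, max_size=40))
    def test_conservation_and_idempotence(self, rows):
        """Counts sum to n_raw; filtering twice equals filtering once."""
        age, los, surv, order = zip(*rows)
        df = make_cohort(list(los), list(surv), age=list(age),
                         order=list(order))
        kept, rep = apply_inclusion_criteria(df)
        assert (rep.n_included + rep.n_excluded_age + rep.n_excluded_not_index
                + rep.n_excluded_missing) == rep.n_raw == len(df)
        if len(kept):
            again, rep2 = apply_inclusion_criteria(kept)
            assert rep2.n_included == rep.n_included
            assert rep2.n_excluded_age == rep2.n_excluded_not_index == \
                rep2.n_excluded_missing == 0
            pd.testing.assert_frame_equal(again, kept)


class TestSummarize:
    def test_three_point_median_and_iqr(self):
        df = make_cohort([1, 1, 1], [True] * 3, age=[50.0, 64.0, 74.0])
        s = summarize_cohort(df)
        assert s.median_age == 64.0
        assert s.iqr_age == (57.0, 69.0)

    def test_survival_percentage(self):
        df = make_cohort([1.0] * 1000, [True] * 815 + [False] * 185)
        assert summarize_cohort(df).pct_survived == pytest.approx(81.5)

    def test_all_male_cohort(self):
        df = make_cohort([1, 2], [True, True], sex=["male", "male"])
        assert summarize_cohort(df).pct_male == 100.0

    def test_empty_cohort_raises(self):
        with pytest.raises(EmptyCohortError):
            summarize_cohort(make_cohort([], []))
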