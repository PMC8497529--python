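"""Model feature construction: rolling windows, age arithmetic, full vectors."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phenocopd import (
    SimConfig,
    age_at_first_code,
    build_datamart,
    build_feature_table,
    extract_cohort,
    generate,
    rolling_window_flag,
)
from phenocopd.features import FEATURE_COLUMNS
from .conftest import make_dx


def _days(*offsets):
    return [pd.Timestamp("2020-01-01") + pd.Timedelta(days=d) for d in offsets]


class TestRollingWindow:
    def test_span_inside_window(self):
        assert rolling_window_flag(_days(0, 100, 200), k=3, window_days=365) == 1

    def test_span_outside_window(self):
        assert rolling_window_flag(_days(0, 200, 400), k=3, window_days=365) == 0

    def test_inclusive_endpoint_boundary(self):
        assert rolling_window_flag(_days(0, 100, 364), k=3, window_days=365) == 1
        assert rolling_window_flag(_days(0, 100, 365), k=3, window_days=365) == 0

    def test_duplicate_dates_count_once(self):
        assert rolling_window_flag(_days(0, 0, 0), k=3, window_days=365) == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            rolling_window_flag(_days(0), k=0, window_days=365)

    def test_agrees_with_exhaustive_triple_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(0, 10))
            dates = _days(*rng.integers(0, 800, size=n))
            uniq = sorted(set(dates))
            oracle = int(any((c - a).days <= 364 for a, _, c in combinations(uniq, 3)))
            assert rolling_window_flag(dates, k=3, window_days=365) == oracle


class TestAgeAtFirstCode:
    def test_forced_arithmetic(self, codesets):
        dx = make_dx([("P", "2015-06-01", "496", "ICD9")])
        assert age_at_first_code(pd.Timestamp("1950-01-01"), dx, codesets["specific"]) == 65

    def test_code_on_birth_date(self, codesets):
        dx = make_dx([("P", "1950-01-01", "496", "ICD9")])
        assert age_at_first_code(pd.Timestamp("1950-01-01"), dx, codesets["specific"]) == 0

    def test_no_matching_code_is_an_error(self, codesets):
        dx = make_dx([("P", "2015-06-01", "401.9", "ICD9")])
        with pytest.raises(ValueError, match="no diagnosis matches"):
            age_at_first_code(pd.Timestamp("1950-01-01"), dx, codesets["specific"])

    def test_agrees_with_date_arithmetic_oracle(self, codesets):
        rng = np.random.default_rng(11)
        for _ in range(50):
            birth = pd.Timestamp("1940-01-01") + pd.Timedelta(days=int(rng.integers(0, 365 * 30)))
            first = birth + pd.Timedelta(days=int(rng.integers(0, 365 * 70)))
            later = first + pd.Timedelta(days=int(rng.integers(1, 1000)))
            dx = make_dx([("P", later, "J44.9", "ICD10"), ("P", first, "496", "ICD9")])
            oracle = int(np.floor((first - birth).days / 365.25))
            assert age_at_first_code(birth, dx, codesets["specific"]) == oracle


def _pipeline_tables(cohort, codesets):
    mart = build_datamart(cohort, codesets)
    ratios, smoking = extract_cohort(cohort)
    return build_feature_table(cohort, mart, codesets, ratios, smoking)


def test_hand_built_patient_matches_expected_vector(codesets):
    """One patient assembled feature-by-feature against a hand-computed vector."""
    from phenocopd.ehr_data import Cohort, _empty_table

    c = Cohort.empty()
    c.patients.loc[0] = {"patient_id": "P1", "birth_date": pd.Timestamp("1950-01-01"),
                         "race": "Black", "sex": "M"}
    c.diagnoses = make_dx([
        ("P1", "2015-06-01", "496", "ICD9", "pulmonary"),     # first specific code, age 65
        ("P1", "2015-07-01", "J44.9", "ICD10", "primary_care"),
        ("P1", "2015-08-01", "491.0", "ICD9", "other"),       # broad + bronchitis
        ("P1", "2015-08-01", "491.0", "ICD9", "other"),       # same date: counts once
        ("P1", "2016-01-01", "494.0", "ICD9", "other"),       # bronchiectasis
        ("P1", "2016-02-01", "401.9", "ICD9", "other"),       # filler
    ])
    c.medications = pd.DataFrame([
        {"patient_id": "P1", "date": pd.Timestamp("2015-06-15"), "drug_name": "Tiotropium Bromide",
         "drug_code": "RX1", "med_class": "LAMA"},
        {"patient_id": "P1", "date": pd.Timestamp("2015-09-15"), "drug_name": "tiotropium bromide",
         "drug_code": "RX1", "med_class": "LAMA"},  # duplicate code: distinct count stays 1
    ])
    c.encounters = pd.DataFrame([
        {"patient_id": "P1", "date": pd.Timestamp("2015-06-01"), "has_coded_dx": True},
        {"patient_id": "P1", "date": pd.Timestamp("2015-07-01"), "has_coded_dx": True},
        {"patient_id": "P1", "date": pd.Timestamp("2015-08-01"), "has_coded_dx": False},
    ])
    c.notes = pd.DataFrame([
        {"patient_id": "P1", "date": pd.Timestamp("2015-06-20"), "note_type": "pft_report",
         "text": "Post-bronchodilator FEV1/FVC: 64%"},
        {"patient_id": "P1", "date": pd.Timestamp("2015-06-25"), "note_type": "clinic_note",
         "text": "30 pack-year smoking history."},
    ])
    c.spirometry = pd.DataFrame([
        {"patient_id": "P1", "date": pd.Timestamp("2015-06-20"), "ratio": 0.64,
         "phase": "post_bronchodilator", "source": "structured"},
    ])

    table = _pipeline_tables(c, codesets).set_index("patient_id")
    expected = {
        "everPFTlt70": 1,          # 0.64 < 0.7
        "nCOPDGTE3_365": 1,        # 2015-06-01/07-01/08-01 within 365 days
        "everTiotropium": 1,
        "iNotWhite": 1,
        "smkEver": 1,
        "everdxAtPulmClinic": 1,   # 496 at pulmonary clinic
        "everCOPDmed": 1,
        "nmedLAMA": 1,             # one distinct prescription code
        "pftCount": 1,             # structured row and pft note share a date
        "ageCOPDt1Specific": 65,
        "nCOPD_ICD": 3,            # 06-01, 07-01, 08-01 (494/401.9 excluded)
        "nBronchitis": 1,          # 491.0 on one date
        "nBronchiectasis": 1,
        "patient_dxenct": 2,
    }
    for name, value in expected.items():
        assert table.loc["P1", name] == value, name


def test_minimal_patient_gets_missing_pft_rule(codesets):
    """One specific code, one note, nothing else: everPFTlt70 falls to 0."""
    from phenocopd.ehr_data import Cohort

    c = Cohort.empty()
    c.patients.loc[0] = {"patient_id": "P1", "birth_date": pd.Timestamp("1950-01-01"),
                         "race": "White", "sex": "F"}
    c.diagnoses = make_dx([("P1", "2015-06-01", "J43.9", "ICD10")])
    c.notes = pd.DataFrame([{"patient_id": "P1", "date": pd.Timestamp("2015-06-01"),
                             "note_type": "clinic_note", "text": "Routine visit."}])
    table = _pipeline_tables(c, codesets).set_index("patient_id")
    row = table.loc["P1"]
    assert row["everPFTlt70"] == 0 and row["smkEver"] == 0
    assert row["ageCOPDt1Specific"] == 65
    assert row["iNotWhite"] == 0
    for name in ("everTiotropium", "everCOPDmed", "nmedLAMA", "pftCount",
                 "nBronchitis", "nBronchiectasis", "patient_dxenct", "nCOPDGTE3_365"):
        assert row[name] == 0, name
    assert row["nCOPD_ICD"] == 1


def test_feature_table_is_idempotent_and_complete(small_cohort, codesets):
    cohort, _ = small_cohort
    t1 = _pipeline_tables(cohort, codesets)
    t2 = _pipeline_tables(cohort, codesets)
    pd.testing.assert_frame_equal(t1, t2)
    assert list(t1.columns) == ["patient_id", *FEATURE_COLUMNS]
    binaries = ["everPFTlt70", "nCOPDGTE3_365", "everTiotropium", "iNotWhite",
                "smkEver", "everdxAtPulmClinic", "everCOPDmed"]
    assert t1[binaries].isin([0, 1]).all().all()
    counts = ["nmedLAMA", "pftCount", "nCOPD_ICD", "nBronchitis", "nBronchiectasis", "patient_dxenct"]
    assert (t1[counts] >= 0).all().all()
    # bronchitis dates are a subset of all diagnosis dates
    total_dates = cohort.diagnoses.groupby("patient_id")["date"].nunique()
    merged = t1.set_index("patient_id")["nBronchitis"]
    assert (merged <= total_dates.reindex(merged.index).fillna(0)).all()


def test_adding_events_is_monotone(codesets):
    """More history can only raise counts and never clears an 'ever' flag."""
    cohort, _ = generate(SimConfig(n_patients=30, seed=9))
    base = _pipeline_tables(cohort, codesets).set_index("patient_id")
    extra_dx = make_dx([(pid, "2018-06-01", "J44.9", "ICD10", "pulmonary") for pid in base.index])
    cohort.diagnoses = pd.concat([cohort.diagnoses, extra_dx], ignore_index=True)
    extra_med = pd.DataFrame([{"patient_id": pid, "date": pd.Timestamp("2018-06-01"),
                               "drug_name": "tiotropium", "drug_code": "RX-NEW", "med_class": "LAMA"}
                              for pid in base.index])
    cohort.medications = pd.concat([cohort.medications, extra_med], ignore_index=True)
    grown = _pipeline_tables(cohort, codesets).set_index("patient_id")
    count_cols = ["nmedLAMA", "pftCount", "nCOPD_ICD", "nBronchitis", "nBronchiectasis", "patient_dxenct"]
    ever_cols = ["everPFTlt70", "everTiotropium", "smkEver", "everdxAtPulmClinic", "everCOPDmed",
                 "nCOPDGTE3_365"]
    common = base.index.intersection(grown.index)
    assert (grown.loc[common, count_cols] >= base.loc[common, count_cols]).all().all()
    assert (grown.loc[common, ever_cols] >= base.loc[common, ever_cols]).all().all()
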