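"""Datamart screening filters and rule-based COPD classifiers.

Patients carrying at least one COPD-specific ICD code form the screen-positive
datamart.  A stricter data floor — at least three broad COPD-family codes on
distinct dates plus at least one non-empty clinical note — marks records rich
enough for chart review and model application.  Two rule-based classifiers
(3-of and 2-of COPD-specific distinct dates) and a control-selection rule
(zero broad-family codes ever, plus a minimum of two encounters) serve as
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .codesets import CodeSet, match_code
from .ehr_data import Cohort


class Rule(str, Enum):
    ICD_STRICT = "ICD_STRICT"
    ICD_BROAD = "ICD_BROAD"
    CONTROL = "CONTROL"


class Label(str, Enum):
    CASE = "case"
    NON_CASE = "non_case"
    CONTROL = "control"
    INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class DatamartResult:
    patient_id: str
    screen_positive: bool
    meets_data_floor: bool
    n_specific_distinct_dates: int
    n_broad_distinct_dates: int
    n_notes: int


def _matches(diagnoses: pd.DataFrame, codeset: CodeSet) -> pd.Series:
    if not len(diagnoses):
        return pd.Series(False, index=diagnoses.index, dtype=bool)
    return diagnoses.apply(lambda r: match_code(r["code"], r["system"], codeset), axis=1)


def count_distinct_dates(diagnoses: pd.DataFrame, codeset: CodeSet) -> int:
    """Distinct calendar dates bearing >= 1 code from the family.

    Duplicate codes on one date count once; the count is per-codeset, not
    per-individual-code.
    """
    m = _matches(diagnoses, codeset)
    return int(diagnoses.loc[m, "date"].nunique())


def matching_dates(diagnoses: pd.DataFrame, codeset: CodeSet) -> list[pd.Timestamp]:
    """Sorted unique dates with >= 1 matching code (feeds rolling-window flags)."""
    m = _matches(diagnoses, codeset)
    return sorted(diagnoses.loc[m, "date"].unique())


def screen_positive(diagnoses: pd.DataFrame, specific: CodeSet) -> bool:
    """True iff the patient carries >= 1 COPD-specific code."""
    return bool(_matches(diagnoses, specific).any())


def _n_nonempty_notes(notes: pd.DataFrame) -> int:
    if not len(notes):
        return 0
    return int((notes["text"].astype(str).str.strip() != "").sum())


def meets_data_floor(diagnoses: pd.DataFrame, notes: pd.DataFrame, broad: CodeSet) -> bool:
    """>= 3 broad-family codes on distinct dates AND >= 1 non-empty note."""
    return count_distinct_dates(diagnoses, broad) >= 3 and _n_nonempty_notes(notes) >= 1


def classify_rule(
    diagnoses: pd.DataFrame,
    encounters: pd.DataFrame,
    rule: Rule,
    specific: CodeSet,
    broad: CodeSet,
) -> Label:
    """Apply one rule-based classifier to a single patient's events.

    ICD_STRICT: case iff >= 3 specific-code distinct dates.
    ICD_BROAD:  case iff >= 2 specific-code distinct dates.
    CONTROL:    control iff zero broad-family matches ever and >= 2 encounters,
                else ineligible.
    """
    rule = Rule(rule)
    if rule is Rule.ICD_STRICT:
        return Label.CASE if count_distinct_dates(diagnoses, specific) >= 3 else Label.NON_CASE
    if rule is Rule.ICD_BROAD:
        return Label.CASE if count_distinct_dates(diagnoses, specific) >= 2 else Label.NON_CASE
    if rule is Rule.CONTROL:
        no_copd_history = not _matches(diagnoses, broad).any()
        return Label.CONTROL if no_copd_history and len(encounters) >= 2 else Label.INELIGIBLE
    raise ValueError(f"unknown rule {rule!r}")  # pragma: no cover


def build_datamart(cohort: Cohort, codesets: dict[str, CodeSet]) -> pd.DataFrame:
    """Screen every patient; one row per patient with filter outcomes."""
    specific, broad = codesets["specific"], codesets["broad"]
    rows = []
    dx_by_pid = dict(iter(cohort.diagnoses.groupby("patient_id"))) if len(cohort.diagnoses) else {}
    notes_by_pid = dict(iter(cohort.notes.groupby("patient_id"))) if len(cohort.notes) else {}
    empty_dx = cohort.diagnoses.iloc[0:0]
    empty_notes = cohort.notes.iloc[0:0]
    for pid in cohort.patients["patient_id"]:
        dx = dx_by_pid.get(pid, empty_dx)
        notes = notes_by_pid.get(pid, empty_notes)
        n_spec = count_distinct_dates(dx, specific)
        n_broad = count_distinct_dates(dx, broad)
        rows.append(
            {
                "patient_id": pid,
                "screen_positive": n_spec >= 1,
                "meets_data_floor": n_broad >= 3 and _n_nonempty_notes(notes) >= 1,
                "n_specific_distinct_dates": n_spec,
                "n_broad_distinct_dates": n_broad,
                "n_notes": _n_nonempty_notes(notes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "screen_positive",
            "meets_data_floor",
            "n_specific_distinct_dates",
            "n_broad_distinct_dates",
            "n_notes",
        ],
    )


def apply_rules(cohort: Cohort, codesets: dict[str, CodeSet]) -> pd.DataFrame:
    """Label every patient under each of the three rules (long format)."""
    specific, broad = codesets["specific"], codesets["broad"]
    dx_by_pid = dict(iter(cohort.diagnoses.groupby("patient_id"))) if len(cohort.diagnoses) else {}
    enc_by_pid = dict(iter(cohort.encounters.groupby("patient_id"))) if len(cohort.encounters) else {}
    empty_dx = cohort.diagnoses.iloc[0:0]
    empty_enc = cohort.encounters.iloc[0:0]
    rows = []
    for pid in cohort.patients["patient_id"]:
        dx = dx_by_pid.get(pid, empty_dx)
        enc = enc_by_pid.get(pid, empty_enc)
        for rule in Rule:
            rows.append(
                {
                    "patient_id": pid,
                    "rule": rule.value,
                    "label": classify_rule(dx, enc, rule, specific, broad).value,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "rule", "label"])
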