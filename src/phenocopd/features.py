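"""The 14 patient-history features consumed by the fixed-weight COPD model.

One row per screen-positive (datamart) patient, with columns named exactly as
the model weights expect:

    everPFTlt70, nCOPDGTE3_365, everTiotropium, iNotWhite, smkEver,
    everdxAtPulmClinic, everCOPDmed, nmedLAMA, pftCount, ageCOPDt1Specific,
    nCOPD_ICD, nBronchitis, nBronchiectasis, patient_dxenct

Count features use distinct-date semantics (duplicate codes on one day count
once).  Age is whole years at the first COPD-specific code, using 365.25-day
years.  Patients without any spirometry get everPFTlt70 = 0 by the published
missing-PFT rule.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codesets import CodeSet, match_code
from .datamart import count_distinct_dates, matching_dates
from .ehr_data import Cohort
from .nlp import ever_pft_lt70

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "everPFTlt70",
    "nCOPDGTE3_365",
    "everTiotropium",
    "iNotWhite",
    "smkEver",
    "everdxAtPulmClinic",
    "everCOPDmed",
    "nmedLAMA",
    "pftCount",
    "ageCOPDt1Specific",
    "nCOPD_ICD",
    "nBronchitis",
    "nBronchiectasis",
    "patient_dxenct",
]

DAYS_PER_YEAR = 365.25


def load_meds_config(path: str | Path | None = None) -> dict:
    if path is None:
        text = resources.files("phenocopd.configs").joinpath("meds_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)["medications"]


def rolling_window_flag(dates, k: int = 3, window_days: int = 365) -> int:
    """1 iff some k distinct dates fall inside one rolling window.

    A window of ``window_days`` spans inclusive endpoints, so k dates qualify
    when the k-th minus the first is at most ``window_days - 1`` days.  Sorted
    distinct dates are scanned with a length-k run, which is equivalent to
    testing all k-subsets.
    """
    if k < 1 or window_days < 1:
        raise ValueError("k and window_days must be >= 1")
    uniq = sorted(pd.to_datetime(pd.Series(list(dates))).unique()) if len(list(dates)) else []
    if len(uniq) < k:
        return 0
    limit = pd.Timedelta(days=window_days - 1)
    for i in range(len(uniq) - k + 1):
        if uniq[i + k - 1] - uniq[i] <= limit:
            return 1
    return 0


def age_at_first_code(birth_date, diagnoses: pd.DataFrame, codeset: CodeSet, fractional: bool = False) -> float:
    """Age in years at the earliest diagnosis matching ``codeset``.

    Raises ``ValueError`` when no code matches: the caller must guarantee the
    patient is screen-positive, and silently imputing 0 would poison the
    linear predictor.
    """
    dates = matching_dates(diagnoses, codeset)
    if not dates:
        raise ValueError("no diagnosis matches the codeset; cannot compute age at first code")
    years = (pd.Timestamp(dates[0]) - pd.Timestamp(birth_date)).days / DAYS_PER_YEAR
    return float(years) if fractional else float(np.floor(years))


def _norm(s: object) -> str:
    return str(s).strip().lower()


def build_feature_vector(
    patient: pd.Series,
    diagnoses: pd.DataFrame,
    medications: pd.DataFrame,
    encounters: pd.DataFrame,
    notes: pd.DataFrame,
    spirometry: pd.DataFrame,
    nlp_ratios: pd.DataFrame,
    smk_ever: int,
    codesets: dict[str, CodeSet],
    meds_config: dict | None = None,
    fractional_age: bool = False,
) -> dict[str, float]:
    """Feature vector for one screen-positive patient (see module docstring)."""
    meds_config = meds_config or load_meds_config()
    copd_icd = codesets["copd_icd"]
    tio_names = [_norm(n) for n in meds_config["tiotropium_names"]]
    lama_classes = set(meds_config["lama_classes"])
    copd_classes = set(meds_config["copd_med_classes"])

    drug_names = medications["drug_name"].astype(str).str.lower() if len(medications) else pd.Series(dtype=str)
    ever_tio = bool(drug_names.apply(lambda n: any(t in n for t in tio_names)).any()) if len(medications) else False
    ever_copd_med = bool(medications["med_class"].isin(copd_classes).any()) if len(medications) else False
    lama = medications[medications["med_class"].isin(lama_classes)] if len(medications) else medications
    nmed_lama = int(lama["drug_code"].nunique()) if len(lama) else 0

    # PFT records: structured spirometry rows plus pft_report notes,
    # de-duplicated per patient-date (the flat schema carries no CPT codes).
    pft_dates = set()
    if len(spirometry):
        pft_dates.update(pd.to_datetime(spirometry["date"]).dt.normalize())
    if len(notes):
        pft_notes = notes[notes["note_type"] == "pft_report"]
        pft_dates.update(pd.to_datetime(pft_notes["date"]).dt.normalize())
    pft_count = len(pft_dates)

    ratios = []
    if len(spirometry):
        ratios.extend(float(r) for r in spirometry["ratio"])
    if len(nlp_ratios):
        ratios.extend(float(r) for r in nlp_ratios["ratio"])

    copd_mask = (
        diagnoses.apply(lambda r: match_code(r["code"], r["system"], copd_icd), axis=1)
        if len(diagnoses)
        else pd.Series(dtype=bool)
    )
    copd_dx = diagnoses[copd_mask] if len(diagnoses) else diagnoses
    ever_pulm = bool((copd_dx["clinic"].astype(str).str.lower() == "pulmonary").any()) if len(copd_dx) else False

    race = patient.get("race", "")
    i_not_white = int(_norm(race) != "white")
    if not str(race).strip():
        log.warning("patient %s: missing race; iNotWhite set to 1", patient.get("patient_id"))

    n_enc_dx = int(encounters["has_coded_dx"].sum()) if len(encounters) else 0

    return {
        "everPFTlt70": ever_pft_lt70(ratios),
        "nCOPDGTE3_365": rolling_window_flag(matching_dates(diagnoses, copd_icd), k=3, window_days=365),
        "everTiotropium": int(ever_tio),
        "iNotWhite": i_not_white,
        "smkEver": int(smk_ever),
        "everdxAtPulmClinic": int(ever_pulm),
        "everCOPDmed": int(ever_copd_med),
        "nmedLAMA": nmed_lama,
        "pftCount": pft_count,
        "ageCOPDt1Specific": age_at_first_code(patient["birth_date"], diagnoses, codesets["specific"], fractional=fractional_age),
        "nCOPD_ICD": count_distinct_dates(diagnoses, copd_icd),
        "nBronchitis": count_distinct_dates(diagnoses, codesets["bronchitis"]),
        "nBronchiectasis": count_distinct_dates(diagnoses, codesets["bronchiectasis"]),
        "patient_dxenct": n_enc_dx,
    }


def build_feature_table(
    cohort: Cohort,
    datamart: pd.DataFrame,
    codesets: dict[str, CodeSet],
    nlp_ratios: pd.DataFrame,
    smoking: pd.DataFrame,
    meds_config: dict | None = None,
    fractional_age: bool = False,
) -> pd.DataFrame:
    """Feature vectors for every screen-positive patient (datamart rows)."""
    meds_config = meds_config or load_meds_config()
    in_mart = datamart.loc[datamart["screen_positive"], "patient_id"]
    smk_by_pid = smoking.set_index("patient_id")["smk_ever"] if len(smoking) else pd.Series(dtype=int)

    def group_by_pid(df):
        return dict(iter(df.groupby("patient_id"))) if len(df) else {}

    dx_g = group_by_pid(cohort.diagnoses)
    med_g = group_by_pid(cohort.medications)
    enc_g = group_by_pid(cohort.encounters)
    note_g = group_by_pid(cohort.notes)
    spiro_g = group_by_pid(cohort.spirometry)
    ratio_g = group_by_pid(nlp_ratios)

    patients = cohort.patients.set_index("patient_id", drop=False)
    rows = []
    for pid in in_mart:
        fv = build_feature_vector(
            patients.loc[pid],
            dx_g.get(pid, cohort.diagnoses.iloc[0:0]),
            med_g.get(pid, cohort.medications.iloc[0:0]),
            enc_g.get(pid, cohort.encounters.iloc[0:0]),
            note_g.get(pid, cohort.notes.iloc[0:0]),
            spiro_g.get(pid, cohort.spirometry.iloc[0:0]),
            ratio_g.get(pid, nlp_ratios.iloc[0:0]),
            int(smk_by_pid.get(pid, 0)),
            codesets,
            meds_config,
            fractional_age=fractional_age,
        )
        rows.append({"patient_id": pid, **fv})
    return pd.DataFrame(rows, columns=["patient_id", *FEATURE_COLUMNS])
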