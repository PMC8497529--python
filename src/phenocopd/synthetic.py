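"""Seeded synthetic EHR cohorts with planted COPD status.

The generator emulates the statistical structure the classifier assumes: a
screened datamart in which cases are enriched for every positively weighted
model feature.  Per-arm (case vs non-case) rates drive Poisson streams of
dated COPD-family diagnosis codes over a follow-up span, plus planted
spirometry (written both as structured rows and as templated
"FEV1/FVC: NN%" note text, so the NLP path and the structured path can be
cross-checked), smoking sentences with positive and negated phrasing,
tiotropium/LAMA prescriptions, pulmonary-clinic visits, and encounter
streams.  A handful of deterministic boundary patients straddle each filter
threshold (2 vs 3 distinct broad-code dates; 364- vs 365-day code spans;
control eligibility at 2 vs 1 encounters).

Everything is driven by one ``numpy`` Generator, so a seed fixes the cohort
byte-for-byte.  The shape is deliberately schematic — templated sentences,
uniform visit dates, no coding drift or demographic margins from any real
system — so conclusions from it concern pipeline correctness, not clinical
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ehr_data import Cohort, _empty_table

T0 = pd.Timestamp("2015-01-01")

SPECIFIC_CODES = [("491.21", "ICD9"), ("493.20", "ICD9"), ("496", "ICD9"), ("J43.9", "ICD10"), ("J44.9", "ICD10")]
BROAD_ONLY_CODES = [("491.0", "ICD9"), ("492.8", "ICD9"), ("J41.0", "ICD10"), ("J42", "ICD10")]
FILLER_CODES = [("401.9", "ICD9"), ("272.4", "ICD9"), ("E11.9", "ICD10"), ("I10", "ICD10")]

SMOKER_SENTENCES = [
    "30 pack-year history, quit 2005.",
    "Patient is a current smoker.",
    "Former smoker, approximately 20 pack years.",
]
NEVER_SENTENCES = [
    "Patient is a never smoker.",
    "Denies tobacco use.",
    "No history of smoking.",
]


@dataclass(frozen=True)
class ArmRates:
    """Event rates for one planted arm (case or non-case)."""

    copd_code_rate: float  # COPD-family diagnosis events per year
    p_pft_lt70: float      # probability of spirometry with ratio < 0.7
    p_pft_normal: float    # probability of spirometry with a normal ratio
    p_smoker: float
    p_tiotropium: float
    p_copd_med: float
    p_pulm_clinic: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the strong-signal condition: case features well separated
    from non-case features, 3-year follow-up, datamart-style prevalence.
    """

    n_patients: int = 2000
    prevalence: float = 0.4
    seed: int = 7
    followup_years: float = 3.0
    age_low: float = 50.0
    age_high: float = 80.0
    p_white: float = 0.85
    n_boundary: int = 6  # deterministic filter-boundary patients, prepended
    emit_notes: bool = True        # False: no note text anywhere (NLP features fall to 0)
    emit_spirometry: bool = True   # False: no structured spirometry rows
    case: ArmRates = field(
        default_factory=lambda: ArmRates(
            copd_code_rate=4.0, p_pft_lt70=0.9, p_pft_normal=0.05,
            p_smoker=0.9, p_tiotropium=0.6, p_copd_med=0.7, p_pulm_clinic=0.5,
        )
    )
    noncase: ArmRates = field(
        default_factory=lambda: ArmRates(
            copd_code_rate=0.5, p_pft_lt70=0.05, p_pft_normal=0.5,
            p_smoker=0.3, p_tiotropium=0.02, p_copd_med=0.2, p_pulm_clinic=0.05,
        )
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        for arm in (self.case, self.noncase):
            probs = (arm.p_pft_lt70, arm.p_pft_normal, arm.p_smoker, arm.p_tiotropium, arm.p_copd_med, arm.p_pulm_clinic)
            if arm.copd_code_rate < 0 or any(not 0 <= p <= 1 for p in probs):
                raise ValueError("arm rates must be non-negative, probabilities in [0, 1]")


def null_config(**overrides) -> SimConfig:
    """Both arms identical: the label carries no signal (AUC should be ~0.5)."""
    arm = ArmRates(
        copd_code_rate=2.0, p_pft_lt70=0.3, p_pft_normal=0.3,
        p_smoker=0.5, p_tiotropium=0.2, p_copd_med=0.4, p_pulm_clinic=0.2,
    )
    return replace(SimConfig(case=arm, noncase=arm), **overrides)


class _Builder:
    def __init__(self) -> None:
        self.patients: list[dict] = []
        self.diagnoses: list[dict] = []
        self.medications: list[dict] = []
        self.encounters: list[dict] = []
        self.notes: list[dict] = []
        self.spirometry: list[dict] = []
        self.truth: list[dict] = []

    def add_patient(self, pid: str, birth: pd.Timestamp, race: str, sex: str) -> None:
        self.patients.append({"patient_id": pid, "birth_date": birth, "race": race, "sex": sex})

    def add_dx(self, pid: str, date: pd.Timestamp, code: str, system: str, clinic: str) -> None:
        self.diagnoses.append({"patient_id": pid, "date": date, "code": code, "system": system, "clinic": clinic})

    def cohort(self) -> Cohort:
        def frame(rows, name):
            if not rows:
                return _empty_table(name)
            return pd.DataFrame(rows)

        return Cohort(
            patients=frame(self.patients, "patients"),
            diagnoses=frame(self.diagnoses, "diagnoses"),
            medications=frame(self.medications, "medications"),
            encounters=frame(self.encounters, "encounters"),
            notes=frame(self.notes, "notes"),
            spirometry=frame(self.spirometry, "spirometry"),
        )


def _boundary_patient(b: _Builder, idx: int, kind: int, emit_notes: bool = True) -> None:
    """Deterministic patients straddling each filter threshold."""
    pid = f"P{idx:05d}"
    b.add_patient(pid, T0 - pd.Timedelta(days=int(65 * 365.25)), "White", "F")
    if emit_notes:
        b.notes.append({"patient_id": pid, "date": T0 + pd.Timedelta(days=10), "note_type": "clinic_note",
                        "text": "Follow-up visit. Patient is a never smoker."})
    enc_dates = [T0 + pd.Timedelta(days=d) for d in (5, 25)]
    if kind == 0:  # exactly 2 distinct broad-code dates: screen-positive, below the data floor
        for d in (0, 30):
            b.add_dx(pid, T0 + pd.Timedelta(days=d), "496", "ICD9", "primary_care")
    elif kind == 1:  # exactly 3 distinct broad-code dates: meets the data floor
        for d in (0, 40, 80):
            b.add_dx(pid, T0 + pd.Timedelta(days=d), "496", "ICD9", "primary_care")
    elif kind == 2:  # 3 dates spanning 364 days: inside one rolling 365-day window
        for d in (0, 180, 364):
            b.add_dx(pid, T0 + pd.Timedelta(days=d), "J44.9", "ICD10", "primary_care")
    elif kind == 3:  # 3 dates spanning 365 days: outside every 365-day window
        for d in (0, 180, 365):
            b.add_dx(pid, T0 + pd.Timedelta(days=d), "J44.9", "ICD10", "primary_care")
    elif kind == 4:  # no COPD-family codes, 2 encounters: control-eligible
        b.add_dx(pid, T0 + pd.Timedelta(days=3), "401.9", "ICD9", "primary_care")
    elif kind == 5:  # no COPD-family codes, 1 encounter: control-ineligible
        b.add_dx(pid, T0 + pd.Timedelta(days=3), "401.9", "ICD9", "primary_care")
        enc_dates = enc_dates[:1]
    for d in enc_dates:
        b.encounters.append({"patient_id": pid, "date": d, "has_coded_dx": True})
    b.truth.append({"patient_id": pid, "true_label": "non_case", "planted_pft_lt70": 0,
                    "planted_smoker": 0, "planted_tiotropium": 0, "boundary_kind": kind})


def _random_patient(b: _Builder, rng: np.random.Generator, idx: int, sim: SimConfig) -> None:
    pid = f"P{idx:05d}"
    is_case = rng.random() < sim.prevalence
    arm = sim.case if is_case else sim.noncase
    fdays = int(sim.followup_years * 365)

    age = rng.uniform(sim.age_low, sim.age_high)
    birth = T0 - pd.Timedelta(days=int(age * 365.25))
    race = "White" if rng.random() < sim.p_white else str(rng.choice(["Black", "Asian", "Other"]))
    sex = str(rng.choice(["F", "M"]))
    b.add_patient(pid, birth, race, sex)

    def rand_date() -> pd.Timestamp:
        return T0 + pd.Timedelta(days=int(rng.integers(0, fdays)))

    # COPD-family diagnosis stream (Poisson over follow-up), mostly specific codes
    n_copd = int(rng.poisson(arm.copd_code_rate * sim.followup_years))
    got_specific = False
    for _ in range(n_copd):
        pool = SPECIFIC_CODES if rng.random() < 0.8 else BROAD_ONLY_CODES
        code, system = pool[int(rng.integers(0, len(pool)))]
        got_specific = got_specific or pool is SPECIFIC_CODES
        clinic = "pulmonary" if rng.random() < arm.p_pulm_clinic else str(rng.choice(["primary_care", "other"]))
        b.add_dx(pid, rand_date(), code, system, clinic)
    if not got_specific:  # every simulated patient enters the screen-positive datamart
        code, system = SPECIFIC_CODES[int(rng.integers(0, len(SPECIFIC_CODES)))]
        b.add_dx(pid, rand_date(), code, system, "primary_care")

    for _ in range(int(rng.poisson(3.0))):
        code, system = FILLER_CODES[int(rng.integers(0, len(FILLER_CODES)))]
        b.add_dx(pid, rand_date(), code, system, "other")

    for _ in range(2 + int(rng.poisson(8.0))):
        b.encounters.append({"patient_id": pid, "date": rand_date(), "has_coded_dx": bool(rng.random() < 0.8)})

    planted_tio = int(rng.random() < arm.p_tiotropium)
    if planted_tio:
        n_codes = 1 if rng.random() < 0.7 else 2
        for j in range(n_codes):
            b.medications.append({
                "patient_id": pid, "date": rand_date(), "drug_name": "tiotropium bromide",
                "drug_code": f"RX-TIO-{j + 1:02d}", "med_class": "LAMA",
            })
    if rng.random() < arm.p_copd_med:
        b.medications.append({
            "patient_id": pid, "date": rand_date(), "drug_name": "albuterol sulfate",
            "drug_code": "RX-ALB-01", "med_class": "COPD_med",
        })

    planted_smoker = int(rng.random() < arm.p_smoker)
    sentences = SMOKER_SENTENCES if planted_smoker else NEVER_SENTENCES
    smoking_sentence = sentences[int(rng.integers(0, len(sentences)))]
    if sim.emit_notes:
        b.notes.append({
            "patient_id": pid, "date": rand_date(), "note_type": "clinic_note",
            "text": f"Clinic visit for respiratory complaints. {smoking_sentence}",
        })

    u = rng.random()
    planted_low = int(u < arm.p_pft_lt70)
    has_pft = u < arm.p_pft_lt70 + arm.p_pft_normal
    if has_pft:
        pct = int(rng.integers(45, 68)) if planted_low else int(rng.integers(72, 93))
        pft_date = rand_date()
        if sim.emit_spirometry:
            b.spirometry.append({
                "patient_id": pid, "date": pft_date, "ratio": pct / 100.0,
                "phase": "post_bronchodilator", "source": "structured",
            })
        if sim.emit_notes:
            b.notes.append({
                "patient_id": pid, "date": pft_date, "note_type": "pft_report",
                "text": f"Spirometry interpretation.\n\nPost-bronchodilator FEV1/FVC: {pct}%",
            })

    b.truth.append({
        "patient_id": pid, "true_label": "case" if is_case else "non_case",
        "planted_pft_lt70": planted_low, "planted_smoker": planted_smoker,
        "planted_tiotropium": planted_tio, "boundary_kind": -1,
    })


def generate(sim: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its truth table; deterministic given ``sim.seed``."""
    rng = np.random.default_rng(sim.seed)
    b = _Builder()
    n_boundary = min(sim.n_boundary, sim.n_patients)
    for i in range(n_boundary):
        _boundary_patient(b, i, i % 6, emit_notes=sim.emit_notes)
    for i in range(n_boundary, sim.n_patients):
        _random_patient(b, rng, i, sim)
    truth = pd.DataFrame(b.truth)
    return b.cohort(), truth


def end_to_end_check(sim: SimConfig, model=None, n_boot: int = 0, seed: int = 0):
    """Generate -> datamart -> NLP -> features -> classify -> evaluate, one call.

    Evaluation compares predicted labels with the planted truth over the
    scored (screen-positive) patients.  Returns (PerformanceReport, artifacts
    dict with every intermediate table).
    """
    from .pipeline import run_pipeline  # local import: pipeline imports this module's peers

    cohort, truth = generate(sim)
    artifacts = run_pipeline(cohort, model=model)
    scores = artifacts["scores"]
    gold = truth.set_index("patient_id").loc[scores["patient_id"], "true_label"]
    from .evaluation import evaluate

    report = evaluate(gold.tolist(), scores["label"].tolist(), scores=scores["probability"].tolist(),
                      n_boot=n_boot, seed=seed)
    artifacts["truth"] = truth
    artifacts["cohort"] = cohort
    return report, artifacts
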