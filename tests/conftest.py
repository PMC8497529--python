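import pandas as pd
import pytest

from phenocopd import SimConfig, generate, load_codesets, load_model


@pytest.fixture(scope="session")
def codesets():
    return load_codesets()


@pytest.fixture(scope="session")
def model():
    return load_model()


@pytest.fixture(scope="session")
def small_cohort():
    """100-patient seeded synthetic cohort reused across modules."""
    cohort, truth = generate(SimConfig(n_patients=100, seed=42))
    return cohort, truth


def make_dx(rows):
    """diagnoses frame from (patient_id, date, code, system[, clinic]) tuples."""
    recs = []
    for r in rows:
        pid, date, code, system = r[:4]
        clinic = r[4] if len(r) > 4 else "primary_care"
        recs.append({"patient_id": pid, "date": pd.Timestamp(date), "code": code,
                     "system": system, "clinic": clinic})
    cols = ["patient_id", "date", "code", "system", "clinic"]
    return pd.DataFrame(recs, columns=cols)


def make_notes(rows):
    """notes frame from (patient_id, date, note_type, text) tuples."""
    cols = ["patient_id", "date", "note_type", "text"]
    return pd.DataFrame(
        [{"patient_id": p, "date": pd.Timestamp(d), "note_type": t, "text": x} for p, d, t, x in rows],
        columns=cols,
    )
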