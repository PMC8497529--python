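"""End-to-end wiring: cohort -> datamart -> NLP -> features -> scores."""

from __future__ import annotations

import pandas as pd

from .classifier import ModelSpec, classify_table, load_model
from .codesets import load_codesets
from .datamart import build_datamart
from .ehr_data import Cohort
from .features import build_feature_table, load_meds_config
from .nlp import extract_cohort, load_nlp_config


def run_pipeline(
    cohort: Cohort,
    codesets: dict | None = None,
    model: ModelSpec | None = None,
    nlp_config: dict | None = None,
    meds_config: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every stage on an in-memory cohort; returns all intermediate tables.

    Keys: ``datamart``, ``nlp_ratios``, ``smoking``, ``features``, ``scores``.
    Only screen-positive patients are scored.
    """
    codesets = codesets or load_codesets()
    model = model or load_model()
    nlp_config = nlp_config or load_nlp_config()
    meds_config = meds_config or load_meds_config()

    datamart = build_datamart(cohort, codesets)
    ratios, smoking = extract_cohort(cohort, nlp_config)
    features = build_feature_table(cohort, datamart, codesets, ratios, smoking, meds_config)
    scores = classify_table(features, model)
    return {
        "datamart": datamart,
        "nlp_ratios": ratios,
        "smoking": smoking,
        "features": features,
        "scores": scores,
    }
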