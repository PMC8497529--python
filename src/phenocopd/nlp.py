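"""Rule-based extraction of FEV1/FVC ratios and smoking status from note text.

The final classifier needs exactly two unstructured inputs: whether any
spirometry ever showed FEV1/FVC < 0.7 (pre- or post-bronchodilator), and
whether the patient has any current/former smoking history.  Both are
extracted with deterministic, auditable regular expressions rather than a
learned model, which keeps the pipeline portable across EHR sites.

Ratio normalization: a number following a ratio token that exceeds 2 is read
as a percentage and divided by 100 ("65%", "65" and "0.65" all mean 0.65 —
true ratios cannot plausibly exceed 2, percentages cannot plausibly fall
below 2).  Bronchodilator phase is taken from the nearest preceding pre/post
cue within the same blank-line-separated section, else left unspecified.

Negation is a NegEx-style token window: a smoking term is negative when a cue
("never", "denies", "no", ...) occurs within 4 tokens before it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .ehr_data import Cohort

log = logging.getLogger(__name__)

PRE = "pre_bronchodilator"
POST = "post_bronchodilator"
UNSPECIFIED = "unspecified"

# "FEV1/FVC", "FEV1 : FVC ratio", "FEV1 / FVC ratio of" ... then a number,
# optionally a percent sign.
_RATIO_RE = re.compile(
    r"FEV[-_ ]?1\s*[/:]\s*FVC(?:\s+ratio)?\s*(?:of|is|was|=|:)?\s*"
    r"(?P<num>\d+(?:\.\d+)?)\s*%?",
    re.IGNORECASE,
)


def load_nlp_config(path: str | Path | None = None) -> dict:
    if path is None:
        text = resources.files("phenocopd.configs").joinpath("nlp_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class RatioMention:
    ratio: float
    phase: str
    matched_span: str


@dataclass
class SmokingCall:
    patient_id: str
    smk_ever: int
    evidence: list[tuple[object, str, str]] = field(default_factory=list)  # (date, span, polarity)


def _phase_for(text: str, pos: int, config: dict) -> str:
    """Nearest preceding pre/post cue in the same section, else unspecified."""
    section_start = text.rfind("\n\n", 0, pos)
    section = text[section_start + 2 if section_start >= 0 else 0 : pos].lower()
    best, best_at = UNSPECIFIED, -1
    for phase, key in ((PRE, "pre_cues"), (POST, "post_cues")):
        for cue in config["spirometry"][key]:
            at = section.rfind(cue.lower())
            if at > best_at:
                best, best_at = phase, at
    return best


def extract_ratios(text: str, config: dict | None = None) -> list[RatioMention]:
    """All FEV1/FVC ratio mentions in one note, normalized to the fraction scale.

    Component volumes alone ("FEV1 2.1 L; FVC 3.0 L") are never extracted —
    only explicit ratio constructs count.
    """
    config = config or load_nlp_config()
    mentions: list[RatioMention] = []
    for m in _RATIO_RE.finditer(text or ""):
        try:
            value = float(m.group("num"))
        except ValueError:  # pragma: no cover - regex guarantees a float
            log.warning("unparseable ratio number in %r", m.group(0))
            continue
        if value > 2.0:
            value = value / 100.0
        if not 0 < value <= 2.0:
            log.warning("ratio %s out of (0, 2] after normalization; skipped", value)
            continue
        mentions.append(RatioMention(ratio=value, phase=_phase_for(text, m.start(), config), matched_span=m.group(0)))
    return mentions


def ever_pft_lt70(ratios: list[float]) -> int:
    """1 iff any structured or extracted FEV1/FVC ratio < 0.7 (strict).

    Patients with no spirometry anywhere are classified 0 ("No") — the
    published missing-PFT rule that keeps the model computable everywhere.
    """
    return int(any(r < 0.7 for r in ratios))


def _smoking_matches(text: str, config: dict):
    cfg = config["smoking"]
    terms = sorted(cfg["terms"], key=len, reverse=True)
    pattern = re.compile(
        "|".join(r"\b" + re.escape(t).replace(r"\ ", r"\s+") + r"\b" for t in terms),
        re.IGNORECASE,
    )
    cues = {c.lower() for c in cfg["negation_cues"]}
    window = int(cfg["window"])
    for m in pattern.finditer(text or ""):
        preceding = re.findall(r"[\w-]+", text[: m.start()].lower())[-window:]
        tokens = set(preceding)
        for tok in preceding:
            tokens.update(tok.split("-"))
        polarity = "negative" if tokens & cues else "positive"
        yield m.group(0), polarity


def smoking_ever(notes: pd.DataFrame, config: dict | None = None, patient_id: str = "") -> SmokingCall:
    """Ever-smoker call for one patient from their notes.

    smk_ever = 1 iff at least one smoking-lexicon mention survives the
    negation window.  No notes, or only negated mentions, yield 0.
    """
    config = config or load_nlp_config()
    if config["smoking"].get("restrict_to_pft_reports") and len(notes):
        notes = notes[notes["note_type"] == "pft_report"]
    evidence: list[tuple[object, str, str]] = []
    if len(notes):
        for _, row in notes.sort_values("date", kind="stable").iterrows():
            for span, polarity in _smoking_matches(str(row["text"]), config):
                evidence.append((row["date"], span, polarity))
    smk = int(any(pol == "positive" for _, _, pol in evidence))
    return SmokingCall(patient_id=patient_id, smk_ever=smk, evidence=evidence)


def extract_cohort(cohort: Cohort, config: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both extractors over a cohort.

    Returns (ratio mentions table: patient_id, date, ratio, phase, source;
    smoking table: patient_id, smk_ever).
    """
    config = config or load_nlp_config()
    ratio_rows = []
    smoking_rows = []
    notes_by_pid = dict(iter(cohort.notes.groupby("patient_id"))) if len(cohort.notes) else {}
    empty_notes = cohort.notes.iloc[0:0]
    for pid in cohort.patients["patient_id"]:
        notes = notes_by_pid.get(pid, empty_notes)
        for _, row in notes.iterrows():
            for mention in extract_ratios(str(row["text"]), config):
                ratio_rows.append(
                    {
                        "patient_id": pid,
                        "date": row["date"],
                        "ratio": mention.ratio,
                        "phase": mention.phase,
                        "source": "nlp",
                    }
                )
        call = smoking_ever(notes, config, patient_id=pid)
        smoking_rows.append({"patient_id": pid, "smk_ever": call.smk_ever})
    ratios = pd.DataFrame(ratio_rows, columns=["patient_id", "date", "ratio", "phase", "source"])
    smoking = pd.DataFrame(smoking_rows, columns=["patient_id", "smk_ever"])
    return ratios, smoking
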