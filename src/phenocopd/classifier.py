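"""Fixed-weight logistic scoring and optional site refitting.

A :class:`ModelSpec` is a named bundle of intercept, per-feature weights, a
probability cutoff and missing-data fill rules, loaded from YAML.  The shipped
default is the published curated-features-plus-spirometry COPD model.  Scoring
is the plain logistic form

    lp = intercept + sum_i w_i x_i,      p = 1 / (1 + exp(-lp))

with case status assigned strictly above the cutoff ("above the cutoff" is
strict; probabilities exactly at it are non-cases).

``fit_penalized_model`` rebuilds a model at a new site with elastic-net
penalized logistic regression (5-fold cross-validated deviance over an
l1-ratio/strength grid, optional adaptive penalty re-weighting) and re-derives
the cutoff at a target specificity on the training labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_COLUMNS

CASE = "case"
NON_CASE = "non_case"


@dataclass(frozen=True)
class ModelSpec:
    """Intercept, named weights, decision cutoff and missing-data policy."""

    name: str
    intercept: float
    weights: dict[str, float]
    threshold: float
    missing_policy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must lie strictly in (0, 1), got {self.threshold}")
        unknown = set(self.weights) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"model {self.name!r} weights name unknown features: {sorted(unknown)}")


@dataclass(frozen=True)
class ScoredPatient:
    patient_id: str
    linear_predictor: float
    probability: float
    label: str


def load_model(path: str | Path | None = None) -> ModelSpec:
    """Load a ModelSpec from YAML (the shipped published model when None)."""
    if path is None:
        text = resources.files("phenocopd.configs").joinpath("model_crtpft_plus.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return ModelSpec(
        name=str(raw["name"]),
        intercept=float(raw["intercept"]),
        weights={k: float(v) for k, v in raw["weights"].items()},
        threshold=float(raw["threshold"]),
        missing_policy={k: float(v) for k, v in raw.get("missing_policy", {}).items()},
    )


def save_model(model: ModelSpec, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "name": model.name,
        "intercept": float(model.intercept),
        "weights": {k: float(v) for k, v in model.weights.items()},
        "threshold": float(model.threshold),
        "missing_policy": {k: float(v) for k, v in model.missing_policy.items()},
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def _resolve(fv: Mapping[str, float], name: str, model: ModelSpec) -> float:
    value = fv.get(name) if hasattr(fv, "get") else fv[name]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        if name in model.missing_policy:
            return float(model.missing_policy[name])
        raise KeyError(f"feature {name!r} missing and no fill rule in model {model.name!r}")
    return float(value)


def linear_predictor(fv: Mapping[str, float], model: ModelSpec) -> float:
    """intercept + sum of weight * feature over the model's named weights."""
    total = model.intercept
    for name, w in model.weights.items():
        try:
            total += w * _resolve(fv, name, model)
        except KeyError as err:
            raise KeyError(f"cannot score: {err}") from err
    return float(total)


def score(fv: Mapping[str, float], model: ModelSpec, patient_id: str = "") -> ScoredPatient:
    lp = linear_predictor(fv, model)
    prob = float(expit(lp))
    return ScoredPatient(
        patient_id=patient_id or str(fv.get("patient_id", "")),
        linear_predictor=lp,
        probability=prob,
        label=CASE if prob > model.threshold else NON_CASE,
    )


def classify_table(features: pd.DataFrame, model: ModelSpec) -> pd.DataFrame:
    """Score a feature table; one row per patient with lp, probability, label."""
    rows = [score(row, model, patient_id=str(row.get("patient_id", i))) for i, row in features.iterrows()]
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "linear_predictor": [r.linear_predictor for r in rows],
            "probability": [r.probability for r in rows],
            "label": [r.label for r in rows],
        }
    )


def select_threshold_at_specificity(
    scores, gold_labels, target_specificity: float
) -> tuple[float, float, float]:
    """Smallest cutoff achieving the target specificity; returns (cutoff, sens, spec).

    Labels are assigned strictly above the cutoff, so specificity at cutoff c
    is the fraction of gold non-cases scoring <= c.  The smallest qualifying
    cutoff automatically maximizes sensitivity among qualifying cutoffs.  If
    even the largest score cannot reach the target, a cutoff just above the
    maximum is returned (everything non-case) — degenerate but explicit.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if g in (1, True, CASE) else 0 for g in gold_labels])
    if len(s) != len(y):
        raise ValueError("scores and gold labels differ in length")
    if not (y == 0).any():
        raise ValueError("need at least one gold non-case to anchor specificity")
    neg = s[y == 0]
    pos = s[y == 1]
    candidates = np.concatenate([[np.nextafter(s.min(), -np.inf)], np.unique(s)])
    for c in candidates:
        spec = float(np.mean(neg <= c))
        if spec >= target_specificity:
            sens = float(np.mean(pos > c)) if len(pos) else float("nan")
            return float(c), sens, spec
    c = float(np.nextafter(s.max(), np.inf))  # pragma: no cover - max score always qualifies
    return c, 0.0, 1.0


def fit_penalized_model(
    features: pd.DataFrame,
    gold_labels,
    cv_folds: int = 5,
    l1_ratios=(0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
    n_lambdas: int = 20,
    seed: int = 0,
    adaptive: bool = False,
    target_specificity: float = 0.95,
    name: str = "site_refit",
) -> ModelSpec:
    """Refit the classifier at a new site with elastic-net logistic regression.

    Penalty strength and l1 mixing are chosen by ``cv_folds``-fold
    cross-validated deviance (log loss) over a log-spaced strength grid.  The
    optional adaptive stage re-weights per-feature penalties by the inverse
    magnitude of an initial ridge fit, implemented by rescaling each column by
    that magnitude before the penalized fit and rescaling the coefficients
    back.  The decision cutoff is then re-derived on the training data at
    ``target_specificity``.  Deterministic given ``seed``.
    """
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    X = features[cols].to_numpy(dtype=float)
    y = np.asarray([1 if g in (1, True, CASE) else 0 for g in gold_labels])
    if len(np.unique(y)) < 2:
        raise ValueError("gold labels contain a single class; cannot fit")
    if len(y) < cv_folds:
        raise ValueError("fewer observations than CV folds")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    adaptive_scale = np.ones(Xs.shape[1])
    if adaptive:
        ridge = LogisticRegression(C=1.0, max_iter=5000).fit(Xs, y)
        adaptive_scale = np.abs(ridge.coef_.ravel())
        adaptive_scale[adaptive_scale < 1e-8] = 1e-8
        Xs = Xs * adaptive_scale

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=np.logspace(-4, 2, n_lambdas),
        l1_ratios=list(l1_ratios),
        solver="saga",
        scoring="neg_log_loss",
        cv=cv,
        max_iter=10000,
        random_state=seed,
        use_legacy_attributes=True,
    ).fit(Xs, y)

    # undo adaptive scaling and standardization to express weights on the
    # original feature scale
    beta_std = clf.coef_.ravel() * adaptive_scale
    beta = beta_std / scaler.scale_
    intercept = float(clf.intercept_[0] - np.sum(beta * scaler.mean_))

    lp = intercept + X @ beta
    probs = expit(lp)
    cutoff, _, _ = select_threshold_at_specificity(probs, y, target_specificity)
    cutoff = float(np.clip(cutoff, 1e-9, 1 - 1e-9))
    return ModelSpec(
        name=name,
        intercept=intercept,
        weights={c: float(b) for c, b in zip(cols, beta)},
        threshold=cutoff,
        missing_policy={"everPFTlt70": 0, "smkEver": 0},
    )


def case_boundary_lp(model: ModelSpec) -> float:
    """The linear-predictor value equivalent to the probability cutoff."""
    return float(logit(model.threshold))
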