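"""Validation machinery: confusion counts, F-beta, AUC, bootstrap CIs, kappa.

Point metrics follow the standard definitions with case = positive:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)
    F_beta      = (1 + b^2) * PPV * sens / (b^2 * PPV + sens)

A metric with a zero denominator is reported as undefined with a reason,
never silently 0 — this matters in small validation strata.  Confidence
intervals are percentile bootstrap over patient-level resamples (B = 1000 by
default), deterministic given a seed.  AUC is the rank statistic (probability
a random case outscores a random non-case, ties half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, roc_auc_score

log = logging.getLogger(__name__)

CASE = "case"
NON_CASE = "non_case"

_POSITIVE = (1, True, CASE)


def _as_binary(labels) -> np.ndarray:
    return np.asarray([1 if x in _POSITIVE else 0 for x in labels], dtype=int)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class PerformanceReport:
    """Point metrics (None where undefined), with optional bootstrap CIs."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    f0_5: float | None
    auc: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None

    def as_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "f0_5": self.f0_5,
            "auc": self.auc,
        }
        if self.undefined:
            out["undefined"] = dict(self.undefined)
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
            out["n_boot"] = self.n_boot
            out["seed"] = self.seed
        return out


def confusion(gold, predicted) -> ConfusionMatrix:
    """2x2 cross-tabulation of gold vs predicted binary labels."""
    g = _as_binary(gold)
    p = _as_binary(predicted)
    if len(g) != len(p):
        raise ValueError("gold and predicted labels cover different patient sets")
    return ConfusionMatrix(
        tp=int(np.sum((g == 1) & (p == 1))),
        tn=int(np.sum((g == 0) & (p == 0))),
        fp=int(np.sum((g == 0) & (p == 1))),
        fn=int(np.sum((g == 1) & (p == 0))),
    )


def _ratio(num: int, den: int, name: str, undefined: dict[str, str]) -> float | None:
    if den == 0:
        undefined[name] = f"denominator zero ({name})"
        return None
    return num / den


def fbeta(ppv: float | None, sens: float | None, beta: float) -> float | None:
    if ppv is None or sens is None or (ppv == 0 and sens == 0):
        return None
    b2 = beta * beta
    return (1 + b2) * ppv * sens / (b2 * ppv + sens)


def metrics(cm: ConfusionMatrix) -> PerformanceReport:
    """Point estimates of all confusion-derived metrics."""
    undefined: dict[str, str] = {}
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", undefined)
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity", undefined)
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "ppv", undefined)
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv", undefined)
    f1 = fbeta(ppv, sens, 1.0)
    f0_5 = fbeta(ppv, sens, 0.5)
    if f1 is None and "f1" not in undefined:
        undefined["f1"] = "ppv or sensitivity undefined or both zero"
    if f0_5 is None and "f0_5" not in undefined:
        undefined["f0_5"] = "ppv or sensitivity undefined or both zero"
    return PerformanceReport(sens, spec, ppv, npv, f1, f0_5, undefined=undefined)


def auc(scores, gold) -> float:
    """Rank-based ROC AUC; requires both classes present."""
    g = _as_binary(gold)
    if len(np.unique(g)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(g, np.asarray(scores, dtype=float)))


_METRIC_FUNCS = {
    "sensitivity": lambda g, p: metrics(confusion(g, p)).sensitivity,
    "specificity": lambda g, p: metrics(confusion(g, p)).specificity,
    "ppv": lambda g, p: metrics(confusion(g, p)).ppv,
    "npv": lambda g, p: metrics(confusion(g, p)).npv,
    "f1": lambda g, p: metrics(confusion(g, p)).f1,
    "f0_5": lambda g, p: metrics(confusion(g, p)).f0_5,
}


def bootstrap_ci(
    gold,
    predictions,
    metric: str,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI over patient-level resamples with replacement.

    ``metric`` is one of sensitivity/specificity/ppv/npv/f1/f0_5/auc; for
    "auc" the predictions are continuous scores, otherwise binary labels.
    Resamples where the metric is undefined are dropped (with a logged count);
    more than half undefined is an error, not an interval.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    g = np.asarray(gold, dtype=object)
    p = np.asarray(predictions, dtype=object)
    if metric == "auc":
        def func(gi, pi):
            try:
                return auc(pi.astype(float), gi)
            except ValueError:
                return None
    elif metric in _METRIC_FUNCS:
        func = _METRIC_FUNCS[metric]
    else:
        raise ValueError(f"unknown metric {metric!r}")

    rng = np.random.default_rng(seed)
    n = len(g)
    values = []
    n_undefined = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        v = func(g[idx], p[idx])
        if v is None:
            n_undefined += 1
        else:
            values.append(v)
    if n_undefined > n_boot / 2:
        raise RuntimeError(
            f"{metric} undefined in {n_undefined}/{n_boot} bootstrap resamples; "
            "stratum too small or degenerate"
        )
    if n_undefined:
        log.info("bootstrap: dropped %d/%d resamples with undefined %s", n_undefined, n_boot, metric)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(np.asarray(values, dtype=float), [alpha, 1 - alpha])
    return float(lo), float(hi)


def cohens_kappa(rater_a, rater_b) -> float:
    """Chance-corrected agreement between two raters over the same items."""
    a = np.asarray(rater_a, dtype=object)
    b = np.asarray(rater_b, dtype=object)
    if len(a) != len(b):
        raise ValueError("raters labeled different item sets")
    # expected agreement from marginal products; p_e == 1 leaves kappa undefined
    labels = pd.unique(np.concatenate([a, b]))
    pa = np.array([np.mean(a == lab) for lab in labels])
    pb = np.array([np.mean(b == lab) for lab in labels])
    if np.isclose(float(pa @ pb), 1.0):
        raise ValueError("expected agreement is 1; kappa undefined")
    return float(cohen_kappa_score(a.astype(str), b.astype(str)))


def evaluate(
    gold,
    predicted,
    scores=None,
    n_boot: int = 0,
    seed: int = 0,
) -> PerformanceReport:
    """Full report: counts-derived metrics, optional AUC and bootstrap CIs."""
    report = metrics(confusion(gold, predicted))
    if scores is not None:
        try:
            report.auc = auc(scores, gold)
        except ValueError as err:
            report.undefined["auc"] = str(err)
    if n_boot:
        report.n_boot = n_boot
        report.seed = seed
        for name in ("sensitivity", "specificity", "ppv", "npv", "f1", "f0_5"):
            if getattr(report, name if name != "f0_5" else "f0_5") is None:
                continue
            try:
                report.ci[name] = bootstrap_ci(gold, predicted, name, n_boot=n_boot, seed=seed)
            except RuntimeError as err:
                report.undefined[f"{name}_ci"] = str(err)
        if scores is not None and report.auc is not None:
            report.ci["auc"] = bootstrap_ci(gold, scores, "auc", n_boot=n_boot, seed=seed)
    return report
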