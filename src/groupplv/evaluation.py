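"""Classifier evaluation: accuracy, precision, recall, F-measure, ROC/PR.

The positive class is "high" (high arousal / high valence) for both
target dimensions; all precision/recall figures are anchored on it.
Curves are computed from the softmax probability of the positive class
by a threshold sweep over the unique scores (equal scores collapse into
one threshold step) and the ROC AUC uses the trapezoid rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm

__all__ = [
    "confusion_metrics",
    "roc_pr_curves",
    "EvaluationReport",
    "evaluate_predictions",
    "compare_levels",
]

POSITIVE = 1  # encoded "high"


def _encode(labels) -> np.ndarray:
    a = np.asarray(labels)
    if a.dtype.kind in "UO":
        return np.array([1 if v == "high" else 0 for v in a])
    return a.astype(int)


def confusion_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F-measure) with "high" positive.

    F = 2PR/(P+R), defined as 0 when P + R = 0; precision/recall are 0
    when their denominator is empty.
    """
    t, p = _encode(y_true), _encode(y_pred)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("label vectors must be non-empty and equal-length")
    acc = skm.accuracy_score(t, p)
    prec = skm.precision_score(t, p, pos_label=POSITIVE, zero_division=0)
    rec = skm.recall_score(t, p, pos_label=POSITIVE, zero_division=0)
    f = skm.f1_score(t, p, pos_label=POSITIVE, zero_division=0)
    return float(acc), float(prec), float(rec), float(f)


def roc_pr_curves(y_true, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points, PR points and ROC AUC from positive-class scores.

    Returns ``(roc, pr, auc)`` where ``roc`` is an (m, 2) array of
    (FPR, TPR) from (0, 0) to (1, 1) and ``pr`` an (m', 2) array of
    (recall, precision).

    Raises if only one class is present (the ROC is undefined).
    """
    t = _encode(y_true)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("ROC undefined for single-class truth")
    fpr, tpr, _ = skm.roc_curve(t, s, pos_label=POSITIVE)
    prec, rec, _ = skm.precision_recall_curve(t, s, pos_label=POSITIVE)
    auc = float(skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), np.column_stack([rec, prec]), auc


@dataclass
class EvaluationReport:
    """Metrics for one (dimension, level, band) cell."""

    dimension: str
    level: str
    band: str
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    auc: float
    roc: np.ndarray
    pr: np.ndarray
    n_test: int
    seeds: list[int] = field(default_factory=list)

    def scalars(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "auc": self.auc,
        }

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension, "level": self.level, "band": self.band,
            "n_test": self.n_test, "seeds": list(self.seeds),
            **self.scalars(),
            "roc": self.roc.tolist(), "pr": self.pr.tolist(),
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        d["roc"] = np.asarray(d["roc"])
        d["pr"] = np.asarray(d["pr"])
        return cls(**d)


def evaluate_predictions(
    y_true, probabilities: np.ndarray, *,
    dimension: str, level: str, band: str, seeds: list[int] | None = None,
) -> EvaluationReport:
    """Build a full report from softmax outputs (column 1 = P(high))."""
    t = _encode(y_true)
    prob = np.asarray(probabilities, dtype=float)
    scores = prob[:, POSITIVE]
    pred = prob.argmax(axis=1)
    acc, prec, rec, f = confusion_metrics(t, pred)
    roc, pr, auc = roc_pr_curves(t, scores)
    return EvaluationReport(
        dimension=dimension, level=level, band=band,
        accuracy=acc, precision=prec, recall=rec, f_measure=f, auc=auc,
        roc=roc, pr=pr, n_test=int(t.size), seeds=list(seeds or []),
    )


def compare_levels(
    individual: dict[str, EvaluationReport],
    group: dict[str, EvaluationReport],
) -> pd.DataFrame:
    """Side-by-side per-band metric table for the two analysis levels.

    Keys of both dicts are band names; the cells must match.  Rows are
    (metric, level) and (metric, delta = group - individual), columns
    the bands — the same layout as a per-band precision/recall table.
    """
    if set(individual) != set(group):
        raise ValueError("mismatched band cells between levels")
    bands = list(individual)
    rows = {}
    for metric in ("accuracy", "precision", "recall", "f_measure", "auc"):
        ind = [individual[b].scalars()[metric] for b in bands]
        grp = [group[b].scalars()[metric] for b in bands]
        rows[(metric, "individual")] = ind
        rows[(metric, "group")] = grp
        rows[(metric, "delta")] = [g - i for g, i in zip(grp, ind)]
    frame = pd.DataFrame(rows, index=bands).T
    frame.index.names = ("metric", "level")
    return frame
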