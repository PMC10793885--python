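"""Binary classification scoring for the abnormal-vs-no-finding task.

The positive class is "Abnormal" (label 1) and a model's score is the
softmax probability it assigns to that class.  The decision rule is
``score >= threshold``; the operating threshold is chosen on the
validation split by maximizing the F-score over the candidate set of
unique validation scores.

Zero-denominator metrics (degenerate confusion rows/columns, common in
early training epochs) are reported as 0 with a logged warning rather
than raising.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionSet",
    "ConfusionCounts",
    "MetricReport",
    "confusion_from_scores",
    "classification_metrics",
    "auprc",
    "select_threshold_max_f",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class PredictionSet:
    """Per-sample positive-class scores with binary ground truth.

    ``threshold`` is optional until an operating point has been selected.
    """

    scores: np.ndarray
    labels: np.ndarray
    threshold: float | None = None
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if scores.ndim != 1 or labels.ndim != 1 or len(scores) != len(labels):
            raise ValueError("scores and labels must be 1-D and of equal length")
        if len(scores) == 0:
            raise ValueError("empty prediction set")
        if np.any((scores < 0) | (scores > 1)) or np.any(np.isnan(scores)):
            raise ValueError("scores must lie in [0, 1]")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 (No finding) or 1 (Abnormal)")
        if self.threshold is not None and not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.scores)

    def with_threshold(self, threshold: float) -> "PredictionSet":
        return replace(self, threshold=float(threshold))

    def to_frame(self, split: str = "") -> pd.DataFrame:
        ids = self.sample_ids or tuple(f"s{i}" for i in range(len(self)))
        return pd.DataFrame(
            {"sample_id": ids, "score": self.scores, "label": self.labels, "split": split}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, threshold: float | None = None) -> "PredictionSet":
        return cls(
            scores=df["score"].to_numpy(),
            labels=df["label"].to_numpy(),
            threshold=threshold,
            sample_ids=tuple(df["sample_id"].astype(str)),
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """One model's scores on one test set.  ``auprc`` may be NaN when the
    report was built from counts alone."""

    balanced_accuracy: float
    precision: float
    recall: float
    f_score: float
    mcc: float
    n: int
    auprc: float = float("nan")

    def rounded(self, decimals: int = 4) -> dict:
        out = {}
        for key, val in asdict(self).items():
            out[key] = val if key == "n" else (round(val, decimals) if math.isfinite(val) else None)
        return out

    def to_json(self, **round_kw) -> str:
        return json.dumps(self.rounded(**round_kw))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("degenerate confusion matrix: %s has zero denominator; reporting 0", what)
        return 0.0
    return num / den


def confusion_from_scores(preds: PredictionSet, threshold: float) -> ConfusionCounts:
    """Count the confusion matrix at ``threshold`` (positive iff score >= t)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pred_pos = preds.scores >= threshold
    pos = preds.labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & pos)),
        fp=int(np.sum(pred_pos & ~pos)),
        tn=int(np.sum(~pred_pos & ~pos)),
        fn=int(np.sum(~pred_pos & pos)),
    )


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Threshold-dependent metrics from confusion counts (AUPRC left unset)."""
    if c.n == 0:
        raise ValueError("no samples")
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    specificity = _safe_div(c.tn, c.tn + c.fp, "specificity")
    f_score = _safe_div(2 * precision * recall, precision + recall, "F-score")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    mcc = _safe_div(float(c.tp) * c.tn - float(c.fp) * c.fn, mcc_den, "MCC")
    return MetricReport(
        balanced_accuracy=(recall + specificity) / 2.0,
        precision=precision,
        recall=recall,
        f_score=f_score,
        mcc=mcc,
        n=c.n,
    )


def auprc(preds: PredictionSet) -> float:
    """Area under the precision-recall curve, as average precision.

    The estimator is the step-wise sum over recall increments of the
    precision at each threshold (non-interpolated AP), which is never
    optimistic; a perfect ranking scores 1.0.
    """
    labels = preds.labels
    if labels.min() == labels.max():
        raise ValueError("AUPRC undefined: labels contain a single class")
    return float(average_precision_score(labels, preds.scores))


def select_threshold_max_f(validation: PredictionSet) -> float:
    """Operating threshold that maximizes F on the validation split.

    Candidates are the sorted unique validation scores (any other
    threshold duplicates a confusion matrix under the >= rule); ties are
    broken toward the smallest threshold.
    """
    labels = validation.labels
    if labels.min() == labels.max():
        raise ValueError("threshold selection needs both classes in validation")
    best_t, best_f = None, -1.0
    for t in np.unique(validation.scores):
        c = confusion_from_scores(validation, float(t))
        p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
        r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        if f > best_f:  # strict: first (smallest) threshold wins ties
            best_t, best_f = float(t), f
    assert best_t is not None
    return best_t


def evaluate_predictions(preds: PredictionSet, threshold: float) -> MetricReport:
    """Full report (including AUPRC when both classes are present)."""
    report = classification_metrics(confusion_from_scores(preds, threshold))
    if preds.labels.min() != preds.labels.max():
        report = replace(report, auprc=auprc(preds))
    return report
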