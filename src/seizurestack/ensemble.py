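"""Stacking ensemble and binary-classification metrics.

The three personalized backbones are combined in one of two modes:

* ``stack`` (default) — the penultimate features of the three models are
  concatenated per window (64 + 256 + 1280 = 1600 dimensions at
  width_scale 1) and a logistic-regression meta-model maps them to the
  final seizure probability.  The meta-model is fit on the target
  patient's validation split, which the base models' weights were never
  trained on, to avoid optimistic leakage.
* ``average`` — the arithmetic mean of the three models' probabilities.

Metrics: confusion matrix at a stated threshold (default 0.5, ties count
as positive), accuracy / precision / recall / F1 from its counts, and the
ROC curve with AUC equal to the Mann-Whitney probability
P(score_pos > score_neg) + P(tie)/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .models import extract_features, forward_probability
from .types import ValidationError

__all__ = [
    "MetaModel",
    "ConfusionMatrix",
    "MetricsReport",
    "fit_meta",
    "meta_probability",
    "predict_ensemble",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "evaluate",
]

ENSEMBLE_MODES = ("stack", "average")


@dataclass
class MetaModel:
    """Binary logistic regression over concatenated backbone features."""

    weights: np.ndarray
    bias: float
    l2: float

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(features) @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-z))


def fit_meta(features: np.ndarray, labels: np.ndarray, l2: float = 1.0
             ) -> MetaModel:
    """Fit the logistic meta-model by L2-penalized maximum likelihood.

    ``features``: [n, d] concatenated per-window feature vectors;
    ``l2``: penalty strength (0 disables the penalty).  Optimized to
    convergence tolerance 1e-6.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2 or len(features) != len(labels):
        raise ValidationError("features must be [n, d] aligned with labels")
    if len(np.unique(labels)) < 2:
        raise ValidationError("meta-model fitting needs both classes present")
    C = 1.0 / l2 if l2 > 0 else np.inf
    clf = LogisticRegression(C=C, tol=1e-6, solver="lbfgs", max_iter=5000)
    clf.fit(features, labels)
    return MetaModel(weights=clf.coef_[0].copy(), bias=float(clf.intercept_[0]),
                     l2=float(l2))


def stacked_features(models: dict, images) -> np.ndarray:
    """Concatenate penultimate features across the three architectures.

    ``models`` maps arch name -> model, concatenated in the fixed order
    custom2dcnn, resnet18, efficientnet_b0.
    """
    from .models import ARCHS  # canonical order

    missing = [a for a in ARCHS if a not in models]
    if missing:
        raise ValidationError(f"stack mode requires all three archs; missing {missing}")
    feats = [np.atleast_2d(extract_features(models[a], images)) for a in ARCHS]
    return np.concatenate(feats, axis=1)


def meta_probability(models: dict, meta: MetaModel, images) -> np.ndarray:
    return meta.predict_proba(stacked_features(models, images))


def predict_ensemble(models: dict, meta: MetaModel | None, image,
                     mode: str = "stack") -> np.ndarray:
    """Ensemble seizure probability for one image or a batch.

    ``stack``: logistic meta-model on concatenated features (requires all
    three models and a fitted meta-model).  ``average``: arithmetic mean
    of the available models' probabilities.
    """
    if mode not in ENSEMBLE_MODES:
        raise ValidationError(f"unknown ensemble mode {mode!r}")
    if mode == "stack":
        if meta is None:
            raise ValidationError("stack mode requires a fitted meta-model")
        return meta_probability(models, meta, image)
    if not models:
        raise ValidationError("average mode requires at least one model")
    probs = [np.atleast_1d(forward_probability(m, image)) for m in models.values()]
    return np.mean(probs, axis=0)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float = 0.5

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally the confusion matrix; prediction is 1 iff p >= threshold."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise ValidationError(f"labels {y.shape} and probabilities {p.shape} differ")
    pred = (p >= threshold).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        threshold=float(threshold),
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> dict:
    """accuracy, precision, recall, F1 from confusion counts.

    Zero-denominator cases return 0.0 and are recorded in ``flags``.
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    flags = []

    def safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = safe(cm.tp, cm.tp + cm.fp, "precision_undefined")
    recall = safe(cm.tp, cm.tp + cm.fn, "recall_undefined")
    f1 = safe(2 * precision * recall, precision + recall, "f1_undefined")
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "flags": flags,
    }


def roc_auc(labels, scores) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney probability) plus ROC points from a threshold sweep.

    Returns (auc, points) with points[:, 0] = FPR, points[:, 1] = TPR,
    monotone non-decreasing in both coordinates.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC/AUC needs both classes present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, np.column_stack([fpr, tpr])


@dataclass
class MetricsReport:
    """Full evaluation of one scorer on one labeled split."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc: np.ndarray
    threshold: float
    confusion: ConfusionMatrix
    mode: str = "single"
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": {"tp": self.confusion.tp, "tn": self.confusion.tn,
                          "fp": self.confusion.fp, "fn": self.confusion.fn},
            "roc": self.roc.tolist(),
            "flags": list(self.flags),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def evaluate(labels, probabilities, threshold: float = 0.5,
             mode: str = "single") -> MetricsReport:
    """Confusion matrix, threshold metrics and ROC/AUC for one scorer."""
    cm = confusion(labels, probabilities, threshold)
    m = metrics_from_confusion(cm)
    auc, roc = roc_auc(labels, probabilities)
    return MetricsReport(
        accuracy=m["accuracy"], precision=m["precision"], recall=m["recall"],
        f1=m["f1"], auc=auc, roc=roc, threshold=threshold, confusion=cm,
        mode=mode, flags=m["flags"],
    )
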