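"""Macro-averaged multi-label metrics and feature-separability diagnostics.

Per label: AUROC (rank statistic with midranks for ties), AUPRC
(precision-recall step integration), and thresholded F1/Precision/Recall.
Macro values are unweighted means over labels for which the metric is
defined; labels lacking both a positive and a negative example are excluded
from the macro mean and reported explicitly — in small validation splits rare
labels can legitimately lack positives.

The silhouette diagnostic scores the separation of a label's positive and
negative banks in the original feature space: per point, (b - a)/max(a, b)
with a the mean intra-cluster Euclidean distance and b the mean distance to
the other cluster; a point in a singleton cluster scores 0 by convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import (average_precision_score,
                             precision_recall_fscore_support, roc_auc_score)

from .errors import ValidationError

METRIC_NAMES = ("auc", "auprc", "f1", "precision", "recall")


@dataclass
class MetricReport:
    label_names: list[str]
    per_label: dict          # metric name -> list (NaN where undefined)
    macro: dict              # metric name -> float
    threshold: float
    n_samples: int
    undefined_labels: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        clean = {m: [None if np.isnan(v) else float(v) for v in vals]
                 for m, vals in self.per_label.items()}
        return json.dumps({
            "label_names": self.label_names,
            "per_label": clean,
            "macro": {k: float(v) for k, v in self.macro.items()},
            "threshold": self.threshold,
            "n_samples": self.n_samples,
            "undefined_labels": self.undefined_labels,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        obj = json.loads(text)
        per_label = {m: [np.nan if v is None else v for v in vals]
                     for m, vals in obj["per_label"].items()}
        return cls(label_names=obj["label_names"], per_label=per_label,
                   macro=obj["macro"], threshold=obj["threshold"],
                   n_samples=obj["n_samples"],
                   undefined_labels=obj["undefined_labels"])


def macro_metrics(scores, y, threshold: float = 0.5,
                  label_names: list[str] | None = None) -> MetricReport:
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y)
    if scores.ndim == 1:
        scores = scores[:, None]
        y = y.reshape(-1, 1)
    if scores.shape != y.shape:
        raise ValidationError(
            f"scores {scores.shape} and labels {y.shape} shape mismatch")
    if scores.min() < 0 or scores.max() > 1:
        raise ValidationError("scores must be probabilities in [0, 1]")
    n, k = scores.shape
    label_names = label_names or [f"label_{i + 1}" for i in range(k)]
    per = {m: [] for m in METRIC_NAMES}
    undefined = []
    for i in range(k):
        yi, si = y[:, i], scores[:, i]
        if yi.min() == yi.max():
            undefined.append(label_names[i])
            for m in METRIC_NAMES:
                per[m].append(np.nan)
            continue
        if np.ptp(si) == 0:
            auc = 0.5  # constant scorer: every pair tied, midrank convention
        else:
            auc = float(roc_auc_score(yi, si))
        per["auc"].append(auc)
        per["auprc"].append(float(average_precision_score(yi, si)))
        pred = (si >= threshold).astype(int)
        p, r, f1, _ = precision_recall_fscore_support(
            yi, pred, average="binary", zero_division=0)
        per["precision"].append(float(p))
        per["recall"].append(float(r))
        per["f1"].append(float(f1))
    if undefined:
        warnings.warn(
            f"labels excluded from macro means (single-class): {undefined}",
            stacklevel=2)
    macro = {}
    for m in METRIC_NAMES:
        vals = np.asarray(per[m], dtype=np.float64)
        defined = vals[~np.isnan(vals)]
        macro[m] = float(defined.mean()) if defined.size else float("nan")
    return MetricReport(label_names=label_names, per_label=per, macro=macro,
                        threshold=threshold, n_samples=n,
                        undefined_labels=undefined)


def silhouette_score(vectors, assignments) -> float:
    """Mean silhouette over points for a binary cluster assignment."""
    x = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(assignments)
    if x.shape[0] != labels.shape[0]:
        raise ValidationError("vectors and assignments length mismatch")
    if x.shape[0] < 3:
        raise ValidationError("silhouette needs at least 3 points")
    ids = np.unique(labels)
    if ids.size != 2:
        raise ValidationError("silhouette expects exactly two clusters")
    d = cdist(x, x)
    scores = np.zeros(x.shape[0])
    for k, pt_label in enumerate(labels):
        own = labels == pt_label
        n_own = own.sum()
        if n_own == 1:
            scores[k] = 0.0  # singleton-cluster convention
            continue
        a = d[k, own].sum() / (n_own - 1)
        b = d[k, ~own].mean()
        top = max(a, b)
        scores[k] = 0.0 if top == 0 else (b - a) / top
    return float(scores.mean())


def pool_silhouettes(pool) -> dict[str, float]:
    """Silhouette of {positive bank vs negative bank} per label."""
    out = {}
    for i, name in enumerate(pool.label_names):
        pos, neg = pool.bank(i, True), pool.bank(i, False)
        x = np.concatenate([pos, neg], axis=0)
        assign = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        out[name] = silhouette_score(x, assign)
    return out


def evaluate_checkpoint(model, pool, dataset, threshold: float = 0.5,
                        batch_size: int = 40):
    """Run inference and report macro metrics plus per-label pool silhouettes."""
    if pool is not None and list(pool.label_names) != list(dataset.label_names):
        raise ValidationError(
            f"label-name mismatch: pool has {pool.label_names}, dataset has "
            f"{dataset.label_names}")
    if model.n_labels != dataset.n_labels:
        raise ValidationError(
            f"model predicts {model.n_labels} labels, dataset has "
            f"{dataset.n_labels}")
    scores = model.predict_proba(dataset.images, batch_size=batch_size)
    report = macro_metrics(scores, dataset.labels, threshold=threshold,
                           label_names=list(dataset.label_names))
    silhouettes = pool_silhouettes(pool) if pool is not None else {}
    return report, silhouettes
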