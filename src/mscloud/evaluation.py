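"""Accuracy assessment and variable importance.

Per-class metrics follow the one-vs-all convention standard in
remote-sensing accuracy assessment: for class c with TP true positives,
FP false positives and FN false negatives read off the confusion matrix,

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the 0/0 cases defined as 0 so every class always has a complete row.
Overall accuracy is the confusion-matrix trace over the total, and the
chance-corrected agreement is Cohen's kappa,
kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
product of row and column marginals.

Variable importance for random forests is the mean decrease in Gini
impurity: every time a feature splits a node, the drop in
sample-weighted Gini impurity (G = 1 - sum p_i^2 over class fractions
p_i) is credited to that feature; credits are summed over all nodes and
divided by the number of trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion",
    "one_vs_all_metrics",
    "overall_accuracy",
    "kappa",
    "gini_index",
    "importance_report",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are the reference class, columns the prediction."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if counts.shape[0] != len(self.classes):
            raise ValueError("counts size does not match class list")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_index(self, cls) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise KeyError(f"unknown class {cls!r}") from None


def confusion(reference, predicted, classes=None) -> ConfusionMatrix:
    """Confusion matrix of a predicted labeling against the reference.

    ``classes`` fixes the row/column order; it defaults to the sorted
    union of observed labels.  Labels outside ``classes`` are an error.
    """
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {reference.shape} reference vs "
            f"{predicted.shape} predicted labels"
        )
    if classes is None:
        classes = np.unique(np.concatenate([reference, predicted])).tolist()
    classes = list(classes)
    known = set(classes)
    bad = set(np.unique(reference)) | set(np.unique(predicted))
    bad -= known
    if bad:
        raise ValueError(f"labels {sorted(bad)} not in class list {classes}")
    counts = _sk_confusion(reference, predicted, labels=classes)
    return ConfusionMatrix(counts, tuple(classes))


def one_vs_all_metrics(cm: ConfusionMatrix, cls) -> tuple[float, float, float]:
    """(precision, recall, F1) for one class against all others."""
    i = cm.class_index(cls)
    tp = cm.counts[i, i]
    fp = cm.counts[:, i].sum() - tp
    fn = cm.counts[i, :].sum() - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return float(precision), float(recall), float(f1)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of points on the confusion-matrix diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement from the marginals.

    Degenerate matrices with expected agreement 1 (all mass in one
    row-column pair) are defined to have kappa 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.total
    p_o = np.trace(cm.counts) / n
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / (n * n)
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def gini_index(class_fractions) -> float:
    """Gini impurity ``1 - sum p_i^2`` of a class-fraction vector.

    0 for a pure node; approaches 1 as classes mix evenly.
    """
    p = np.asarray(class_fractions, dtype=np.float64)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("class fractions must be a 1D vector")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(
            "class fractions must be non-negative and sum to 1"
        )
    return float(1.0 - np.sum(p * p))


def importance_report(clf) -> pd.DataFrame:
    """Mean-decrease-in-Gini importance ranking of a fitted random forest.

    Walks every tree: at each internal node the drop in sample-weighted
    impurity between the node and its two children — impurity recomputed
    from the node class counts with :func:`gini_index` — is credited to
    the splitting feature.  Credits are summed over the forest and
    divided by the number of trees.  Only the random forest exposes this;
    other families raise.

    Returns a DataFrame with columns ``feature`` and
    ``mean_gini_decrease`` sorted descending, covering every feature
    bound at fit time.
    """
    if getattr(clf, "family", None) != "rf":
        raise ValueError(
            "variable importance via Gini decrease requires a fitted "
            f"random forest (family='rf'), got family={clf.family!r}"
        )
    forest = clf.model_
    names = clf.feature_names_
    totals = np.zeros(len(names))
    for est in forest.estimators_:
        tree = est.tree_
        # class-fraction vector per node; robust to whether tree.value
        # stores raw counts or already-normalized fractions
        value = tree.value[:, 0, :]
        fractions = value / value.sum(axis=1, keepdims=True)
        weight = tree.weighted_n_node_samples / tree.weighted_n_node_samples[0]
        impurity = weight * np.array([gini_index(p) for p in fractions])
        for node in range(tree.node_count):
            left = tree.children_left[node]
            right = tree.children_right[node]
            if left == -1:  # leaf
                continue
            dec = impurity[node] - impurity[left] - impurity[right]
            totals[tree.feature[node]] += dec
    totals /= len(forest.estimators_)
    report = pd.DataFrame(
        {"feature": names, "mean_gini_decrease": totals}
    ).sort_values("mean_gini_decrease", ascending=False, kind="mergesort")
    return report.reset_index(drop=True)


@dataclass
class EvaluationReport:
    """Full accuracy assessment of one predicted labeling."""

    confusion: ConfusionMatrix
    per_class: pd.DataFrame  # columns: class, precision, recall, f1
    overall_accuracy: float
    kappa: float
    importance: pd.DataFrame | None = None
    class_names: dict[int, str] | None = None

    def to_dict(self) -> dict:
        d = {
            "classes": list(self.confusion.classes),
            "confusion": self.confusion.counts.tolist(),
            "per_class": self.per_class.to_dict(orient="records"),
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
        }
        if self.importance is not None:
            d["importance"] = self.importance.to_dict(orient="records")
        if self.class_names is not None:
            d["class_names"] = {int(k): v for k, v in self.class_names.items()}
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_csv(self, path: str | Path) -> None:
        """Per-class table plus overall accuracy / kappa summary rows."""
        rows = self.per_class.copy()
        rows["class"] = [self._name(c) for c in rows["class"]]
        summary = pd.DataFrame(
            {
                "class": ["Ov. Acc", "Kappa"],
                "precision": [self.overall_accuracy, self.kappa],
                "recall": [np.nan, np.nan],
                "f1": [np.nan, np.nan],
            }
        )
        pd.concat([rows, summary], ignore_index=True).to_csv(
            path, index=False, float_format="%.6f"
        )

    def _name(self, cls):
        if self.class_names and cls in self.class_names:
            return self.class_names[cls]
        return cls


def evaluate(
    reference,
    predicted,
    classes=None,
    importance: pd.DataFrame | None = None,
    class_names: dict[int, str] | None = None,
) -> EvaluationReport:
    """One-call accuracy assessment: confusion, per-class metrics, OA, kappa."""
    cm = confusion(reference, predicted, classes)
    rows = []
    for cls in cm.classes:
        p, r, f1 = one_vs_all_metrics(cm, cls)
        rows.append({"class": cls, "precision": p, "recall": r, "f1": f1})
    return EvaluationReport(
        confusion=cm,
        per_class=pd.DataFrame(rows),
        overall_accuracy=overall_accuracy(cm),
        kappa=kappa(cm),
        importance=importance,
        class_names=class_names,
    )
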