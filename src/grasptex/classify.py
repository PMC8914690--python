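"""Shallow classifiers, stratified cross-validation, and evaluation metrics.

Two families are used throughout the pipeline: a 1-nearest-neighbour
classifier with Manhattan (L1) distance and no distance weighting, and
a cubic support vector machine (degree-3 polynomial kernel
(1 + <u, v>)^3 after automatic kernel scaling, box constraint C = 1,
one-vs-one coding). Evaluation is by stratified 10-fold
cross-validation; reports carry the 6x6 confusion matrix in canonical
class order C, H, L, P, S, T plus accuracy, per-class recall /
precision / F1 and their macro averages, all in percent.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data import GraspClass

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "kernel_scale",
    "crossval_predict",
    "evaluation_report",
]


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of one shallow-classifier family.

    ``kernel_scale=None`` requests the automatic heuristic: features are
    divided by the median pairwise L1 distance of a seeded subsample
    (at most 1000 points) before the polynomial kernel.
    """

    family: str  # "kNN" or "SVM"
    k: int = 1
    svm_degree: int = 3
    svm_c: float = 1.0
    kernel_scale: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("kNN", "SVM"):
            raise ValueError(f"unknown classifier family: {self.family!r}")


def kernel_scale(X: np.ndarray, seed: int = 0, max_points: int = 1000) -> float:
    """Median pairwise L1 distance over a seeded subsample (0 -> 1)."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    idx = rng.choice(n, size=min(n, max_points), replace=False)
    sub = X[idx]
    from scipy.spatial.distance import pdist

    d = pdist(sub, metric="cityblock")
    s = float(np.median(d)) if d.size else 0.0
    return s if s > 0 else 1.0


def _build(spec: ClassifierSpec):
    if spec.family == "kNN":
        return KNeighborsClassifier(n_neighbors=spec.k, metric="manhattan", weights="uniform")
    # gamma=1 with pre-scaled features gives the kernel (1 + <u, v>)^3
    return SVC(
        kernel="poly",
        degree=spec.svm_degree,
        C=spec.svm_c,
        gamma=1.0,
        coef0=1.0,
        decision_function_shape="ovo",
    )


def crossval_predict(X, y, spec: ClassifierSpec, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold predictions under stratified k-fold cross-validation.

    Every observation is predicted exactly once by a model trained on
    the remaining folds; fold assignment is a pure function of ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {folds} folds; use fewer folds"
        )
    if spec.family == "SVM":
        s = spec.kernel_scale if spec.kernel_scale is not None else kernel_scale(X, seed=seed)
        X = X / s
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=y.dtype)
    for train, test in skf.split(X, y):
        model = _build(spec)
        model.fit(X[train], y[train])
        out = model.predict(X[test])
        pred[test] = out
    return pred


@dataclasses.dataclass
class EvaluationReport:
    """Confusion matrix and the derived percentage metrics."""

    confusion: np.ndarray  # (6, 6) rows = true, cols = predicted
    accuracy: float
    recall: np.ndarray  # per class, %
    precision: np.ndarray
    f1: np.ndarray
    macro_recall: float
    macro_precision: float
    macro_f1: float
    class_order: tuple[str, ...] = tuple(c.name for c in GraspClass.ordered())

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "recall": self.recall.tolist(),
            "precision": self.precision.tolist(),
            "f1": self.f1.tolist(),
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Render the confusion matrix and metric rows as a plain-text table."""
        names = self.class_order
        width = max(7, max(len(n) for n in names) + 1)
        rows = ["True\\Pred".ljust(10) + "".join(n.rjust(width) for n in names)]
        for i, name in enumerate(names):
            rows.append(
                name.ljust(10) + "".join(str(int(v)).rjust(width) for v in self.confusion[i])
            )
        for label, vals in (
            ("Recall%", self.recall),
            ("Prec%", self.precision),
            ("F1%", self.f1),
        ):
            rows.append(label.ljust(10) + "".join(f"{v:.2f}".rjust(width) for v in vals))
        rows.append(f"Accuracy: {self.accuracy:.2f}%")
        return "\n".join(rows)


def _labels_to_names(y) -> np.ndarray:
    return np.array([v.name if isinstance(v, GraspClass) else str(v) for v in y])


def evaluation_report(y_true, y_pred) -> EvaluationReport:
    """Compute the full metric set from true and predicted labels."""
    yt, yp = _labels_to_names(y_true), _labels_to_names(y_pred)
    if len(yt) == 0:
        raise ValueError("empty input")
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred must have equal lengths")
    order = [c.name for c in GraspClass.ordered()]
    index = {name: i for i, name in enumerate(order)}
    confusion = np.zeros((6, 6), dtype=int)
    for t, p in zip(yt, yp):
        confusion[index[t], index[p]] += 1
    return report_from_confusion(confusion)


def report_from_confusion(confusion) -> EvaluationReport:
    """Derive all percentage metrics from a 6x6 confusion matrix."""
    confusion = np.asarray(confusion, dtype=int)
    if confusion.shape != (6, 6):
        raise ValueError("confusion matrix must be 6x6")
    n = confusion.sum()
    tp = np.diag(confusion).astype(float)
    row = confusion.sum(axis=1).astype(float)
    col = confusion.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, 100.0 * tp / row, 0.0)
        precision = np.where(col > 0, 100.0 * tp / col, 0.0)
        f1 = np.where(recall + precision > 0, 2 * recall * precision / (recall + precision), 0.0)
    if np.any(col == 0):
        warnings.warn("empty predicted-class column: precision reported as 0", stacklevel=2)
    return EvaluationReport(
        confusion=confusion,
        accuracy=float(100.0 * tp.sum() / n),
        recall=recall,
        precision=precision,
        f1=f1,
        macro_recall=float(recall.mean()),
        macro_precision=float(precision.mean()),
        macro_f1=float(f1.mean()),
    )
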