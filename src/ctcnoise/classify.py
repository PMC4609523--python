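"""Binary CTC classifiers and performance measures.

Two classifiers are supported, with the hyperparameters fixed up front:
a Breiman random forest of 500 trees, and a soft-margin SVM with RBF
kernel exp(-γ‖x−y‖²), C = 2 and γ = 0.005 (γ the inverse squared kernel
radius).  No probability calibration or threshold tuning is applied:
hard labels only.  Fitting is delegated to scikit-learn; this module
owns the contract and the evaluation measures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

ClassifierKind = Literal["random_forest", "svm_rbf"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to fit and with what fixed hyperparameters."""

    kind: ClassifierKind
    n_trees: int = 500  # RF only
    C: float = 2.0  # SVM only
    gamma: float = 0.005  # SVM only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "svm_rbf"):
            raise ValueError(f"unknown classifier kind: {self.kind}")
        if self.kind == "random_forest" and self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.kind == "svm_rbf" and (self.C <= 0 or self.gamma <= 0):
            raise ValueError("C and gamma must be positive")

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return ClassifierSpec(self.kind, self.n_trees, self.C, self.gamma, seed)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "n_trees": self.n_trees,
                "C": self.C,
                "gamma": self.gamma,
                "seed": self.seed,
            }
        )


def train(spec: ClassifierSpec, features: np.ndarray, labels: np.ndarray):
    """Fit a classifier on a feature matrix and binary label vector.

    The RF uses sqrt(p) features per split and unlimited depth (the
    standard Breiman defaults) and is reproducible given the spec seed;
    the SVM is deterministic given the data.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must be row-aligned")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    if spec.kind == "random_forest":
        model = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features="sqrt",
            random_state=spec.seed,
            n_jobs=1,
        )
    else:
        model = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
    model.fit(X, y)
    return model


def predict(model, features: np.ndarray) -> np.ndarray:
    """Hard binary label per feature row."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=np.int8)
    if X.ndim != 2 or X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else 'n/a'} does not "
            f"match training width {model.n_features_in_}"
        )
    return model.predict(X).astype(np.int8)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )


@dataclass(frozen=True)
class PerformanceReport:
    """Accuracy, precision and recall with dispersion across
    folds/repetitions for one experimental condition.

    Precision (recall) is NaN — a flagged missing value — when no
    positive prediction (no positive reference point) exists.
    """

    accuracy: float
    precision: float
    recall: float
    accuracy_sd: float = 0.0
    precision_sd: float = 0.0
    recall_sd: float = 0.0
    condition_label: str = ""

    def as_dict(self) -> dict:
        return {
            "condition": self.condition_label,
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "precision": self.precision,
            "precision_sd": self.precision_sd,
            "recall": self.recall,
            "recall_sd": self.recall_sd,
        }

    def __str__(self) -> str:  # Table-style two-decimal rendering
        return (
            f"{self.condition_label}: "
            f"Acc {self.accuracy:.2f} ± {self.accuracy_sd:.2f}, "
            f"Pre {self.precision:.2f} ± {self.precision_sd:.2f}, "
            f"Rec {self.recall:.2f} ± {self.recall_sd:.2f}"
        )


def confusion(predictions, reference) -> ConfusionCounts:
    p = np.asarray(predictions).astype(int)
    r = np.asarray(reference).astype(int)
    if p.shape != r.shape:
        raise ValueError("predictions and reference must have equal length")
    return ConfusionCounts(
        TP=int(((p == 1) & (r == 1)).sum()),
        FP=int(((p == 1) & (r == 0)).sum()),
        TN=int(((p == 0) & (r == 0)).sum()),
        FN=int(((p == 0) & (r == 1)).sum()),
    )


def measures(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, precision, recall) from confusion counts; undefined
    ratios are NaN."""
    acc = (counts.TP + counts.TN) / counts.total if counts.total else math.nan
    pre = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else math.nan
    rec = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else math.nan
    return acc, pre, rec


def score(predictions, reference, condition_label: str = "") -> tuple[ConfusionCounts, PerformanceReport]:
    """Confusion counts and Acc/Pre/Rec of a prediction against a
    reference labelling."""
    counts = confusion(predictions, reference)
    acc, pre, rec = measures(counts)
    return counts, PerformanceReport(
        accuracy=acc, precision=pre, recall=rec, condition_label=condition_label
    )
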