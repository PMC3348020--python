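"""Discriminate mutants that increase vs. decrease EC50.

Each mutant is labelled from the sign of its response change (positive class
= "increase"; note a higher EC50 means *lower* potency) and encoded, per
selected property, as the quadruple

    [P(wild), P(mutant), dP, window sum of the local-sequence effect],

then classified with a small fixed set of standard methods (logistic
discriminant, Gaussian naive Bayes, k-nearest-neighbour, decision tree).
All methods are evaluated and reported -- the report includes the maximum,
but nothing is silently selected post hoc.

Evaluation follows two protocols: self-consistency (train and test on all N)
and the jack-knife (leave-one-out) test, in which each mutant is predicted
exactly once by a model trained on the other N-1.  Any feature
standardization is fit inside the training fold only, so the left-out mutant
never leaks into training.  Performance is scored by sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy (TP+TN)/N.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    FeatureContextError,
    LabelingError,
    SingleClassError,
    UndefinedStatisticError,
    UnknownMethodError,
)
from .features import (
    MutantDataset,
    delta_property,
    local_sequence_effect,
)
from .properties import PropertyTable
from .regression import _as_matrix  # shared FeatureMatrix/DataFrame coercion

INCREASE, DECREASE = "increase", "decrease"


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledDataset:
    """Feature rows plus an increase/decrease label per mutant."""

    features: pd.DataFrame
    labels: np.ndarray  # 1 = increase, 0 = decrease

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if len(labels) != len(self.features):
            raise LabelingError("label count differs from feature row count")
        if not set(np.unique(labels)) <= {0, 1}:
            raise LabelingError("labels must be 0 (decrease) or 1 (increase)")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_increase(self) -> int:
        return int(self.labels.sum())

    @property
    def n_decrease(self) -> int:
        return int(self.n - self.labels.sum())

    @property
    def trainable(self) -> bool:
        return 0 < self.n_increase < self.n


@dataclass(frozen=True)
class ConfusionMetrics:
    """TP/FP/TN/FN counts and the derived sensitivity/specificity/accuracy."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedStatisticError("sensitivity undefined: no positive instances")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedStatisticError("specificity undefined: no negative instances")
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Build :class:`ConfusionMetrics` from the four counts."""
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def _confusion_from_predictions(labels: np.ndarray, predicted: np.ndarray) -> ConfusionMetrics:
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    return ConfusionMetrics(
        tp=int(((labels == 1) & (predicted == 1)).sum()),
        fp=int(((labels == 0) & (predicted == 1)).sum()),
        tn=int(((labels == 0) & (predicted == 0)).sum()),
        fn=int(((labels == 1) & (predicted == 0)).sum()),
    )


@dataclass
class EvaluationReport:
    """Self-consistency and jack-knife metrics for every evaluated method."""

    metrics: dict[str, dict[str, ConfusionMetrics]]  # method -> mode -> metrics
    configuration: dict = field(default_factory=dict)
    seed: int = 0

    def best(self, mode: str = "jackknife") -> tuple[str, ConfusionMetrics]:
        """(method, metrics) with the highest accuracy under the given mode."""
        return max(
            ((m, modes[mode]) for m, modes in self.metrics.items() if mode in modes),
            key=lambda kv: (kv[1].accuracy, kv[0]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, modes in self.metrics.items():
            for mode, cm in modes.items():
                rows.append({"method": method, "mode": mode, **cm.to_dict(),
                             "seed": self.seed})
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | PathLike) -> None:
        payload = {
            "configuration": self.configuration,
            "seed": self.seed,
            "metrics": {
                m: {mode: cm.to_dict() for mode, cm in modes.items()}
                for m, modes in self.metrics.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# labelling and encoding
# ---------------------------------------------------------------------------

def label_by_sign(responses) -> np.ndarray:
    """Map signed response changes to labels: positive -> increase (1).

    A zero response is ambiguous and raises; no silent default.
    """
    responses = np.asarray(responses, dtype=float)
    if np.any(responses == 0):
        rows = np.nonzero(responses == 0)[0].tolist()
        raise LabelingError(f"response exactly 0 at row(s) {rows}: increase/decrease undefined")
    return (responses > 0).astype(int)


def encode_for_classification(
    table: PropertyTable,
    dataset: MutantDataset,
    property_ids: Sequence[str] | None = None,
    k: int = 1,
    scale: str = "normalized",
    labels: np.ndarray | None = None,
) -> LabeledDataset:
    """Feature vectors [P(wild), P(mutant), dP, window sum] per property.

    Labels default to the sign of each record's response.  Requires the
    dataset sequence for the window term (same truncation convention as the
    regression features).
    """
    if dataset.sequence is None:
        raise FeatureContextError("classification encoding needs the receptor sequence "
                                  "for its window term")
    if property_ids is None:
        property_ids = table.property_ids
    if labels is None:
        labels = label_by_sign(dataset.responses)
    columns: dict[str, np.ndarray] = {}
    for pid in property_ids:
        wild = np.array([table.get_value(pid, r.wild, scale) for r in dataset.records])
        mut = np.array([table.get_value(pid, r.mutant, scale) for r in dataset.records])
        delta = np.array(
            [delta_property(table, pid, r.wild, r.mutant, scale) for r in dataset.records]
        )
        window = np.array(
            [
                local_sequence_effect(
                    table, pid, dataset.sequence, r.position, r.mutant, k, scale
                )
                for r in dataset.records
            ]
        )
        columns[f"wild:{pid}"] = wild
        columns[f"mutant:{pid}"] = mut
        columns[f"delta:{pid}"] = delta
        columns[f"seq_window(k={k}):{pid}"] = window
    frame = pd.DataFrame(columns, index=dataset.names)
    return LabeledDataset(features=frame, labels=labels)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _make_classifier(method: str, seed: int):
    if method == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=5000, random_state=seed),
        )
    if method == "naive_bayes":
        return GaussianNB()
    if method == "knn1":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=1))
    if method == "knn3":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=3))
    if method == "tree":
        return DecisionTreeClassifier(random_state=seed)
    raise UnknownMethodError(
        f"unknown classifier method {method!r}; bundled methods: {sorted(METHODS)}"
    )


#: The fixed bundled classifier set (all are evaluated and reported).
METHODS: tuple[str, ...] = ("logistic", "naive_bayes", "knn1", "knn3", "tree")


def train_and_classify(data: LabeledDataset, method: str, seed: int = 0):
    """Fit one bundled classifier on the full dataset; returns the fitted model.

    Deterministic given (data, method, seed).  Raises on single-class data.
    """
    if not data.trainable:
        raise SingleClassError(
            f"cannot train on a single class ({data.n_increase} increase / "
            f"{data.n_decrease} decrease)"
        )
    clf = _make_classifier(method, seed)
    clf.fit(data.features.to_numpy(dtype=float), data.labels)
    return clf


def self_consistency(data: LabeledDataset, method: str, seed: int = 0) -> ConfusionMetrics:
    """Train on all N mutants and evaluate on the same N."""
    clf = train_and_classify(data, method, seed)
    predicted = clf.predict(data.features.to_numpy(dtype=float))
    return _confusion_from_predictions(data.labels, predicted)


def jackknife(data: LabeledDataset, method: str, seed: int = 0) -> ConfusionMetrics:
    """Leave-one-out test: each mutant predicted by a model that never saw it.

    N folds of sizes (N-1, 1); standardization (where the method uses it) is
    refit on the N-1 training rows of each fold.  A fold whose training set
    collapses to one class predicts that training majority class (warned).
    """
    if data.n < 3:
        raise SingleClassError(f"jack-knife needs N >= 3, got N = {data.n}")
    if not data.trainable:
        raise SingleClassError("jack-knife needs both classes present")
    if min(data.n_increase, data.n_decrease) < 2:
        warnings.warn(
            "a class has a single member: the fold leaving it out trains on one "
            "class and predicts the training majority",
            stacklevel=2,
        )
    X = data.features.to_numpy(dtype=float)
    labels = data.labels
    predicted = np.empty(data.n, dtype=int)
    for i in range(data.n):
        mask = np.ones(data.n, dtype=bool)
        mask[i] = False
        y_train = labels[mask]
        if y_train.min() == y_train.max():
            predicted[i] = int(y_train[0])
            continue
        clf = _make_classifier(method, seed)
        clf.fit(X[mask], y_train)
        predicted[i] = int(clf.predict(X[i : i + 1])[0])
    return _confusion_from_predictions(labels, predicted)


def evaluate_methods(
    data: LabeledDataset,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    configuration: dict | None = None,
) -> EvaluationReport:
    """Self-consistency and jack-knife metrics for every requested method."""
    metrics: dict[str, dict[str, ConfusionMetrics]] = {}
    for method in methods:
        metrics[method] = {
            "self": self_consistency(data, method, seed),
            "jackknife": jackknife(data, method, seed),
        }
    return EvaluationReport(metrics=metrics, configuration=dict(configuration or {}),
                            seed=seed)


def jackknife_strict(
    table: PropertyTable,
    dataset: MutantDataset,
    method: str,
    n_properties: int = 3,
    k: int = 1,
    seed: int = 0,
    scale: str = "normalized",
) -> ConfusionMetrics:
    """Jack-knife with the property choice nested inside each fold.

    Within every fold the candidate properties are re-ranked by |r| of their
    delta feature against the training responses, the top ``n_properties``
    are selected, and the classifier is trained on the re-encoded training
    rows only.  Stricter (and typically lower-scoring) than the default
    protocol, which fixes the encoding once on the full data.
    """
    labels = label_by_sign(dataset.responses)
    responses = dataset.responses
    n = dataset.n
    predicted = np.empty(n, dtype=int)
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        train = dataset.subset(train_idx)
        # rank properties on the training fold only
        deltas = {
            pid: np.array(
                [delta_property(table, pid, r.wild, r.mutant, scale) for r in train.records]
            )
            for pid in table.property_ids
        }
        y_train = responses[train_idx]
        scores = {}
        for pid, d in deltas.items():
            if np.ptp(d) == 0 or np.ptp(y_train) == 0:
                continue
            scores[pid] = abs(np.corrcoef(d, y_train)[0, 1])
        chosen = sorted(scores, key=lambda p: (-scores[p], p))[:n_properties]
        enc_train = encode_for_classification(
            table, train, chosen, k=k, scale=scale, labels=labels[train_idx]
        )
        if not enc_train.trainable:
            predicted[i] = int(round(enc_train.labels.mean()))
            continue
        clf = train_and_classify(enc_train, method, seed)
        enc_test = encode_for_classification(
            table, dataset.subset([i]), chosen, k=k, scale=scale,
            labels=labels[i : i + 1],
        )
        predicted[i] = int(clf.predict(enc_test.features.to_numpy(dtype=float))[0])
    return _confusion_from_predictions(labels, predicted)
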