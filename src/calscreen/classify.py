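"""Decision-tree phenotyping of Ca2+ responses.

A binary entropy-gain decision tree (the C4.5/J48 family) is trained on
the 27-descriptor feature vectors to assign each cell one of the three
phenotype classes. Model quality is assessed by stratified k-fold
cross-validation aggregated into a 3x3 confusion matrix with overall
and per-class accuracies.

The tree learner is scikit-learn's ``DecisionTreeClassifier``
(criterion="entropy", minimum leaf size 2); NaN descriptor values are
legal inputs — each split learns at training time which branch missing
values follow. The fitted tree is exported into plain node arrays so
the model serializes to JSON and predictions are made by the package's
own traversal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import NUMERIC_COLUMNS, FeatureVector, features_frame
from .synth import PhenotypeClass
from .traces import TraceSeries

__all__ = [
    "CLASS_ORDER",
    "TreeParams",
    "TrainingSet",
    "DecisionTreeModel",
    "ConfusionMatrix",
    "train_tree",
    "cross_validate",
    "confusion_metrics",
]

#: Fixed class order of every confusion matrix (rows true, cols predicted).
CLASS_ORDER: tuple[str, ...] = (
    PhenotypeClass.OSC_PEAK.value,
    PhenotypeClass.PEAK.value,
    PhenotypeClass.OTHER.value,
)


@dataclass(frozen=True)
class TreeParams:
    """Hyperparameters of the decision-tree learner."""

    min_leaf: int = 2
    max_depth: int | None = None
    ccp_alpha: float = 0.0


@dataclass
class TrainingSet:
    """Labeled feature records.

    ``X`` is (n_records, n_features) float with NaN for missing
    descriptors; ``y`` holds class label strings. The benchmark
    composition is 333 OscillationAndPeak / 536 Peak / 840 Other.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = NUMERIC_COLUMNS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray([
            v.value if isinstance(v, PhenotypeClass) else str(v) for v in self.y
        ])
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-d with one row per label")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("X width must match feature_names")
        unknown = set(self.y) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")

    @property
    def class_counts(self) -> dict[str, int]:
        return {c: int((self.y == c).sum()) for c in CLASS_ORDER}

    def __len__(self) -> int:
        return int(self.y.size)

    @classmethod
    def from_frame(cls, features: pd.DataFrame, labels: Sequence) -> "TrainingSet":
        X = features[list(NUMERIC_COLUMNS)].to_numpy(dtype=float)
        return cls(X=X, y=np.asarray(list(labels), dtype=object))

    @classmethod
    def from_traces(cls, traces: list[TraceSeries], labels: Sequence) -> "TrainingSet":
        return cls.from_frame(features_frame(traces), labels)


@dataclass
class DecisionTreeModel:
    """A fitted binary decision tree in plain node arrays.

    Internal node k splits on ``feature[k] <= threshold[k]`` (left) vs
    greater (right); NaN inputs follow ``missing_left[k]``. Leaves carry
    the training class counts; prediction returns the majority class.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    missing_left: np.ndarray
    class_counts: np.ndarray  # (n_nodes, 3) in CLASS_ORDER
    feature_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return int(self.feature.size)

    def _leaf_for(self, x: np.ndarray) -> int:
        node = 0
        while self.children_left[node] >= 0:
            v = x[self.feature[node]]
            if np.isnan(v):
                go_left = bool(self.missing_left[node])
            else:
                go_left = v <= self.threshold[node]
            node = self.children_left[node] if go_left else self.children_right[node]
        return node

    def predict(self, fv: FeatureVector | np.ndarray | pd.DataFrame):
        """Predict the phenotype class of one FeatureVector, a numeric
        row, or each row of a matrix / feature DataFrame."""
        if isinstance(fv, FeatureVector):
            row = fv.to_row()
            x = np.array([row[name] for name in self.feature_names], dtype=float)
            return PhenotypeClass(CLASS_ORDER[self._predict_matrix(x[None, :])[0]])
        if isinstance(fv, pd.DataFrame):
            missing = set(self.feature_names) - set(fv.columns)
            if missing:
                raise ValueError(f"feature columns absent: {sorted(missing)}")
            X = fv[list(self.feature_names)].to_numpy(dtype=float)
            return np.array([CLASS_ORDER[k] for k in self._predict_matrix(X)])
        X = np.asarray(fv, dtype=float)
        if X.ndim == 1:
            if X.size != len(self.feature_names):
                raise ValueError("feature vector has the wrong length")
            return PhenotypeClass(CLASS_ORDER[self._predict_matrix(X[None, :])[0]])
        return np.array([CLASS_ORDER[k] for k in self._predict_matrix(X)])

    # Leaf ties are broken alphabetically by class name (the learner's
    # convention), not by CLASS_ORDER position.
    _TIE_ORDER = tuple(sorted(range(len(CLASS_ORDER)), key=lambda i: CLASS_ORDER[i]))

    def _predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix width mismatch")
        pref = np.asarray(self._TIE_ORDER)
        out = np.empty(X.shape[0], dtype=int)
        for i in range(X.shape[0]):
            leaf = self._leaf_for(X[i])
            counts = self.class_counts[leaf][pref]
            out[i] = int(pref[np.argmax(counts)])
        return out

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format": "calscreen-tree-v1",
            "classes": list(CLASS_ORDER),
            "feature_names": list(self.feature_names),
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "missing_left": self.missing_left.astype(int).tolist(),
            "class_counts": self.class_counts.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTreeModel":
        d = json.loads(text)
        if d.get("format") != "calscreen-tree-v1":
            raise ValueError("not a calscreen decision-tree JSON document")
        return cls(
            children_left=np.asarray(d["children_left"], dtype=int),
            children_right=np.asarray(d["children_right"], dtype=int),
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=float),
            missing_left=np.asarray(d["missing_left"], dtype=bool),
            class_counts=np.asarray(d["class_counts"], dtype=float),
            feature_names=tuple(d["feature_names"]),
            metadata=d.get("metadata", {}),
        )


def _export_sklearn(clf: DecisionTreeClassifier, feature_names, metadata) -> DecisionTreeModel:
    t = clf.tree_
    # Map sklearn's class order onto the fixed CLASS_ORDER columns.
    counts = np.zeros((t.node_count, len(CLASS_ORDER)))
    sk_value = t.value[:, 0, :]  # fractions per node in sklearn >= 1.3
    weights = t.weighted_n_node_samples
    for j, cls_name in enumerate(clf.classes_):
        counts[:, CLASS_ORDER.index(str(cls_name))] = sk_value[:, j] * weights
    try:
        missing_left = t.missing_go_to_left.astype(bool)
    except AttributeError:  # pragma: no cover - older sklearn
        missing_left = np.ones(t.node_count, dtype=bool)
    return DecisionTreeModel(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        missing_left=missing_left,
        class_counts=counts,
        feature_names=tuple(feature_names),
        metadata=metadata,
    )


def train_tree(
    ts: TrainingSet,
    params: TreeParams | None = None,
    seed: int = 0,
) -> DecisionTreeModel:
    """Train the phenotype decision tree.

    Deterministic given (training set, params, seed). A single-class
    training set degenerates to one leaf with a warning.
    """
    params = params or TreeParams()
    if len(set(ts.y)) == 1:
        warnings.warn("single-class training set: degenerate single-leaf tree")
    clf = DecisionTreeClassifier(
        criterion="entropy",
        min_samples_leaf=params.min_leaf,
        max_depth=params.max_depth,
        ccp_alpha=params.ccp_alpha,
        random_state=seed,
    )
    clf.fit(ts.X, ts.y)
    meta = {
        "seed": int(seed),
        "min_leaf": params.min_leaf,
        "max_depth": params.max_depth,
        "ccp_alpha": params.ccp_alpha,
        "n_train": len(ts),
        "class_counts": ts.class_counts,
    }
    return _export_sklearn(clf, ts.feature_names, meta)


@dataclass
class ConfusionMatrix:
    """3x3 class-count matrix in the benchmark table's orientation:
    columns = true (manually assigned) class, rows = predicted class,
    so each column sums to its class's record count and the per-class
    accuracy row is the column diagonal over the column sum."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square in the label order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def overall_accuracy(self) -> float:
        """Overall accuracy in percent (100 * n_correct / n_total)."""
        if self.n_total == 0:
            raise ValueError("empty confusion matrix")
        return 100.0 * self.n_correct / self.n_total

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Per-class accuracy in percent: column diagonal over column
        sum, i.e. the fraction of each true class predicted correctly
        (NaN for a class with no records)."""
        col_sums = self.counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = 100.0 * np.diag(self.counts) / col_sums
        return acc

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: predicted-class rows, true-class columns,
        and a final per-class "Acc. %" row rounded to one decimal."""
        df = pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))
        df.loc["Acc. %"] = np.round(self.per_class_accuracy, 1)
        return df


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, tuple[float, ...], int]:
    """Overall %, per-class % (both rounded to one decimal for
    reporting) and the number of correct assignments."""
    overall = round(cm.overall_accuracy, 1)
    per_class = tuple(
        float(round(a, 1)) if np.isfinite(a) else float("nan")
        for a in cm.per_class_accuracy
    )
    return overall, per_class, cm.n_correct


def cross_validate(
    ts: TrainingSet,
    k: int = 10,
    seed: int = 0,
    params: TreeParams | None = None,
) -> ConfusionMatrix:
    """Stratified k-fold cross-validation of the decision tree.

    Fold assignment is stratified by class and seeded; every record is
    predicted exactly once by a model not trained on it, and the counts
    are aggregated so that the matrix total equals the training-set
    size.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    for c, n in ts.class_counts.items():
        if 0 < n < k:
            raise ValueError(
                f"class {c} has only {n} members; use k <= {n}"
            )
    params = params or TreeParams()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    counts = np.zeros((3, 3), dtype=int)
    label_index = {c: i for i, c in enumerate(CLASS_ORDER)}
    for train_idx, test_idx in skf.split(ts.X, ts.y):
        fold = TrainingSet(ts.X[train_idx], ts.y[train_idx], ts.feature_names)
        model = train_tree(fold, params, seed)
        pred = model.predict(ts.X[test_idx])
        for yt, yp in zip(ts.y[test_idx], pred):
            counts[label_index[yp], label_index[yt]] += 1
    return ConfusionMatrix(counts)
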