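"""The four base classifiers behind one fit/predict contract.

SVM (linear, one-against-the-rest), a naive-structure Bayesian network
classifier with Laplace smoothing, a decision tree standing in for C5.0,
and 3-nearest-neighbors -- all with fixed, documented hyperparameters on
the binarized SOM feature vectors.  scikit-learn provides the estimators;
this module pins their settings and the label/tie conventions.

Levels are coded 1 (mild) < 2 (moderate) < 3 (severe).  Wherever a
classifier must break a tie (equal votes, equal decision margins after the
argmax), the lower-severity level wins: estimators receive labels in
ascending severity order so scikit-learn's lowest-label tie-breaking
implements exactly that rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from embar.errors import ValidationError
from embar.records import AddictionLevel

CLASSIFIER_KINDS = ("svm", "bnc", "c5", "knn")

KNN_K = 3  # matches the three-level label set


@dataclass
class LabeledDataset:
    """Aligned binary feature vectors and addiction levels."""

    features: np.ndarray  # (n, d) uint8/0-1
    labels: np.ndarray  # (n,) int codes 1..3
    tag: str = "Tr"  # split tag, "Tr" or "Te"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.labels = np.asarray(
            [int(l) for l in np.asarray(self.labels).ravel()])
        if len(self.features) != len(self.labels):
            raise ValidationError("features and labels must be aligned")

    def __len__(self) -> int:
        return len(self.labels)


def _build_estimator(kind: str, seed: int):
    if kind == "svm":
        # linear kernel, C=1, explicit one-against-the-rest; prediction is
        # the binary machine with the highest decision margin
        return OneVsRestClassifier(SVC(kernel="linear", C=1.0))
    if kind == "bnc":
        # naive Bayes over binary features with Laplace (+1) smoothing
        return BernoulliNB(alpha=1.0)
    if kind == "c5":
        # entropy-criterion tree, min leaf 2: a documented stand-in for the
        # proprietary C5.0
        return DecisionTreeClassifier(criterion="entropy", min_samples_leaf=2,
                                      random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=KNN_K, metric="euclidean")
    raise ValidationError(
        f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")


@dataclass
class BaseClassifier:
    """One base classifier: ``fit`` then ``predict``; predict-before-fit errors."""

    kind: str
    seed: int = 0
    _estimator: object = field(default=None, repr=False)
    _n_features: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(
                f"unknown classifier kind {self.kind!r}; "
                f"expected one of {CLASSIFIER_KINDS}")

    @property
    def fitted(self) -> bool:
        return self._estimator is not None

    def fit(self, data: LabeledDataset) -> "BaseClassifier":
        classes = set(data.labels.tolist())
        if len(classes) < 2:
            missing = sorted(str(AddictionLevel(c)) for c in
                             {1, 2, 3} - classes)
            raise ValidationError(
                "training data contains a single class; missing levels: "
                + ", ".join(missing))
        if self.kind == "knn" and len(data) < KNN_K:
            raise ValidationError(
                f"KNN with k={KNN_K} needs at least {KNN_K} training examples,"
                f" got {len(data)}")
        est = _build_estimator(self.kind, self.seed)
        est.fit(np.asarray(data.features, dtype=float), data.labels)
        self._estimator = est
        self._n_features = data.features.shape[1]
        return self

    def predict(self, x: np.ndarray) -> np.ndarray | AddictionLevel:
        """Predict the level of one vector (returns AddictionLevel) or a
        batch (returns an int array of level codes)."""
        if not self.fitted:
            raise ValidationError(f"{self.kind} classifier is not fitted")
        single = np.asarray(x).ndim == 1
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[1] != self._n_features:
            raise ValidationError(
                f"feature dimension {X.shape[1]} does not match training "
                f"dimension {self._n_features}")
        pred = np.asarray(self._estimator.predict(X), dtype=int)
        return AddictionLevel(int(pred[0])) if single else pred

    def training_accuracy(self, data: LabeledDataset) -> float:
        pred = self.predict(data.features)
        return float((pred == data.labels).mean())


def make_classifier(kind: str, seed: int = 0) -> BaseClassifier:
    """Factory for one of the four base classifiers."""
    return BaseClassifier(kind=kind, seed=seed)


def fit_members(data: LabeledDataset, seed: int = 0) -> list[BaseClassifier]:
    """Fit all four members in the canonical (svm, bnc, c5, knn) order."""
    return [make_classifier(k, seed).fit(data) for k in CLASSIFIER_KINDS]


def predict_all(members: Sequence[BaseClassifier],
                x: np.ndarray) -> tuple[AddictionLevel, ...]:
    """Member predictions for one vector, tuple order (svm, bnc, c5, knn)."""
    return tuple(m.predict(x) for m in members)
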