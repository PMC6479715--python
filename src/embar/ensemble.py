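"""Accuracy-weighted voting ensemble with a case-based-reasoning fallback.

The ensemble combines the four base classifiers' predictions in two modes:

* ``ensemble_only`` -- weighted voting over all member predictions, with
  weight w_i = accuracy_i / sum_j accuracy_j from each member's training
  accuracy;
* full EMBAR (default) -- a consistency test first: if all members agree
  that level is final; otherwise CBR retrieves, within each *disputed*
  level only, the most similar stored training case (1-nearest-neighbor
  under the simple-matching coefficient on the binary feature vectors)
  and returns the level whose best case is most similar.

Case retention ("retain" in the retrieve/reuse/revise/retain cycle) is
implemented but disabled by default so evaluation runs stay deterministic
and leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from embar.classifiers import BaseClassifier, LabeledDataset, fit_members, predict_all
from embar.errors import ValidationError
from embar.records import AddictionLevel


@dataclass
class EnsembleWeights:
    """Accuracy-proportional member weights: w_i = acc_i / sum acc_j."""

    weights: np.ndarray
    accuracies: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.accuracies = np.asarray(self.accuracies, dtype=float)

    @property
    def k(self) -> int:
        return len(self.weights)


def compute_weights(training_accuracies: Sequence[float]) -> EnsembleWeights:
    """Normalize member training accuracies into voting weights.

    Order-preserving; requires every accuracy in (0, 1].
    """
    acc = np.asarray(list(training_accuracies), dtype=float)
    if acc.size < 1:
        raise ValidationError("need at least one accuracy")
    if (acc <= 0).any() or (acc > 1).any():
        raise ValidationError("accuracies must lie in (0, 1]")
    return EnsembleWeights(weights=acc / acc.sum(), accuracies=acc)


def weighted_vote(predictions: Sequence[AddictionLevel],
                  weights: EnsembleWeights) -> AddictionLevel:
    """Level with the maximal summed weight; ties go to lower severity."""
    if len(predictions) != weights.k:
        raise ValidationError(
            f"{len(predictions)} predictions but {weights.k} weights")
    score: dict[AddictionLevel, float] = {}
    for p, w in zip(predictions, weights.weights):
        p = AddictionLevel(p)
        score[p] = score.get(p, 0.0) + float(w)
    best = max(score.values())
    # iterate levels in ascending severity so ties resolve low
    return next(l for l in AddictionLevel
                if score.get(l, -1.0) >= best - 1e-12)


def consistency_test(predictions: Sequence[AddictionLevel]
                     ) -> tuple[bool, frozenset[AddictionLevel]]:
    """Duplicate/consistency check over member predictions.

    Returns ``(True, {level})`` when all members agree, else ``(False,
    distinct levels)`` -- the candidate set handed to CBR.
    """
    if not predictions:
        raise ValidationError("consistency test needs at least one prediction")
    distinct = frozenset(AddictionLevel(p) for p in predictions)
    return (len(distinct) == 1, distinct)


def similarity(a: np.ndarray, b: np.ndarray, kind: str = "matching") -> float:
    """Similarity of two equal-length binary vectors, in [0, 1].

    ``matching`` (default) is the simple-matching coefficient, the fraction
    of positions where the vectors agree; ``jaccard`` ignores joint
    absences.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValidationError(
            f"vector lengths differ: {a.size} vs {b.size}")
    if kind == "matching":
        return float((a == b).mean())
    if kind == "jaccard":
        union = ((a == 1) | (b == 1)).sum()
        if union == 0:
            return 1.0
        return float(((a == 1) & (b == 1)).sum() / union)
    raise ValidationError(f"unknown similarity kind {kind!r}")


@dataclass
class CaseLibrary:
    """Stored (binary feature vector, level) cases for CBR retrieval."""

    features: np.ndarray  # (n, d)
    levels: np.ndarray  # (n,) codes 1..3
    retain_enabled: bool = False

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features))
        self.levels = np.asarray(
            [int(l) for l in np.asarray(self.levels).ravel()])
        if len(self.features) != len(self.levels):
            raise ValidationError("case features and levels must be aligned")
        if len(self.levels) == 0:
            raise ValidationError("case library must be non-empty")
        if not set(self.levels.tolist()) <= {1, 2, 3}:
            raise ValidationError("case levels must be addiction level codes")

    def __len__(self) -> int:
        return len(self.levels)

    @classmethod
    def from_dataset(cls, data: LabeledDataset,
                     retain_enabled: bool = False) -> "CaseLibrary":
        return cls(np.array(data.features, copy=True),
                   np.array(data.labels, copy=True), retain_enabled)

    def class_cases(self, level: AddictionLevel) -> np.ndarray:
        return self.features[self.levels == int(level)]

    def save_csv(self, path) -> None:
        """Serialize as ``bits,level`` rows (bits as a 0/1 string)."""
        with open(path, "w") as fh:
            fh.write("bits,level\n")
            for vec, lvl in zip(self.features, self.levels):
                fh.write("".join(str(int(b)) for b in vec)
                         + f",{AddictionLevel(int(lvl)).name.lower()}\n")

    @classmethod
    def load_csv(cls, path) -> "CaseLibrary":
        feats, lvls = [], []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                bits, name = line.strip().split(",")
                feats.append([int(c) for c in bits])
                lvls.append(int(AddictionLevel.from_name(name)))
        return cls(np.asarray(feats, dtype=np.uint8), np.asarray(lvls))


def retain_case(library: CaseLibrary, x: np.ndarray,
                level: AddictionLevel) -> CaseLibrary:
    """Append a confirmed case when retention is enabled (no-op otherwise)."""
    if not library.retain_enabled:
        return library
    library.features = np.vstack([library.features,
                                  np.asarray(x).reshape(1, -1)])
    library.levels = np.append(library.levels, int(AddictionLevel(level)))
    return library


def class_similarities(x: np.ndarray, candidates: Sequence[AddictionLevel],
                       library: CaseLibrary, kind: str = "matching",
                       aggregate: str = "max",
                       ) -> dict[AddictionLevel, float]:
    """Per-candidate-class similarity of x to the stored cases.

    ``max`` aggregation is 1-NN retrieval (the most similar case in the
    class); ``mean`` averages over the class's cases.
    """
    sims: dict[AddictionLevel, float] = {}
    for level in sorted(candidates):
        level = AddictionLevel(level)
        cases = library.class_cases(level)
        if len(cases) == 0:
            raise ValidationError(
                f"case library has no cases for level {level}")
        vals = [similarity(x, c, kind) for c in cases]
        sims[level] = max(vals) if aggregate == "max" else float(np.mean(vals))
    return sims


def cbr_resolve(x: np.ndarray, candidates: Sequence[AddictionLevel],
                library: CaseLibrary, kind: str = "matching",
                aggregate: str = "max",
                weights: EnsembleWeights | None = None,
                predictions: Sequence[AddictionLevel] | None = None,
                ) -> tuple[AddictionLevel, dict[AddictionLevel, float]]:
    """Resolve disputed candidate levels by case similarity.

    Returns the level whose class similarity is maximal, plus the
    per-level similarities.  On an exact similarity tie the restricted
    weighted vote over the tied levels decides (when weights and member
    predictions are supplied), then lower severity.
    """
    cset = frozenset(AddictionLevel(c) for c in candidates)
    if not cset:
        raise ValidationError("cbr_resolve needs at least one candidate level")
    sims = class_similarities(x, cset, library, kind, aggregate)
    best = max(sims.values())
    tied = [l for l in sorted(sims) if sims[l] >= best - 1e-12]
    if len(tied) > 1 and weights is not None and predictions is not None:
        kept = [(p, w) for p, w in zip(predictions, weights.weights)
                if AddictionLevel(p) in tied]
        if kept:
            sub = compute_weights([w for _, w in kept])
            return (weighted_vote([p for p, _ in kept], sub), sims)
    return tied[0], sims


@dataclass
class PredictionOutcome:
    """Final prediction plus an audit trail of how it was reached."""

    final_level: AddictionLevel
    mode: str  # "consistent" | "voted" | "cbr_resolved"
    member_predictions: tuple[AddictionLevel, ...]
    class_similarities: dict[AddictionLevel, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "final_level": str(self.final_level),
            "mode": self.mode,
            "member_predictions": {
                kind: str(p) for kind, p in
                zip(("svm", "bnc", "c5", "knn"), self.member_predictions)
            },
            "class_similarities": {
                str(l): s for l, s in self.class_similarities.items()
            },
        }


def predict_embar(x: np.ndarray, members: Sequence[BaseClassifier],
                  weights: EnsembleWeights, library: CaseLibrary | None,
                  ensemble_only: bool = False,
                  similarity_kind: str = "matching",
                  aggregate: str = "max") -> PredictionOutcome:
    """Two-phase prediction for one feature vector.

    Phase one collects the member predictions.  In ``ensemble_only`` mode
    the weighted vote is final.  Otherwise the consistency test either
    accepts the unanimous level or hands the *disputed* levels to CBR.
    """
    preds = predict_all(members, x)
    if ensemble_only:
        return PredictionOutcome(weighted_vote(preds, weights), "voted", preds)
    consistent, levels = consistency_test(preds)
    if consistent:
        return PredictionOutcome(next(iter(levels)), "consistent", preds)
    if library is None:
        raise ValidationError(
            "members disagree but no case library was provided")
    final, sims = cbr_resolve(x, levels, library, similarity_kind, aggregate,
                              weights=weights, predictions=preds)
    return PredictionOutcome(final, "cbr_resolved", preds, sims)


@dataclass
class EnsembleModel:
    """Four fitted members, their voting weights, and the case library."""

    members: list[BaseClassifier]
    weights: EnsembleWeights
    library: CaseLibrary
    ensemble_only: bool = False
    similarity_kind: str = "matching"
    aggregate: str = "max"

    @classmethod
    def fit(cls, data: LabeledDataset, seed: int = 0,
            ensemble_only: bool = False,
            similarity_kind: str = "matching",
            aggregate: str = "max") -> "EnsembleModel":
        members = fit_members(data, seed)
        weights = compute_weights(
            [m.training_accuracy(data) for m in members])
        return cls(members, weights, CaseLibrary.from_dataset(data),
                   ensemble_only, similarity_kind, aggregate)

    def predict_one(self, x: np.ndarray) -> PredictionOutcome:
        return predict_embar(x, self.members, self.weights, self.library,
                             self.ensemble_only, self.similarity_kind,
                             self.aggregate)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Level codes for a batch; member predictions computed batched."""
        X = np.atleast_2d(np.asarray(X))
        member_preds = np.column_stack(
            [m.predict(X) for m in self.members])  # (n, 4)
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(member_preds):
            preds = tuple(AddictionLevel(int(p)) for p in row)
            if self.ensemble_only:
                out[i] = int(weighted_vote(preds, self.weights))
                continue
            consistent, levels = consistency_test(preds)
            if consistent:
                out[i] = int(next(iter(levels)))
            else:
                final, _ = cbr_resolve(X[i], levels, self.library,
                                       self.similarity_kind, self.aggregate,
                                       weights=self.weights, predictions=preds)
                out[i] = int(final)
        return out
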