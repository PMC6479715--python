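"""Repeated stratified-holdout evaluation with per-level one-vs-rest metrics.

The protocol: split users 2/3 train / 1/3 test preserving class
proportions, fit every method on the training fold, score the test fold,
and repeat (ten times by default) with fresh splits, averaging the
results.  Performance is reported per level as one-vs-rest sensitivity
(true-positive rate), specificity (true-negative rate) and accuracy, all
in percent, plus the unweighted mean of the three per-level accuracies
("average accuracy" -- the tables' headline number).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from embar.classifiers import CLASSIFIER_KINDS, LabeledDataset, fit_members
from embar.ensemble import EnsembleModel, CaseLibrary, compute_weights
from embar.errors import ValidationError
from embar.records import AddictionLevel

#: Method names accepted by run_experiment, in report order.
METHODS = ("svm", "bnc", "c5", "knn", "ensemble", "embar", "majority")


@dataclass
class SplitPlan:
    """Repeated stratified 2/3-1/3 holdout plan.

    ``seeds`` fixes one RNG seed per repetition; when omitted they derive
    deterministically from ``base_seed``.
    """

    train_fraction: float = 2 / 3
    repetitions: int = 10
    stratified: bool = True
    base_seed: int = 0
    seeds: list[int] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if self.seeds is None:
            self.seeds = [(self.base_seed + 1000 * i) % (2 ** 31)
                          for i in range(self.repetitions)]
        if len(self.seeds) != self.repetitions:
            raise ValidationError("need one seed per repetition")


def stratified_split(labels: Sequence[int], plan: SplitPlan,
                     repetition: int) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (train, test) for one repetition.

    Per class, the train count is round-half-up(train_fraction * class
    size); the remainder goes to test.  Deterministic per repetition seed.
    """
    y = np.asarray([int(l) for l in labels])
    if not 0 <= repetition < plan.repetitions:
        raise ValidationError(
            f"repetition {repetition} outside 0..{plan.repetitions - 1}")
    rng = np.random.default_rng(plan.seeds[repetition])
    train_idx: list[int] = []
    test_idx: list[int] = []
    classes = np.unique(y) if plan.stratified else np.array([0])
    for cls in classes:
        idx = np.nonzero(y == cls)[0] if plan.stratified else np.arange(len(y))
        if len(idx) < 2:
            raise ValidationError(
                f"class {cls} has {len(idx)} member(s); need at least 2")
        n_train = int(np.floor(plan.train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both folds non-empty
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single positive level."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions: Sequence[int], truths: Sequence[int],
              level: AddictionLevel) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``level`` as positive."""
    pred = np.asarray([int(p) for p in predictions])
    true = np.asarray([int(t) for t in truths])
    if pred.shape != true.shape:
        raise ValidationError("predictions and truths must be aligned")
    for arr, what in ((pred, "prediction"), (true, "truth")):
        bad = set(arr.tolist()) - {1, 2, 3}
        if bad:
            raise ValidationError(f"{what} labels outside level set: {bad}")
    pos = int(AddictionLevel(level))
    p, t = pred == pos, true == pos
    return ConfusionCounts(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                           tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent, full precision.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total.  Both strata must be non-empty.
    """
    if counts.tp + counts.fn == 0:
        raise ValidationError("no positive examples: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValidationError("no negative examples: specificity undefined")
    sens = 100.0 * counts.tp / (counts.tp + counts.fn)
    spec = 100.0 * counts.tn / (counts.tn + counts.fp)
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    return sens, spec, acc


def average_accuracy(per_level_accuracies: Sequence[float],
                     ndigits: int | None = 1) -> float:
    """Unweighted mean of the three per-level accuracies (percent).

    This is the aggregation that reproduces the tables' printed "Average
    Accuracy" rows from their three per-level accuracy cells.
    """
    vals = list(per_level_accuracies)
    if len(vals) != 3:
        raise ValidationError(
            f"expected exactly three per-level accuracies, got {len(vals)}")
    if any(not 0 <= v <= 100 for v in vals):
        raise ValidationError("accuracies must lie in [0, 100]")
    mean = sum(vals) / 3.0
    return round(mean, ndigits) if ndigits is not None else mean


@dataclass
class EvaluationReport:
    """Averaged per-method, per-level metrics over all repetitions.

    ``table[method][level_name][metric]`` holds percentages (full
    precision); ``averages[method]`` is the mean-of-three average
    accuracy; ``raw`` keeps the per-repetition counts for audit.
    """

    table: dict[str, dict[str, dict[str, float]]]
    averages: dict[str, float]
    raw: list[dict] = field(default_factory=list)
    cbr_fraction: float | None = None  # share of test cases resolved by CBR
    seeds: list[int] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"table": self.table, "averages": self.averages,
                       "cbr_fraction": self.cbr_fraction, "seeds": self.seeds,
                       "repetitions": self.raw}, fh, indent=2, default=float)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("method,level,metric,percent\n")
            for method, levels in self.table.items():
                for level, mets in levels.items():
                    for metric, value in mets.items():
                        fh.write(f"{method},{level},{metric},{value:.1f}\n")
                fh.write(f"{method},all,average_accuracy,"
                         f"{self.averages[method]:.1f}\n")


def _method_predictions(method: str, members, weights, library,
                        train_y: np.ndarray, X_test: np.ndarray,
                        ) -> tuple[np.ndarray, int]:
    """Test-fold predictions for one method; returns (codes, n_cbr)."""
    if method in CLASSIFIER_KINDS:
        member = members[CLASSIFIER_KINDS.index(method)]
        return np.asarray(member.predict(X_test)), 0
    if method == "majority":
        counts = np.bincount(train_y, minlength=4)
        return np.full(len(X_test), int(counts[1:].argmax()) + 1), 0
    model = EnsembleModel(members, weights, library,
                          ensemble_only=(method == "ensemble"))
    preds = model.predict(X_test)
    n_cbr = 0
    if method == "embar":
        member_preds = np.column_stack([m.predict(X_test) for m in members])
        n_cbr = int((member_preds != member_preds[:, :1]).any(axis=1).sum())
    return preds, n_cbr


def run_experiment(features: np.ndarray, labels: Sequence[int],
                   plan: SplitPlan,
                   methods: Sequence[str] = ("svm", "bnc", "c5", "knn",
                                             "ensemble", "embar"),
                   seed: int = 0) -> EvaluationReport:
    """Train and evaluate every method over all planned repetitions.

    ``features`` are the users' binarized SOM feature vectors, ``labels``
    their true addiction-level codes.  The four base members are fitted
    once per repetition and shared by the single-classifier, voting and
    EMBAR methods, so all methods see identical splits and identical
    fitted members.
    """
    X = np.atleast_2d(np.asarray(features))
    y = np.asarray([int(l) for l in labels])
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown methods {sorted(unknown)}")
    if not methods:
        raise ValidationError("need at least one method")

    level_names = [str(l) for l in AddictionLevel]
    sums = {m: {ln: {"sensitivity": 0.0, "specificity": 0.0, "accuracy": 0.0}
                for ln in level_names} for m in methods}
    raw: list[dict] = []
    cbr_total, test_total = 0, 0

    for rep in range(plan.repetitions):
        tr_idx, te_idx = stratified_split(y, plan, rep)
        train = LabeledDataset(X[tr_idx], y[tr_idx], "Tr")
        members = fit_members(train, seed=seed)
        weights = compute_weights(
            [m.training_accuracy(train) for m in members])
        library = CaseLibrary.from_dataset(train)
        rep_record: dict = {"repetition": rep, "seed": plan.seeds[rep],
                            "counts": {}}
        for method in methods:
            preds, n_cbr = _method_predictions(
                method, members, weights, library, y[tr_idx], X[te_idx])
            if method == "embar":
                cbr_total += n_cbr
                test_total += len(te_idx)
            rep_record["counts"][method] = {}
            for level in AddictionLevel:
                cc = confusion(preds, y[te_idx], level)
                sens, spec, acc = metrics(cc)
                cell = sums[method][str(level)]
                cell["sensitivity"] += sens
                cell["specificity"] += spec
                cell["accuracy"] += acc
                rep_record["counts"][method][str(level)] = {
                    "tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn}
        raw.append(rep_record)

    table = {m: {ln: {k: v / plan.repetitions for k, v in mets.items()}
                 for ln, mets in levels.items()}
             for m, levels in sums.items()}
    averages = {m: average_accuracy(
        [table[m][ln]["accuracy"] for ln in level_names])
        for m in methods}
    return EvaluationReport(
        table=table, averages=averages, raw=raw,
        cbr_fraction=(cbr_total / test_total if test_total else None),
        seeds=list(plan.seeds))
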