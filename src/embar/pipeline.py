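"""End-to-end glue: profiles -> per-user SOM features -> labeled dataset.

A single global seed fans out into named sub-seeds (cohort, som, split,
classifier) so each stage is independently reproducible.
"""

from __future__ import annotations

import csv
from os import PathLike
from typing import Sequence

import numpy as np

from embar.classifiers import LabeledDataset
from embar.errors import ValidationError
from embar.records import AddictionLevel, UserProfile
from embar.som import (
    DEFAULT_ATTRIBUTES,
    SomTrainingParams,
    binarize,
    extract_feature_matrix,
    record_vectors,
    train_som,
)

#: Stage-name offsets fanned out from the global seed.
_SEED_OFFSETS = {"cohort": 0, "som": 1_000_003, "split": 2_000_003,
                 "classifier": 3_000_017}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    if stage not in _SEED_OFFSETS:
        raise ValidationError(f"unknown stage {stage!r}")
    return (int(global_seed) + _SEED_OFFSETS[stage]) % (2 ** 31)


def featurize_user(profile: UserProfile, params: SomTrainingParams,
                   attributes: Sequence[str] = DEFAULT_ATTRIBUTES) -> np.ndarray:
    """Train this user's SOM and return the binarized feature matrix."""
    if not profile.records:
        raise ValidationError(f"user {profile.user_id} has no records")
    vectors, cats = record_vectors(profile.records, attributes)
    grid = train_som(vectors, params)
    return binarize(extract_feature_matrix(grid, vectors, cats))


def featurize_cohort(profiles: Sequence[UserProfile],
                     params: SomTrainingParams | None = None,
                     attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
                     seed: int = 0,
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-user SOM features for a whole cohort.

    Each user gets an independent map with a seed derived from the stage
    seed and the user's index, so cohorts are reproducible and users are
    decoupled.  Returns (features, level codes, user ids).
    """
    if not profiles:
        raise ValidationError("no profiles to featurize")
    params = params or SomTrainingParams()
    base = stage_seed(seed, "som")
    feats, levels, ids = [], [], []
    for i, p in enumerate(profiles):
        feats.append(featurize_user(
            p, params.with_seed((base + 7919 * i) % (2 ** 31)), attributes))
        levels.append(int(p.level))
        ids.append(p.user_id)
    return np.asarray(feats, dtype=np.uint8), np.asarray(levels), ids


def save_features(path: str | PathLike, features: np.ndarray,
                  levels: np.ndarray, user_ids: Sequence[str],
                  iat_scores: Sequence[int] | None = None) -> None:
    """Write the feature table: user_id, iat_score, level, 0/1 bit string."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["user_id", "iat_score", "level", "bits"])
        for i, uid in enumerate(user_ids):
            score = "" if iat_scores is None else iat_scores[i]
            writer.writerow([
                uid, score, str(AddictionLevel(int(levels[i]))),
                "".join(str(int(b)) for b in features[i])])


def load_features(path: str | PathLike
                  ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a feature table back as (features, level codes, user ids)."""
    feats, levels, ids = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            feats.append([int(c) for c in row["bits"]])
            levels.append(int(AddictionLevel.from_name(row["level"])))
            ids.append(row["user_id"])
    if not feats:
        raise ValidationError(f"no feature rows in {path}")
    return np.asarray(feats, dtype=np.uint8), np.asarray(levels), ids


def dataset_from_features(features: np.ndarray, levels: np.ndarray,
                          tag: str = "Tr") -> LabeledDataset:
    return LabeledDataset(features, levels, tag)
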