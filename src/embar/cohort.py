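"""Synthetic labeled cohorts of browsing-history profiles.

The generator emulates the statistical structure of the study population
this method was designed for: three IAT addiction levels at roughly
114/91/12 proportions among 217 users, level-dependent file-category
mixtures (the discriminative signal), and browsing timestamps concentrated
on weekends and after-work hours *for all levels alike* -- timing is
deliberately non-discriminative, matching the empirical finding that
day-of-week and hour do not separate addiction levels.

The single ``separation`` knob in [0, 1] interpolates every level's
category mixture between a shared base mixture (separation=0: levels are
statistically identical) and level-specific extremes (separation=1:
maximally distinct).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from embar.errors import ValidationError
from embar.records import AddictionLevel, TifRecord, UserProfile

#: IAT score range per level (inclusive), after Young's cut points.
LEVEL_SCORE_RANGES = {
    AddictionLevel.MILD: (20, 50),
    AddictionLevel.MODERATE: (51, 80),
    AddictionLevel.SEVERE: (81, 100),
}

#: Level-specific category-mixture extremes over (document, graphic,
#: archive, multimedia, others).  Mild users skew toward documents
#: (work/study browsing), moderate toward graphics and mixed media,
#: severe toward multimedia (streaming-heavy use).
LEVEL_EXTREMES = {
    AddictionLevel.MILD: np.array([0.55, 0.15, 0.05, 0.10, 0.15]),
    AddictionLevel.MODERATE: np.array([0.15, 0.45, 0.10, 0.20, 0.10]),
    AddictionLevel.SEVERE: np.array([0.05, 0.10, 0.15, 0.60, 0.10]),
}

#: Representative file extension per category used for generated names.
_EXT_BY_CATEGORY = {1: "pdf", 2: "jpg", 3: "zip", 4: "mp4", 5: "dat"}

#: Median generated file size (bytes) per category, log-normal spread.
_SIZE_MEDIAN = {1: 200_000, 2: 80_000, 3: 5_000_000, 4: 20_000_000, 5: 50_000}


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``class_proportions`` orders levels (mild, moderate, severe) and must
    sum to 1; ``category_mixtures`` maps each level to a simplex over the
    five categories; ``timing_profile`` gives the probability that a record
    falls in a leisure slot (weekend, or weekday hours 18-23) versus a
    uniformly random slot.
    """

    n_users: int = 217
    class_proportions: tuple[float, float, float] = (114 / 217, 91 / 217, 12 / 217)
    records_per_user: tuple[int, int] = (150, 250)
    category_mixtures: dict[AddictionLevel, np.ndarray] | None = None
    separation: float = 0.8
    timing_profile: dict[str, float] = field(
        default_factory=lambda: {"leisure_weight": 0.7})
    start_date: str = "2019-01-07"
    n_weeks: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users <= 0:
            raise ValidationError("n_users must be positive")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValidationError(
                "class_proportions must be a 3-simplex summing to 1")
        lo, hi = self.records_per_user
        if not (0 < lo <= hi):
            raise ValidationError("records_per_user range must satisfy 0 < lo <= hi")
        if not 0.0 <= self.separation <= 1.0:
            raise ValidationError("separation must lie in [0, 1]")
        if self.category_mixtures is not None:
            for lvl, mix in self.category_mixtures.items():
                mix = np.asarray(mix, dtype=float)
                if mix.shape != (5,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
                    raise ValidationError(
                        f"category mixture for {lvl} must be a 5-simplex")

    def level_mixture(self, level: AddictionLevel) -> np.ndarray:
        """Effective category mixture for a level at this separation.

        ``(1 - separation) * base + separation * extreme`` where the base is
        the proportion-weighted population mixture of the extremes, so at
        separation=0 all three levels share one mixture by construction.
        """
        if self.category_mixtures is not None:
            extremes = {l: np.asarray(m, float)
                        for l, m in self.category_mixtures.items()}
        else:
            extremes = LEVEL_EXTREMES
        props = np.asarray(self.class_proportions, float)
        base = sum(p * extremes[l]
                   for p, l in zip(props, AddictionLevel))
        return (1.0 - self.separation) * base + self.separation * extremes[level]


def default_study_config(seed: int = 0) -> CohortConfig:
    """The documented study-scale defaults: 217 users at 114/91/12
    proportions, separation 0.8, evening/weekend-heavy timing."""
    return CohortConfig(seed=seed)


def _level_counts(config: CohortConfig) -> dict[AddictionLevel, int]:
    """Largest-remainder allocation of users to levels (deterministic)."""
    props = np.asarray(config.class_proportions, float)
    raw = props * config.n_users
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: config.n_users - counts.sum()]:
        counts[i] += 1
    return dict(zip(AddictionLevel, counts.tolist()))


def _sample_timestamp(rng: np.random.Generator, config: CohortConfig,
                      start: datetime) -> datetime:
    """One timestamp; leisure-slot concentrated, identical for all levels."""
    leisure = rng.random() < config.timing_profile.get("leisure_weight", 0.7)
    week = int(rng.integers(0, config.n_weeks))
    if leisure:
        if rng.random() < 0.5:  # weekend, any hour
            dow = int(rng.integers(5, 7))
            hour = int(rng.integers(0, 24))
        else:  # weekday evening
            dow = int(rng.integers(0, 5))
            hour = int(rng.integers(18, 24))
    else:
        dow = int(rng.integers(0, 7))
        hour = int(rng.integers(0, 24))
    minute, second = int(rng.integers(0, 60)), int(rng.integers(0, 60))
    return start + timedelta(weeks=week, days=dow, hours=hour,
                             minutes=minute, seconds=second)


def generate_cohort(config: CohortConfig) -> list[UserProfile]:
    """Generate ``config.n_users`` labeled profiles, reproducible from seed.

    Level counts follow largest-remainder allocation of the class
    proportions; each user's records draw categories from the user's level
    mixture, IAT scores uniformly inside the level's range, and timestamps
    from the shared leisure-heavy timing profile.
    """
    rng = np.random.default_rng(config.seed)
    start = datetime.fromisoformat(config.start_date)
    # start date anchored to a Monday so day-of-week arithmetic is exact
    start -= timedelta(days=start.weekday())

    levels: list[AddictionLevel] = []
    for level, count in _level_counts(config).items():
        levels.extend([level] * count)
    rng.shuffle(levels)  # type: ignore[arg-type]

    lo, hi = config.records_per_user
    width = len(str(config.n_users))
    profiles: list[UserProfile] = []
    for idx, level in enumerate(levels, start=1):
        uid = f"u{idx:0{width}d}"
        score_lo, score_hi = LEVEL_SCORE_RANGES[level]
        score = int(rng.integers(score_lo, score_hi + 1))
        n_rec = int(rng.integers(lo, hi + 1))
        mixture = config.level_mixture(level)
        cats = rng.choice(5, size=n_rec, p=mixture) + 1
        records = []
        for j, cat in enumerate(cats, start=1):
            cat = int(cat)
            ts = _sample_timestamp(rng, config, start)
            size = int(rng.lognormal(np.log(_SIZE_MEDIAN[cat]), 1.0))
            records.append(TifRecord(
                user_id=uid,
                file_name=f"file_{idx}_{j}.{_EXT_BY_CATEGORY[cat]}",
                category=cat,
                size_bytes=size,
                created_at=ts,
            ))
        records.sort(key=lambda r: r.created_at)
        profiles.append(UserProfile.from_score(uid, records, score))
    return profiles
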