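"""Browsing-history records, IAT addiction levels, and log I/O.

A record models one entry of a Temporary-Internet-Files-style browser
cache: who downloaded which file, of which category, how big, and when.
The five file categories follow the conventional coding
document=1, graphic=2, archive=3, multimedia=4, others=5.

Addiction levels come from Young's Internet Addiction Test (IAT): total
score 20-100, partitioned into mild (20-50), moderate (51-80) and severe
(81-100).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from enum import IntEnum
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from embar.errors import LogFormatError, ValidationError

CATEGORY_NAMES: Mapping[int, str] = {
    1: "document",
    2: "graphic",
    3: "archive",
    4: "multimedia",
    5: "others",
}

#: Shipped default extension table.  Editable: pass your own mapping to
#: :func:`categorize_extension` or load one with :func:`load_extension_table`.
DEFAULT_EXTENSION_TABLE: dict[str, int] = {
    # documents
    **{e: 1 for e in ("doc", "docx", "pdf", "txt", "rtf", "odt", "xls", "xlsx",
                      "ppt", "pptx", "htm", "html", "xml", "csv", "md")},
    # graphics
    **{e: 2 for e in ("jpg", "jpeg", "png", "gif", "bmp", "tif", "tiff", "svg",
                      "webp", "ico")},
    # archives
    **{e: 3 for e in ("zip", "rar", "7z", "tar", "gz", "bz2", "xz", "iso",
                      "cab")},
    # multimedia
    **{e: 4 for e in ("mp3", "mp4", "avi", "flv", "mkv", "mov", "wmv", "wav",
                      "ogg", "webm", "m4a", "mpg", "mpeg", "swf")},
}

LOG_HEADER = ["user_id", "file_name", "category", "size_bytes", "created_at"]


class AddictionLevel(IntEnum):
    """IAT addiction level, totally ordered mild < moderate < severe."""

    MILD = 1
    MODERATE = 2
    SEVERE = 3

    def __str__(self) -> str:  # serialized as lowercase names
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "AddictionLevel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown addiction level {name!r}") from None


@dataclass(frozen=True)
class TifRecord:
    """One browsing-history event (a cached/downloaded file)."""

    user_id: str
    file_name: str
    category: int
    size_bytes: int
    created_at: datetime

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_NAMES:
            raise ValidationError(
                f"category must be in 1..5, got {self.category!r}")
        if self.size_bytes < 0:
            raise ValidationError(
                f"size_bytes must be non-negative, got {self.size_bytes!r}")


@dataclass(frozen=True)
class DerivedAttributes:
    """Calendar attributes of a record: Monday=1..Sunday=7, clock hour 0-23."""

    day_of_week: int
    hour: int


@dataclass
class UserProfile:
    """A user's browsing records plus IAT score and derived level."""

    user_id: str
    records: list[TifRecord] = field(default_factory=list)
    iat_score: int = 20
    level: AddictionLevel = AddictionLevel.MILD

    def __post_init__(self) -> None:
        if not 20 <= self.iat_score <= 100:
            raise ValidationError(
                f"IAT score must be in [20, 100], got {self.iat_score}")
        expected = score_to_level(self.iat_score)
        if self.level != expected:
            raise ValidationError(
                f"level {self.level} inconsistent with IAT score "
                f"{self.iat_score} (expected {expected})")

    @classmethod
    def from_score(cls, user_id: str, records: list[TifRecord],
                   iat_score: int) -> "UserProfile":
        return cls(user_id, records, iat_score, score_to_level(iat_score))


def score_to_level(iat_score: int) -> AddictionLevel:
    """Map an IAT total score to Young's addiction level.

    20-50 -> mild, 51-80 -> moderate, 81-100 -> severe.
    """
    if not 20 <= iat_score <= 100:
        raise ValidationError(
            f"IAT score must be in [20, 100], got {iat_score}")
    if iat_score <= 50:
        return AddictionLevel.MILD
    if iat_score <= 80:
        return AddictionLevel.MODERATE
    return AddictionLevel.SEVERE


def categorize_extension(file_name: str,
                         table: Mapping[str, int] | None = None) -> int:
    """Category code 1-5 for a file name, from its (case-insensitive) extension.

    Unknown or absent extensions fall back to 5 (others).  Total function:
    never raises for a non-empty name.
    """
    if not file_name:
        raise ValidationError("file_name must be non-empty")
    table = DEFAULT_EXTENSION_TABLE if table is None else table
    suffix = Path(file_name).suffix.lstrip(".").lower()
    return table.get(suffix, 5)


def load_extension_table(path: str | PathLike) -> dict[str, int]:
    """Load an extension->category table from a YAML/JSON config file.

    Accepts either a flat ``{ext: code}`` mapping or a grouped
    ``{category_name: [ext, ...]}`` mapping using the five standard names.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"extension table in {path} is not a mapping")
    name_to_code = {v: k for k, v in CATEGORY_NAMES.items()}
    table: dict[str, int] = {}
    for key, value in data.items():
        if isinstance(value, list):  # grouped form
            code = name_to_code.get(str(key).lower())
            if code is None:
                raise ValidationError(f"unknown category name {key!r}")
            for ext in value:
                table[str(ext).lstrip(".").lower()] = code
        else:
            code = int(value)
            if code not in CATEGORY_NAMES:
                raise ValidationError(
                    f"category code for {key!r} must be 1..5, got {code}")
            table[str(key).lstrip(".").lower()] = code
    return table


def derive_attributes(record: TifRecord) -> DerivedAttributes:
    """Day-of-week (Monday=1 .. Sunday=7) and clock hour (0-23)."""
    ts = record.created_at
    return DerivedAttributes(day_of_week=ts.isoweekday(), hour=ts.hour)


def read_log(path: str | PathLike, *,
             extension_table: Mapping[str, int] | None = None,
             delimiter: str = ",") -> list[TifRecord]:
    """Read a browsing-history log CSV into records, in file order.

    The header must name ``user_id,file_name,category,size_bytes,created_at``
    (the ``category`` column may be omitted, in which case the category is
    derived from ``file_name`` via the extension table).  Malformed rows are
    collected and reported together with their 1-based line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"log file not found: {path}")
    records: list[TifRecord] = []
    problems: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in LOG_HEADER if c != "category" and c not in header]
        if missing:
            raise LogFormatError(
                f"log header missing columns {missing} in {path}", lines=[1])
        has_category = "category" in header
        for lineno, row in enumerate(reader, start=2):
            try:
                name = (row["file_name"] or "").strip()
                if has_category and (row.get("category") or "").strip():
                    category = int(row["category"])
                else:
                    category = categorize_extension(name, extension_table)
                records.append(TifRecord(
                    user_id=(row["user_id"] or "").strip(),
                    file_name=name,
                    category=category,
                    size_bytes=int(row["size_bytes"]),
                    created_at=datetime.fromisoformat(
                        (row["created_at"] or "").strip()),
                ))
            except (ValueError, TypeError, KeyError) as exc:
                problems.append((lineno, str(exc)))
    if problems:
        detail = "; ".join(f"line {n}: {m}" for n, m in problems[:10])
        raise LogFormatError(
            f"{len(problems)} malformed row(s) in {path}: {detail}",
            lines=[n for n, _ in problems])
    return records


def write_log(path: str | PathLike, records: Iterable[TifRecord]) -> None:
    """Write records to the log CSV format read by :func:`read_log`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_HEADER)
        for r in records:
            writer.writerow([r.user_id, r.file_name, r.category, r.size_bytes,
                             r.created_at.isoformat()])


def write_labels(path: str | PathLike, profiles: Iterable[UserProfile]) -> None:
    """Write the per-user labels CSV ``user_id,iat_score,level``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["user_id", "iat_score", "level"])
        for p in profiles:
            writer.writerow([p.user_id, p.iat_score, str(p.level)])


def read_labels(path: str | PathLike) -> dict[str, tuple[int, AddictionLevel]]:
    """Read the labels CSV back as ``{user_id: (iat_score, level)}``."""
    out: dict[str, tuple[int, AddictionLevel]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["user_id"]] = (int(row["iat_score"]),
                                   AddictionLevel.from_name(row["level"]))
    return out


def assemble_profiles(records: Iterable[TifRecord],
                      labels: Mapping[str, tuple[int, AddictionLevel]],
                      ) -> tuple[list[UserProfile], list[str]]:
    """Group records by user and attach IAT labels.

    Returns the profiles (in first-appearance order of labeled users) and
    the list of user ids present in the log but absent from the labels.
    """
    by_user: dict[str, list[TifRecord]] = {}
    for r in records:
        by_user.setdefault(r.user_id, []).append(r)
    profiles, unknown = [], []
    for uid, recs in by_user.items():
        if uid in labels:
            score, _level = labels[uid]
            profiles.append(UserProfile.from_score(uid, recs, score))
        else:
            unknown.append(uid)
    return profiles, unknown


def profiles_to_json(path: str | PathLike,
                     profiles: Iterable[UserProfile]) -> None:
    """Export profiles (records inline) as JSON."""
    payload = [
        {
            "user_id": p.user_id,
            "iat_score": p.iat_score,
            "level": str(p.level),
            "records": [
                {
                    "file_name": r.file_name,
                    "category": r.category,
                    "size_bytes": r.size_bytes,
                    "created_at": r.created_at.isoformat(),
                }
                for r in p.records
            ],
        }
        for p in profiles
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
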