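"""Semiquantitative 10-second interval coding of substance content in videos.

Each video is divided into successive 10 s windows; within every window a
coder records presence/absence of each (substance, category, channel)
combination — e.g. alcohol / brand / visual.  The coding unit is the
interval: any appearance within the window, however brief, counts once.
A *content class* is a set of substances whose flags are unioned into a
single per-interval presence measure, so an interval showing both an
alcohol brand and alcohol use contributes one content interval, not two.

Interval indices are 0-based half-open time windows [10k, 10(k+1)) s.
A video whose duration is not a multiple of 10 has ceil(duration/10)
intervals; the trailing short interval is a full coding unit.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSTANCES: tuple[str, ...] = ("tobacco", "alcohol", "electronic_cigarette")
CATEGORIES: tuple[str, ...] = ("actual_use", "implied_use", "paraphernalia", "brand")
CHANNELS: tuple[str, ...] = ("visual", "lyric")

#: Column names of the long-format coding sheet, "substance.category.channel".
FLAG_COLUMNS: tuple[str, ...] = tuple(
    f"{s}.{c}.{ch}" for s in SUBSTANCES for c in CATEGORIES for ch in CHANNELS
)

_META_COLUMNS = ("video_id", "interval_index")


class CodingSheetError(ValueError):
    """Raised when a coding sheet fails validation."""


@dataclass(frozen=True)
class ContentClass:
    """A set of substances treated as one exposure class.

    The canonical classes are ``ContentClass.alcohol()``,
    ``ContentClass.tobacco()`` and ``ContentClass.electronic_cigarette()``;
    combined classes (e.g. tobacco + e-cigarette) are user-configured.
    """

    substances: frozenset[str]

    def __post_init__(self) -> None:
        if not self.substances:
            raise ValueError("content class must contain at least one substance")
        unknown = set(self.substances) - set(SUBSTANCES)
        if unknown:
            raise ValueError(
                f"unknown substance name(s) {sorted(unknown)}; "
                f"known substances are {list(SUBSTANCES)}"
            )

    @classmethod
    def of(cls, *substances: str) -> "ContentClass":
        return cls(frozenset(substances))

    @classmethod
    def parse(cls, text: str) -> "ContentClass":
        """Parse e.g. ``"alcohol"`` or ``"tobacco+electronic_cigarette"``."""
        return cls(frozenset(p.strip() for p in text.split("+") if p.strip()))

    @classmethod
    def alcohol(cls) -> "ContentClass":
        return cls.of("alcohol")

    @classmethod
    def tobacco(cls) -> "ContentClass":
        return cls.of("tobacco")

    @classmethod
    def electronic_cigarette(cls) -> "ContentClass":
        return cls.of("electronic_cigarette")

    @property
    def label(self) -> str:
        return "+".join(sorted(self.substances))

    @property
    def flag_columns(self) -> tuple[str, ...]:
        return tuple(c for c in FLAG_COLUMNS if c.split(".", 1)[0] in self.substances)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class CodedVideo:
    """A video's metadata plus its ordered 10 s interval flag records.

    ``flags`` is a boolean DataFrame with one row per interval (index =
    interval_index, 0-based consecutive) and one column per
    (substance, category, channel) flag, named as in :data:`FLAG_COLUMNS`.
    """

    video_id: str
    duration_s: float
    flags: pd.DataFrame
    title: str = ""
    artist: str = ""
    artist_nationality: str | None = None
    genre: str | None = None
    release_date: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_intervals(self) -> int:
        return len(self.flags)

    def validate(self) -> None:
        expected = math.ceil(self.duration_s / 10)
        df = self.flags
        missing = set(FLAG_COLUMNS) - set(df.columns)
        if missing:
            raise CodingSheetError(
                f"video {self.video_id!r}: missing flag column(s) {sorted(missing)}"
            )
        if list(df.index) != list(range(len(df))):
            raise CodingSheetError(
                f"video {self.video_id!r}: interval_index values must be "
                "0-based, consecutive and unique"
            )
        if len(df) != expected:
            raise CodingSheetError(
                f"video {self.video_id!r}: {len(df)} interval records but "
                f"duration {self.duration_s}s implies ceil(duration/10)={expected}"
            )
        for col in FLAG_COLUMNS:
            if df[col].dtype != bool:
                bad = df[col][~df[col].isin([0, 1, True, False])]
                if len(bad):
                    raise CodingSheetError(
                        f"video {self.video_id!r}: non-boolean flag value "
                        f"{bad.iloc[0]!r} in column {col!r} at interval "
                        f"{bad.index[0]}"
                    )
                df[col] = df[col].astype(bool)

    @classmethod
    def from_flag_matrix(
        cls, video_id: str, matrix: np.ndarray, duration_s: float | None = None, **meta
    ) -> "CodedVideo":
        """Build from a (n_intervals, 24) boolean array in FLAG_COLUMNS order."""
        matrix = np.asarray(matrix, dtype=bool)
        if matrix.ndim != 2 or matrix.shape[1] != len(FLAG_COLUMNS):
            raise ValueError(f"flag matrix must have {len(FLAG_COLUMNS)} columns")
        if duration_s is None:
            duration_s = 10.0 * matrix.shape[0]
        flags = pd.DataFrame(matrix, columns=list(FLAG_COLUMNS))
        return cls(video_id=video_id, duration_s=duration_s, flags=flags, **meta)


def count_content_intervals(video: CodedVideo, content_class: ContentClass) -> int:
    """Number of intervals in which ANY flag of ANY substance in the class is set.

    Union semantics: several flags in the same interval count once.
    """
    cols = list(content_class.flag_columns)
    return int(video.flags[cols].any(axis=1).sum())


def total_content_intervals(
    videos: Iterable[CodedVideo], content_class: ContentClass
) -> int:
    """Sum of :func:`count_content_intervals` over a video collection."""
    videos = list(videos)
    if not videos:
        logger.warning("total_content_intervals called with an empty video collection")
        return 0
    return sum(count_content_intervals(v, content_class) for v in videos)


def total_intervals(videos: Iterable[CodedVideo]) -> int:
    """Total number of coded 10 s intervals across videos."""
    return sum(v.n_intervals for v in videos)


# ---------------------------------------------------------------------------
# I/O: long-format CSV (one row per video-interval) and nested JSON
# ---------------------------------------------------------------------------

def read_coding_sheet(
    path,
    metadata_path=None,
    schema_config: Mapping[str, str] | None = None,
) -> list[CodedVideo]:
    """Read a long-format coding sheet CSV into validated :class:`CodedVideo`\\ s.

    The sheet has one row per (video_id, interval_index) and one 0/1 column
    per flag.  ``metadata_path`` optionally points at a video metadata CSV
    (video_id, title, artist, release_date, duration_s, genre); without it
    each video's duration is taken as 10 s x its interval count.
    ``schema_config`` may rename the two key columns, e.g.
    ``{"video_id": "vid", "interval_index": "t"}``.
    """
    rename = {v: k for k, v in (schema_config or {}).items()}
    df = pd.read_csv(path).rename(columns=rename)
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise CodingSheetError(f"coding sheet is missing column {col!r}")
    missing = set(FLAG_COLUMNS) - set(df.columns)
    if missing:
        raise CodingSheetError(f"coding sheet is missing flag column(s) {sorted(missing)}")

    dup = df.duplicated(subset=["video_id", "interval_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise CodingSheetError(
            f"duplicate (video_id, interval_index) = "
            f"({row['video_id']!r}, {row['interval_index']})"
        )
    for col in FLAG_COLUMNS:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CodingSheetError(
                f"non-boolean flag value {df[col].iloc[i]!r} in column {col!r}, "
                f"row for video {df['video_id'].iloc[i]!r} interval "
                f"{df['interval_index'].iloc[i]}"
            )

    meta: dict[str, dict] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path)
        meta = {str(r["video_id"]): r.to_dict() for _, r in mdf.iterrows()}

    videos: list[CodedVideo] = []
    for vid, grp in df.groupby("video_id", sort=True):
        grp = grp.sort_values("interval_index")
        n = len(grp)
        if list(grp["interval_index"]) != list(range(n)):
            raise CodingSheetError(
                f"video {vid!r}: interval_index values are not consecutive from 0"
            )
        m = meta.get(str(vid), {})
        duration = float(m.get("duration_s", 10.0 * n))
        if math.ceil(duration / 10) != n:
            raise CodingSheetError(
                f"video {vid!r}: metadata duration {duration}s inconsistent with "
                f"{n} interval rows"
            )
        flags = grp[list(FLAG_COLUMNS)].astype(bool).reset_index(drop=True)
        videos.append(
            CodedVideo(
                video_id=str(vid),
                duration_s=duration,
                flags=flags,
                title=str(m.get("title", "") or ""),
                artist=str(m.get("artist", "") or ""),
                genre=m.get("genre") if pd.notna(m.get("genre", None)) else None,
                release_date=str(m["release_date"]) if m.get("release_date") else None,
            )
        )
    return videos


def write_coding_sheet(videos: Sequence[CodedVideo], path, metadata_path=None) -> None:
    """Write videos as a long-format coding sheet (and optional metadata CSV)."""
    frames = []
    for v in videos:
        f = v.flags.astype(int).copy()
        f.insert(0, "interval_index", range(v.n_intervals))
        f.insert(0, "video_id", v.video_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if metadata_path is not None:
        pd.DataFrame(
            [
                {
                    "video_id": v.video_id,
                    "title": v.title,
                    "artist": v.artist,
                    "release_date": v.release_date,
                    "duration_s": v.duration_s,
                    "genre": v.genre,
                }
                for v in videos
            ]
        ).to_csv(metadata_path, index=False)


def videos_to_json(videos: Sequence[CodedVideo]) -> str:
    """Serialise videos to an equivalent nested JSON document."""
    payload = [
        {
            "video_id": v.video_id,
            "title": v.title,
            "artist": v.artist,
            "duration_s": v.duration_s,
            "genre": v.genre,
            "release_date": v.release_date,
            "intervals": [
                {
                    "interval_index": i,
                    "flags": [c for c in FLAG_COLUMNS if bool(row[c])],
                }
                for i, row in v.flags.iterrows()
            ],
        }
        for v in videos
    ]
    return json.dumps(payload, indent=1)


def videos_from_json(text: str) -> list[CodedVideo]:
    out = []
    for d in json.loads(text):
        n = len(d["intervals"])
        mat = np.zeros((n, len(FLAG_COLUMNS)), dtype=bool)
        colix = {c: j for j, c in enumerate(FLAG_COLUMNS)}
        for rec in d["intervals"]:
            for c in rec["flags"]:
                mat[rec["interval_index"], colix[c]] = True
        out.append(
            CodedVideo.from_flag_matrix(
                d["video_id"],
                mat,
                duration_s=d.get("duration_s"),
                title=d.get("title", ""),
                artist=d.get("artist", ""),
                genre=d.get("genre"),
                release_date=d.get("release_date"),
            )
        )
    return out
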