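"""Survey-weighted ever-seen reach estimation by demographic stratum.

Respondents report, for each surveyed video, whether they have ever watched
it.  The stratum-level estimand is the weighted mean, over respondents, of
the per-respondent fraction of videos seen:

    p_bar = sum_r w_r f_r / sum_r w_r,   f_r = (# videos seen) / (# videos)

Standard errors use the weighted variance of f_r with the Kish effective
sample size n_eff = (sum w)^2 / sum w^2; with equal weights this reduces
exactly to the usual ddof=1 standard error of the mean.  95% intervals are
the normal approximation p_bar +/- z * se, clipped to [0, 1].  Weights are
taken as supplied (already calibrated to population margins); the package
does not re-rake them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Stratum",
    "Respondent",
    "ReachEstimate",
    "SurveyDataError",
    "ADOLESCENTS",
    "ADULTS",
    "EVERYONE",
    "DEFAULT_AGE_BANDS",
    "respondent_fraction_seen",
    "mean_proportion_viewed",
    "per_video_proportion",
    "read_survey",
    "write_survey",
]

GENDERS = ("female", "male")


class SurveyDataError(ValueError):
    """Raised when survey microdata fail validation."""


@dataclass(frozen=True)
class Stratum:
    """An age band x gender cell: ages in the half-open interval
    [age_min, age_max), gender one of 'female', 'male' or 'all'.
    ``age_max=None`` means no upper limit (e.g. 55+)."""

    age_min: int
    age_max: int | None
    gender: str = "all"

    def __post_init__(self) -> None:
        if self.gender not in (*GENDERS, "all"):
            raise ValueError(f"gender must be one of female/male/all, got {self.gender!r}")
        if self.age_max is not None and self.age_max <= self.age_min:
            raise ValueError("age_max must exceed age_min")

    def contains(self, age: int, gender: str) -> bool:
        if self.gender != "all" and gender != self.gender:
            return False
        if age < self.age_min:
            return False
        return self.age_max is None or age < self.age_max

    def age_overlaps(self, other: "Stratum") -> bool:
        lo = max(self.age_min, other.age_min)
        hi = min(
            math.inf if self.age_max is None else self.age_max,
            math.inf if other.age_max is None else other.age_max,
        )
        return lo < hi

    def overlaps(self, other: "Stratum") -> bool:
        genders_meet = (
            self.gender == other.gender or "all" in (self.gender, other.gender)
        )
        return genders_meet and self.age_overlaps(other)

    @property
    def age_label(self) -> str:
        if self.age_max is None:
            return f"{self.age_min}+"
        return f"{self.age_min}-{self.age_max - 1}"

    @property
    def label(self) -> str:
        return self.age_label if self.gender == "all" else f"{self.age_label} {self.gender}"

    @classmethod
    def parse(cls, text: str) -> "Stratum":
        """Parse labels like '13-15', '55+', '19-24 female'."""
        parts = text.split()
        gender = parts[1] if len(parts) > 1 else "all"
        ages = parts[0]
        if ages.endswith("+"):
            return cls(int(ages[:-1]), None, gender)
        lo, hi = ages.split("-")
        return cls(int(lo), int(hi) + 1, gender)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: Published stratification: age bands partitioning ages 11+.
DEFAULT_AGE_BANDS: tuple[Stratum, ...] = (
    Stratum(11, 13),
    Stratum(13, 16),
    Stratum(16, 19),
    Stratum(19, 25),
    Stratum(25, 35),
    Stratum(35, 45),
    Stratum(45, 55),
    Stratum(55, None),
)
ADOLESCENTS = Stratum(11, 19)
ADULTS = Stratum(19, None)
EVERYONE = Stratum(11, None)


@dataclass
class Respondent:
    """One survey participant: demographics, calibration weight, and the
    per-video ever-seen indicators keyed by video_id."""

    respondent_id: str
    age: int
    gender: str
    weight: float
    seen: Mapping[str, bool]
    region: str | None = None
    survey_date: str | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise SurveyDataError(
                f"respondent {self.respondent_id!r}: weight must be positive, "
                f"got {self.weight}"
            )
        if self.age < 11:
            raise SurveyDataError(
                f"respondent {self.respondent_id!r}: age must be >= 11, got {self.age}"
            )
        if self.gender not in GENDERS:
            raise SurveyDataError(
                f"respondent {self.respondent_id!r}: gender must be female or male, "
                f"got {self.gender!r}"
            )


@dataclass(frozen=True)
class ReachEstimate:
    """A stratum's weighted mean proportion of videos ever seen, with its
    normal-approximation 95% CI and the Kish effective sample size."""

    stratum: Stratum
    p_bar: float
    se: float
    ci_low: float
    ci_high: float
    n_respondents: int
    n_effective: float


def respondent_fraction_seen(r: Respondent, video_ids: Sequence[str]) -> float:
    """Fraction of the listed videos this respondent has ever seen."""
    if not video_ids:
        raise ValueError("video_ids must be non-empty")
    total = 0
    for vid in video_ids:
        if vid not in r.seen:
            raise SurveyDataError(
                f"respondent {r.respondent_id!r} has no ever-seen answer for "
                f"video {vid!r}"
            )
        total += bool(r.seen[vid])
    return total / len(video_ids)


def _weighted_reach(
    fractions: np.ndarray, weights: np.ndarray, stratum: Stratum, level: float
) -> ReachEstimate:
    w = weights
    sw = w.sum()
    p_bar = float((w * fractions).sum() / sw)
    n_eff = float(sw**2 / (w**2).sum())
    var_w = float((w * (fractions - p_bar) ** 2).sum() / sw)
    if var_w <= 0 or n_eff <= 1:
        se = 0.0
    else:
        se = math.sqrt(var_w / (n_eff - 1.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return ReachEstimate(
        stratum=stratum,
        p_bar=p_bar,
        se=se,
        ci_low=max(0.0, p_bar - z * se),
        ci_high=min(1.0, p_bar + z * se),
        n_respondents=len(fractions),
        n_effective=n_eff,
    )


def _in_stratum(respondents: Iterable[Respondent], stratum: Stratum) -> list[Respondent]:
    sub = [r for r in respondents if stratum.contains(r.age, r.gender)]
    if not sub:
        raise SurveyDataError(f"no respondents in stratum {stratum.label!r}")
    if len(sub) == 1:
        raise SurveyDataError(
            f"stratum {stratum.label!r} has a single respondent; "
            "variance is undefined"
        )
    return sub


def mean_proportion_viewed(
    respondents: Iterable[Respondent],
    video_ids: Sequence[str],
    stratum: Stratum,
    level: float = 0.95,
) -> ReachEstimate:
    """Weighted mean proportion of the listed videos viewed in a stratum."""
    sub = _in_stratum(respondents, stratum)
    f = np.array([respondent_fraction_seen(r, video_ids) for r in sub])
    w = np.array([r.weight for r in sub], dtype=float)
    return _weighted_reach(f, w, stratum, level)


def per_video_proportion(
    respondents: Iterable[Respondent],
    video_id: str,
    stratum: Stratum,
    level: float = 0.95,
) -> ReachEstimate:
    """Weighted proportion of a stratum that has ever seen one video."""
    sub = _in_stratum(respondents, stratum)
    f = np.array([respondent_fraction_seen(r, [video_id]) for r in sub])
    w = np.array([r.weight for r in sub], dtype=float)
    return _weighted_reach(f, w, stratum, level)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SURVEY_META = ("respondent_id", "age", "gender", "region", "weight", "survey_date")


def read_survey(
    path,
    video_ids: Sequence[str] | None = None,
    schema_config: Mapping[str, str] | None = None,
    missing: str = "not_seen",
) -> list[Respondent]:
    """Read survey microdata CSV into validated :class:`Respondent` records.

    The CSV carries respondent_id, age, gender, region, weight, then one
    0/1 ever-seen column per video_id.  ``video_ids`` restricts/orders the
    indicator columns (default: every non-metadata column).  Blank ever-seen
    cells ("don't know") are treated as not-seen when ``missing='not_seen'``
    (the conservative default for exposure) or the whole respondent is
    dropped when ``missing='drop'``.
    """
    if missing not in ("not_seen", "drop"):
        raise ValueError("missing must be 'not_seen' or 'drop'")
    rename = {v: k for k, v in (schema_config or {}).items()}
    df = pd.read_csv(path).rename(columns=rename)
    for col in ("respondent_id", "age", "gender", "weight"):
        if col not in df.columns:
            raise SurveyDataError(f"survey file is missing column {col!r}")
    if df["respondent_id"].duplicated().any():
        dup = df.loc[df["respondent_id"].duplicated(), "respondent_id"].iloc[0]
        raise SurveyDataError(f"duplicate respondent_id {dup!r}")
    if video_ids is None:
        video_ids = [c for c in df.columns if c not in _SURVEY_META]

    out: list[Respondent] = []
    for i, row in df.iterrows():
        rid = str(row["respondent_id"])
        try:
            age = int(row["age"])
        except (TypeError, ValueError):
            raise SurveyDataError(
                f"row {i} (respondent {rid!r}): unparseable age {row['age']!r}"
            ) from None
        weight = float(row["weight"])
        if weight <= 0:
            raise SurveyDataError(
                f"row {i} (respondent {rid!r}): nonpositive weight {weight}"
            )
        seen: dict[str, bool] = {}
        drop = False
        for vid in video_ids:
            val = row.get(vid, np.nan)
            if pd.isna(val):
                if missing == "drop":
                    drop = True
                    break
                seen[vid] = False
            elif val in (0, 1, "0", "1", True, False):
                seen[vid] = bool(int(val))
            else:
                raise SurveyDataError(
                    f"row {i} (respondent {rid!r}): non-boolean ever-seen value "
                    f"{val!r} for video {vid!r}"
                )
        if drop:
            continue
        out.append(
            Respondent(
                respondent_id=rid,
                age=age,
                gender=str(row["gender"]),
                weight=weight,
                seen=seen,
                region=str(row["region"]) if "region" in df.columns and pd.notna(row.get("region")) else None,
                survey_date=str(row["survey_date"]) if "survey_date" in df.columns and pd.notna(row.get("survey_date")) else None,
            )
        )
    return out


def write_survey(respondents: Sequence[Respondent], path) -> None:
    if not respondents:
        raise ValueError("cannot write an empty respondent collection")
    video_ids = list(respondents[0].seen)
    rows = []
    for r in respondents:
        rec: dict = {
            "respondent_id": r.respondent_id,
            "age": r.age,
            "gender": r.gender,
            "region": r.region,
            "weight": r.weight,
            "survey_date": r.survey_date,
        }
        rec.update({vid: int(bool(r.seen[vid])) for vid in video_ids})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)
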