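"""Seeded generator of coded videos, survey respondents and population
tables with the statistical structure the estimator assumes.

The study's survey microdata are not public; this module emulates the
study conditions so every pipeline stage is testable without a download:

* 32 videos totalling 821 coded 10 s intervals, with per-interval content
  drawn so the expected class totals match the published 233 alcohol,
  47 tobacco and 6 e-cigarette intervals;
* ~2068 adolescent (11-18) and ~2232 adult (19+) respondents with
  calibration-style weights, gender mix matching the surveys, and adult
  ages distributed according to the mid-year population margins;
* an ever-seen probability per (respondent, video) following a logistic
  model that declines steeply with age and is higher for females, with a
  per-video popularity random effect (normal on the log-odds scale), so
  group reach is roughly 0.22 for adolescents and 0.06 for adults.

A single root seed is split into independent substreams per component
(video structure, video effects, demographics, indicators), so changing
one component's draw count does not perturb the others.  The truth record
returned by :func:`generate_scenario` carries the model-implied reach of
the realised sample, the quantity recovery and CI-coverage tests target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .content_coding import CHANNELS, CATEGORIES, FLAG_COLUMNS, SUBSTANCES, CodedVideo
from .population import PopulationTable
from .reference_data import (
    ALCOHOL_INTERVALS,
    ECIG_INTERVALS,
    N_ADOLESCENT_FEMALE,
    N_ADOLESCENTS,
    N_ADULT_FEMALE,
    N_ADULTS,
    N_VIDEOS,
    TOBACCO_INTERVALS,
    TOTAL_INTERVALS,
    uk_mid_year_population,
)
from .survey import Respondent, Stratum

__all__ = [
    "ViewingModel",
    "GeneratorConfig",
    "Scenario",
    "generate_videos",
    "generate_survey",
    "generate_scenario",
    "model_reach",
    "population_reach",
    "synthetic_gender_split_population",
]

#: Adult age bands of the population margins, with (low, high-inclusive).
_ADULT_BANDS = ((19, 24, 5.12), (25, 34, 8.68), (35, 44, 8.46), (45, 54, 9.03), (55, 90, 17.90))


@dataclass(frozen=True)
class ViewingModel:
    """Logistic ever-seen model: logit p = intercept + age_coef*(age-age_ref)
    + female_coef*[female] + u_video, u_video ~ N(0, video_sd^2).

    Defaults are calibrated to the published group means: reach ~0.22 at
    ages 11-18 and ~0.06 at 19+, with female reach above male.
    """

    intercept: float = -1.69       # male log-odds at the reference age
    age_coef: float = -0.0575      # per year of age
    female_coef: float = 0.64      # log-odds boost for females
    age_ref: float = 14.5
    video_sd: float = 0.5          # popularity random-effect SD (log-odds)

    def probabilities(
        self, ages: np.ndarray, is_female: np.ndarray, video_effects: np.ndarray
    ) -> np.ndarray:
        """(n_respondents, n_videos) matrix of ever-seen probabilities."""
        logit = (
            self.intercept
            + self.age_coef * (np.asarray(ages, dtype=float) - self.age_ref)
            + self.female_coef * np.asarray(is_female, dtype=float)
        )
        return 1.0 / (1.0 + np.exp(-(logit[:, None] + np.asarray(video_effects)[None, :])))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults emulate the study margins."""

    seed: int = 0
    n_videos: int = N_VIDEOS
    total_intervals: int = TOTAL_INTERVALS
    min_intervals_per_video: int = 10
    #: per-substance Bernoulli probability that an interval carries content;
    #: calibrated so expected totals are 233 / 47 / 6 over 821 intervals.
    content_rates: dict[str, float] = field(
        default_factory=lambda: {
            "alcohol": ALCOHOL_INTERVALS / TOTAL_INTERVALS,
            "tobacco": TOBACCO_INTERVALS / TOTAL_INTERVALS,
            "electronic_cigarette": ECIG_INTERVALS / TOTAL_INTERVALS,
        }
    )
    #: probability a tobacco interval also carries alcohol; None = substances
    #: drawn independently (the overlap structure is unreported).
    overlap_rate: float | None = None
    n_adolescents: int = N_ADOLESCENTS
    n_adults: int = N_ADULTS
    female_fraction_adolescent: float = N_ADOLESCENT_FEMALE / N_ADOLESCENTS
    female_fraction_adult: float = N_ADULT_FEMALE / N_ADULTS
    viewing_model: ViewingModel = field(default_factory=ViewingModel)
    #: sigma of the mean-1 lognormal survey weights; 0 = equal weights.
    weight_dispersion: float = 0.3
    max_adult_age: int = 90

    def __post_init__(self) -> None:
        for s, p in self.content_rates.items():
            if s not in SUBSTANCES:
                raise ValueError(f"unknown substance {s!r} in content_rates")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"content rate for {s!r} must be in [0,1], got {p}")
        if self.overlap_rate is not None and not 0.0 <= self.overlap_rate <= 1.0:
            raise ValueError(f"overlap_rate must be in [0,1], got {self.overlap_rate}")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be non-negative")


@dataclass
class Scenario:
    """A complete runnable input set plus its ground truth."""

    videos: list[CodedVideo]
    respondents: list[Respondent]
    population: PopulationTable
    truth: dict


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("videos", "video_effects", "demographics", "indicators")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _interval_counts(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Random composition: every video gets the minimum, the remaining
    intervals are spread multinomially, so the realised total is exact."""
    base = config.min_intervals_per_video
    extra = config.total_intervals - config.n_videos * base
    if extra < 0:
        raise ValueError(
            f"total_intervals={config.total_intervals} cannot accommodate "
            f"{config.n_videos} videos of at least {base} intervals"
        )
    counts = base + rng.multinomial(extra, np.full(config.n_videos, 1.0 / config.n_videos))
    return counts


def generate_videos(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[CodedVideo]:
    """Draw coded videos: interval counts, then per-interval substance
    presence at ``content_rates``; a present substance sets one uniformly
    chosen (category, channel) flag plus each further flag w.p. 0.15."""
    if rng is None:
        rng = _streams(config.seed)["videos"]
    counts = _interval_counts(config, rng)
    colix = {c: j for j, c in enumerate(FLAG_COLUMNS)}
    n_flags_per_substance = len(CATEGORIES) * len(CHANNELS)
    videos: list[CodedVideo] = []
    for v in range(config.n_videos):
        n = int(counts[v])
        mat = np.zeros((n, len(FLAG_COLUMNS)), dtype=bool)
        present = {
            substance: rng.random(n) < config.content_rates.get(substance, 0.0)
            for substance in SUBSTANCES
        }
        if config.overlap_rate is not None:
            # on tobacco intervals, alcohol presence follows the overlap rate
            redraw = rng.random(n) < config.overlap_rate
            tob = present["tobacco"]
            present["alcohol"] = np.where(tob, redraw, present["alcohol"])
        for substance in SUBSTANCES:
            if not present[substance].any():
                continue
            sub_cols = [colix[f"{substance}.{c}.{ch}"] for c in CATEGORIES for ch in CHANNELS]
            idx = np.flatnonzero(present[substance])
            primary = rng.integers(0, n_flags_per_substance, size=idx.size)
            extras = rng.random((idx.size, n_flags_per_substance)) < 0.15
            for k, i in enumerate(idx):
                mat[i, sub_cols[primary[k]]] = True
                for j in np.flatnonzero(extras[k]):
                    mat[i, sub_cols[j]] = True
        # duration lands inside the final interval's window
        duration = (n - 1) * 10 + float(rng.uniform(1.0, 10.0))
        videos.append(
            CodedVideo.from_flag_matrix(
                f"video_{v:02d}", mat, duration_s=duration, title=f"Synthetic video {v}"
            )
        )
    return videos


def _draw_demographics(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ages, is_female flags and weights for the pooled sample
    (adolescents first, then adults)."""
    n_teen, n_adult = config.n_adolescents, config.n_adults
    teen_ages = rng.integers(11, 19, size=n_teen)
    band_pops = np.array([b[2] for b in _ADULT_BANDS])
    band_idx = rng.choice(len(_ADULT_BANDS), size=n_adult, p=band_pops / band_pops.sum())
    lows = np.array([b[0] for b in _ADULT_BANDS])[band_idx]
    highs = np.minimum(
        np.array([b[1] for b in _ADULT_BANDS])[band_idx], config.max_adult_age
    )
    adult_ages = rng.integers(lows, highs + 1)
    ages = np.concatenate([teen_ages, adult_ages])

    # iid draws (age, gender) emulate the panel's sampling, so the survey
    # estimator's iid variance formula is coherent with the generator
    is_female = np.concatenate(
        [
            rng.random(n_teen) < config.female_fraction_adolescent,
            rng.random(n_adult) < config.female_fraction_adult,
        ]
    )

    sigma = config.weight_dispersion
    if sigma == 0:
        weights = np.ones(n_teen + n_adult)
    else:
        weights = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_teen + n_adult)
    return ages, is_female, weights


def generate_survey(
    config: GeneratorConfig,
    videos: Sequence[CodedVideo],
    _parts: tuple | None = None,
) -> list[Respondent]:
    """Draw survey respondents with ever-seen indicators for ``videos``."""
    if not videos:
        raise ValueError("cannot generate a survey for an empty video collection")
    if _parts is None:
        streams = _streams(config.seed)
        video_effects = streams["video_effects"].normal(
            0.0, config.viewing_model.video_sd, size=len(videos)
        )
        ages, is_female, weights = _draw_demographics(config, streams["demographics"])
        rng_ind = streams["indicators"]
    else:
        video_effects, ages, is_female, weights, rng_ind = _parts
    probs = config.viewing_model.probabilities(ages, is_female, video_effects)
    seen = rng_ind.random(probs.shape) < probs
    video_ids = [v.video_id for v in videos]
    return [
        Respondent(
            respondent_id=f"r{i:05d}",
            age=int(ages[i]),
            gender="female" if is_female[i] else "male",
            weight=float(weights[i]),
            seen={vid: bool(seen[i, j]) for j, vid in enumerate(video_ids)},
        )
        for i in range(len(ages))
    ]


def synthetic_gender_split_population() -> PopulationTable:
    """Synthetic population table with per-gender age-band entries.

    Per-gender band populations are not published; each band's published
    total is split with the adolescent or adult gender share (2.88/5.91
    for ages 11-18, 25.18/49.20 for 19+), so aggregates reproduce the
    published margins.
    """
    base = uk_mid_year_population()
    entries = dict(base.entries)
    teen_f = 2.88 / 5.91
    adult_f = 25.18 / 49.20
    for s, v in base.entries.items():
        if s.gender != "all" or s in (Stratum(11, 19), Stratum(19, None)):
            continue
        share_f = teen_f if (s.age_max is not None and s.age_max <= 19) else adult_f
        entries[Stratum(s.age_min, s.age_max, "female")] = v * share_f
        entries[Stratum(s.age_min, s.age_max, "male")] = v * (1 - share_f)
    return PopulationTable(entries, reference_period=base.reference_period + " (synthetic gender split)")


def model_reach(
    config: GeneratorConfig,
    video_effects: np.ndarray,
    ages: np.ndarray,
    is_female: np.ndarray,
    weights: np.ndarray,
    stratum: Stratum,
) -> float:
    """Model-implied reach of the realised sample in a stratum: the
    weighted mean over in-stratum respondents of their mean ever-seen
    probability across videos.  This is the estimand the weighted survey
    estimator is unbiased for, conditional on the realised sample."""
    genders = np.where(is_female, "female", "male")
    mask = np.array([stratum.contains(int(a), g) for a, g in zip(ages, genders)])
    if not mask.any():
        raise ValueError(f"no synthetic respondents in stratum {stratum.label!r}")
    probs = config.viewing_model.probabilities(ages[mask], is_female[mask], video_effects)
    f_true = probs.mean(axis=1)
    w = weights[mask]
    return float((w * f_true).sum() / w.sum())


def population_reach(
    config: GeneratorConfig, video_effects: np.ndarray, stratum: Stratum
) -> float:
    """Model-implied group reach marginalised over the generator's
    demographic distribution, conditional on the realised per-video
    popularity effects.

    This is the super-population estimand of the survey estimator: the
    expected mean ever-seen probability over the age x gender distribution
    the respondents are drawn from (ages uniform over 11-18 for
    adolescents, band-weighted uniform for adults; gender mix at the
    configured female fractions; groups weighted by their sample sizes).
    Exact enumeration — no Monte Carlo.
    """
    cells: list[tuple[int, bool, float]] = []  # (age, is_female, weight)
    n_total = config.n_adolescents + config.n_adults
    teen_w = config.n_adolescents / n_total
    for age in range(11, 19):
        for fem, share in (
            (True, config.female_fraction_adolescent),
            (False, 1 - config.female_fraction_adolescent),
        ):
            cells.append((age, fem, teen_w * share / 8))
    adult_w = config.n_adults / n_total
    band_pops = np.array([b[2] for b in _ADULT_BANDS])
    band_pops = band_pops / band_pops.sum()
    for (lo, hi, _), bp in zip(_ADULT_BANDS, band_pops):
        hi = min(hi, config.max_adult_age)
        ages = range(lo, hi + 1)
        for age in ages:
            for fem, share in (
                (True, config.female_fraction_adult),
                (False, 1 - config.female_fraction_adult),
            ):
                cells.append((age, fem, adult_w * bp * share / len(ages)))
    genders = ["female" if f else "male" for _, f, _ in cells]
    keep = [
        (a, f, w)
        for (a, f, w), g in zip(cells, genders)
        if stratum.contains(a, g)
    ]
    if not keep:
        raise ValueError(f"stratum {stratum.label!r} is outside the generator's age range")
    ages = np.array([a for a, _, _ in keep], dtype=float)
    fem = np.array([f for _, f, _ in keep], dtype=float)
    w = np.array([wt for _, _, wt in keep])
    probs = config.viewing_model.probabilities(ages, fem, video_effects).mean(axis=1)
    return float((w * probs).sum() / w.sum())


def generate_scenario(config: GeneratorConfig | None = None) -> Scenario:
    """Generate a complete input set (videos, respondents, population) plus
    the ground-truth record used by recovery and coverage tests."""
    if config is None:
        config = GeneratorConfig()
    streams = _streams(config.seed)
    videos = generate_videos(config, streams["videos"])
    video_effects = streams["video_effects"].normal(
        0.0, config.viewing_model.video_sd, size=len(videos)
    )
    ages, is_female, weights = _draw_demographics(config, streams["demographics"])
    respondents = generate_survey(
        config, videos, _parts=(video_effects, ages, is_female, weights, streams["indicators"])
    )
    population = synthetic_gender_split_population()

    from .content_coding import ContentClass, total_content_intervals

    truth = {
        "config": config,
        "video_effects": video_effects,
        "ages": ages,
        "is_female": is_female,
        "weights": weights,
        "intervals": {
            label: total_content_intervals(videos, ContentClass.of(label))
            for label in SUBSTANCES
        },
        "reach": {
            s.label: model_reach(config, video_effects, ages, is_female, weights, s)
            for s in (Stratum(11, 19), Stratum(19, None), Stratum(11, None))
        },
        "population_reach": {
            s.label: population_reach(config, video_effects, s)
            for s in (Stratum(11, 19), Stratum(19, None), Stratum(11, None))
        },
    }
    return Scenario(videos=videos, respondents=respondents, population=population, truth=truth)
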