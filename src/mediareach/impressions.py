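"""Gross and per-capita impression estimation.

The estimand is the number of exposure events ("impressions") a set of
coded videos delivers to a population stratum: one impression is one person
seeing one 10 s interval containing content, counting each person at most
once per video (ever-seen, single-viewing convention).  For stratum g and
content class c,

    G_{g,c} = p_bar_g x N_g x I_c          (gross, millions)
    PC_{g,c} = G_{g,c} / N_g = p_bar_g x I_c   (per capita)

where p_bar_g is the weighted mean proportion of the videos ever seen
(survey module), N_g the stratum population in millions, and I_c the number
of coded intervals containing class-c content.  Reach CI endpoints
propagate linearly through the deterministic multipliers N and I.  Because
one p_bar serves every class, gross(tobacco)/gross(alcohol) =
I_tobacco/I_alcohol exactly within a stratum.

Aggregates over disjoint strata sum gross values and, by default, sum CI
endpoints (the convention the published totals follow for independent
samples); a root-sum-square alternative is available and is narrower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .content_coding import CodedVideo, ContentClass, count_content_intervals, total_content_intervals
from .population import PopulationTable, population_for
from .survey import ReachEstimate, Respondent, Stratum, mean_proportion_viewed, per_video_proportion

__all__ = [
    "ImpressionsResult",
    "gross_impressions",
    "per_capita",
    "aggregate_impressions",
    "video_level_impressions",
    "compute_impressions",
]


@dataclass(frozen=True)
class ImpressionsResult:
    """Gross (millions) and per-capita impressions for a stratum x content
    class, with CIs and the (p_bar, N, I) audit inputs."""

    stratum: Stratum
    content_class: ContentClass | None
    gross: float
    gross_ci_low: float
    gross_ci_high: float
    per_capita: float
    pc_ci_low: float
    pc_ci_high: float
    p_bar: float
    population_m: float
    intervals: float

    @property
    def inputs(self) -> dict:
        """Audit triple: the reach, population and interval count used."""
        return {
            "p_bar": self.p_bar,
            "N_millions": self.population_m,
            "intervals": self.intervals,
        }


def gross_impressions(
    reach: ReachEstimate,
    population_m: float,
    intervals: int,
    content_class: ContentClass | None = None,
) -> ImpressionsResult:
    """Combine a stratum's reach with its population (millions) and a
    class's content-interval count into gross and per-capita impressions.

    CI endpoints scale linearly: N and I are deterministic multipliers of
    the estimated reach.  ``intervals = 0`` yields a valid all-zero result.
    """
    if intervals < 0:
        raise ValueError(f"interval count must be non-negative, got {intervals}")
    if not population_m > 0:
        raise ValueError(f"population must be positive, got {population_m}")
    scale = population_m * intervals
    return ImpressionsResult(
        stratum=reach.stratum,
        content_class=content_class,
        gross=reach.p_bar * scale,
        gross_ci_low=reach.ci_low * scale,
        gross_ci_high=reach.ci_high * scale,
        per_capita=reach.p_bar * intervals,
        pc_ci_low=reach.ci_low * intervals,
        pc_ci_high=reach.ci_high * intervals,
        p_bar=reach.p_bar,
        population_m=population_m,
        intervals=intervals,
    )


def per_capita(gross_m: float, population_m: float) -> float:
    """Per-capita impressions: gross (millions) / population (millions).

    Applied elementwise to CI endpoints by callers.
    """
    if not population_m > 0:
        raise ValueError(f"population must be positive, got {population_m}")
    return gross_m / population_m


def aggregate_impressions(
    results: Sequence[ImpressionsResult], ci_method: str = "endpoint_sum"
) -> ImpressionsResult:
    """Aggregate results over disjoint strata of one content class.

    Gross values and populations add; per-capita is the population-weighted
    combination sum(G)/sum(N).  ``ci_method='endpoint_sum'`` (default) sums
    CI endpoints across strata; ``'rss'`` combines half-widths in
    quadrature (narrower; assumes independent stratum estimates).
    """
    if not results:
        raise ValueError("cannot aggregate an empty result collection")
    if ci_method not in ("endpoint_sum", "rss"):
        raise ValueError("ci_method must be 'endpoint_sum' or 'rss'")
    classes = {r.content_class for r in results}
    if len(classes) > 1:
        raise ValueError(
            "cannot aggregate across content classes: "
            + ", ".join(sorted(c.label if c else "None" for c in classes))
        )
    for i, a in enumerate(results):
        for b in results[i + 1 :]:
            if a.stratum.overlaps(b.stratum):
                raise ValueError(
                    f"strata {a.stratum.label!r} and {b.stratum.label!r} overlap"
                )
    if len(results) == 1:
        return results[0]

    gross = sum(r.gross for r in results)
    n_total = sum(r.population_m for r in results)
    if ci_method == "endpoint_sum":
        lo = sum(r.gross_ci_low for r in results)
        hi = sum(r.gross_ci_high for r in results)
    else:
        half = math.sqrt(sum(((r.gross_ci_high - r.gross_ci_low) / 2) ** 2 for r in results))
        lo, hi = gross - half, gross + half

    age_min = min(r.stratum.age_min for r in results)
    maxes = [r.stratum.age_max for r in results]
    age_max = None if any(m is None for m in maxes) else max(maxes)
    genders = {r.stratum.gender for r in results}
    gender = genders.pop() if len(genders) == 1 else "all"
    combined = Stratum(age_min, age_max, gender)

    intervals = results[0].intervals
    return ImpressionsResult(
        stratum=combined,
        content_class=results[0].content_class,
        gross=gross,
        gross_ci_low=lo,
        gross_ci_high=hi,
        per_capita=gross / n_total,
        pc_ci_low=lo / n_total,
        pc_ci_high=hi / n_total,
        p_bar=gross / (n_total * intervals) if intervals else 0.0,
        population_m=n_total,
        intervals=intervals,
    )


def video_level_impressions(
    video_reach: ReachEstimate,
    population_m: float,
    video_intervals: int,
    content_class: ContentClass | None = None,
) -> ImpressionsResult:
    """Impressions delivered by a single video: its ever-seen proportion
    times the stratum population times its own content-interval count."""
    return gross_impressions(video_reach, population_m, video_intervals, content_class)


def compute_impressions(
    videos: Sequence[CodedVideo],
    respondents: Iterable[Respondent],
    population: PopulationTable,
    stratum: Stratum,
    content_class: ContentClass,
) -> ImpressionsResult:
    """End-to-end: stratum reach over all videos x population x class
    interval total (the aggregate-proportion estimator used for the
    headline stratified results)."""
    respondents = list(respondents)
    video_ids = [v.video_id for v in videos]
    reach = mean_proportion_viewed(respondents, video_ids, stratum)
    n = population_for(population, stratum)
    intervals = total_content_intervals(videos, content_class)
    return gross_impressions(reach, n, intervals, content_class)


def compute_video_impressions(
    video: CodedVideo,
    respondents: Iterable[Respondent],
    population: PopulationTable,
    stratum: Stratum,
    content_class: ContentClass,
) -> ImpressionsResult:
    """End-to-end for a single video: per-video ever-seen proportion x
    population x that video's class interval count."""
    respondents = list(respondents)
    reach = per_video_proportion(respondents, video.video_id, stratum)
    n = population_for(population, stratum)
    intervals = count_content_intervals(video, content_class)
    return video_level_impressions(reach, n, intervals, content_class)
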