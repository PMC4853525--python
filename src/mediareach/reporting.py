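"""Assembly of estimator outputs into presentation tables with an audit trail.

Two surfaces: a stratified exposure table (population, reach and gross /
per-capita impressions per stratum and content class, with a Total row
aggregated from the adolescent and adult rows) and a long-format
per-capita-by-age-band-and-gender chart-data table.  Internal values stay
full precision; rounding (half-up, 2 decimal places by default) happens
only at render time, so the algebraic identities between cells hold
exactly in memory.  Every rendered number is traceable to its
(p_bar, N, I) audit triple.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .content_coding import CodedVideo, ContentClass, count_content_intervals, total_content_intervals
from .impressions import (
    ImpressionsResult,
    aggregate_impressions,
    compute_video_impressions,
    gross_impressions,
)
from .population import PopulationTable, PopulationLookupError, population_for
from .survey import (
    ADOLESCENTS,
    ADULTS,
    DEFAULT_AGE_BANDS,
    ReachEstimate,
    Respondent,
    Stratum,
    mean_proportion_viewed,
)

__all__ = [
    "ExposureTable",
    "DEFAULT_SCHEME",
    "CHART_SCHEME",
    "build_exposure_table",
    "exposure_table_from_data",
    "build_percapita_chart_data",
    "per_video_table",
    "round_half_up",
]

#: Stratified-table row order: summary strata with gender splits, then the
#: age bands, then a Total row aggregated from adolescents + adults.
DEFAULT_SCHEME: tuple[Stratum, ...] = (
    ADOLESCENTS,
    Stratum(11, 19, "female"),
    Stratum(11, 19, "male"),
    ADULTS,
    Stratum(19, None, "female"),
    Stratum(19, None, "male"),
    *DEFAULT_AGE_BANDS,
)

#: Scheme for chart data: every age band split by gender.
CHART_SCHEME: tuple[Stratum, ...] = tuple(
    Stratum(b.age_min, b.age_max, g) for b in DEFAULT_AGE_BANDS for g in ("female", "male")
)


def round_half_up(x: float, places: int = 2) -> float:
    """Decimal half-up rounding at the printed precision."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ExposureTable:
    """Ordered stratified results plus the audit metadata to reproduce them.

    ``rows`` maps each stratum to its reach estimate, population and one
    :class:`ImpressionsResult` per content class; ``total`` holds the
    aggregated Total row.  ``metadata`` echoes the run configuration.
    """

    strata: list[Stratum]
    reach: dict[Stratum, ReachEstimate]
    population: dict[Stratum, float]
    results: dict[tuple[Stratum, str], ImpressionsResult]
    classes: list[ContentClass]
    total: dict[str, ImpressionsResult]
    total_stratum: Stratum
    metadata: dict = field(default_factory=dict)

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """Full-precision (or rendered, if ``decimals`` given) DataFrame in
        the published layout: one row per stratum plus Total."""
        rnd = (lambda x: round_half_up(x, decimals)) if decimals is not None else (lambda x: x)
        rows = []
        for s in self.strata:
            rec: dict = {
                "stratum": s.label,
                "population_millions": rnd(self.population[s]),
                "proportion_viewed": rnd(self.reach[s].p_bar),
                "proportion_ci_low": rnd(self.reach[s].ci_low),
                "proportion_ci_high": rnd(self.reach[s].ci_high),
            }
            for c in self.classes:
                r = self.results[(s, c.label)]
                rec[f"gross_{c.label}"] = rnd(r.gross)
                rec[f"gross_{c.label}_ci_low"] = rnd(r.gross_ci_low)
                rec[f"gross_{c.label}_ci_high"] = rnd(r.gross_ci_high)
                rec[f"percapita_{c.label}"] = rnd(r.per_capita)
                rec[f"percapita_{c.label}_ci_low"] = rnd(r.pc_ci_low)
                rec[f"percapita_{c.label}_ci_high"] = rnd(r.pc_ci_high)
            rows.append(rec)
        r0 = next(iter(self.total.values()))
        scale = r0.population_m * r0.intervals
        tot = {
            "stratum": "Total",
            "population_millions": rnd(r0.population_m),
            "proportion_viewed": rnd(r0.p_bar),
            "proportion_ci_low": rnd(r0.gross_ci_low / scale) if scale else None,
            "proportion_ci_high": rnd(r0.gross_ci_high / scale) if scale else None,
        }
        for c in self.classes:
            r = self.total[c.label]
            tot[f"gross_{c.label}"] = rnd(r.gross)
            tot[f"gross_{c.label}_ci_low"] = rnd(r.gross_ci_low)
            tot[f"gross_{c.label}_ci_high"] = rnd(r.gross_ci_high)
            tot[f"percapita_{c.label}"] = rnd(r.per_capita)
            tot[f"percapita_{c.label}_ci_low"] = rnd(r.pc_ci_low)
            tot[f"percapita_{c.label}_ci_high"] = rnd(r.pc_ci_high)
        rows.append(tot)
        return pd.DataFrame(rows)

    def render_csv(self, path=None, decimals: int = 2) -> str:
        """Deterministic CSV rendering, half-up rounded at ``decimals``."""
        csv = self.to_frame(decimals=decimals).to_csv(index=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(csv)
        return csv

    def audit(self) -> dict:
        """The (p_bar, N, I) triple behind every cell, plus metadata."""
        cells = {
            f"{s.label}|{c}": r.inputs for (s, c), r in self.results.items()
        }
        cells.update({f"Total|{c}": r.inputs for c, r in self.total.items()})
        return {"metadata": self.metadata, "cells": cells}


def build_exposure_table(
    reach: Mapping[Stratum, ReachEstimate],
    population: PopulationTable,
    interval_counts: Mapping[str, int],
    classes: Sequence[ContentClass],
    scheme: Sequence[Stratum] = DEFAULT_SCHEME,
    total_constituents: Sequence[Stratum] = (ADOLESCENTS, ADULTS),
    metadata: Mapping | None = None,
) -> ExposureTable:
    """Assemble reach estimates, populations and class interval counts into
    the stratified exposure table.  ``interval_counts`` maps each class
    label to its content-interval total I_c.  The Total row aggregates the
    ``total_constituents`` rows (CI endpoints summed)."""
    strata = list(scheme)
    pop: dict[Stratum, float] = {}
    for s in strata:
        try:
            pop[s] = population_for(population, s)
        except PopulationLookupError:
            raise PopulationLookupError(
                f"stratum {s.label!r} present in the survey scheme but absent "
                "from the population table"
            ) from None
        if s not in reach:
            raise KeyError(f"no reach estimate supplied for stratum {s.label!r}")

    results: dict[tuple[Stratum, str], ImpressionsResult] = {}
    for s in strata:
        for c in classes:
            results[(s, c.label)] = gross_impressions(
                reach[s], pop[s], int(interval_counts[c.label]), c
            )
    total: dict[str, ImpressionsResult] = {}
    for c in classes:
        parts = [results[(s, c.label)] for s in total_constituents]
        total[c.label] = aggregate_impressions(parts)
    total_stratum = total[classes[0].label].stratum

    meta = dict(metadata or {})
    meta.setdefault("generated_at", _dt.datetime.now().isoformat(timespec="seconds"))
    meta.setdefault("interval_counts", dict(interval_counts))
    meta.setdefault("classes", [c.label for c in classes])
    meta.setdefault("reference_period", population.reference_period)
    return ExposureTable(
        strata=strata,
        reach=dict(reach),
        population=pop,
        results=results,
        classes=list(classes),
        total=total,
        total_stratum=total_stratum,
        metadata=meta,
    )


def exposure_table_from_data(
    videos: Sequence[CodedVideo],
    respondents: Sequence[Respondent],
    population: PopulationTable,
    classes: Sequence[ContentClass],
    scheme: Sequence[Stratum] = DEFAULT_SCHEME,
    metadata: Mapping | None = None,
) -> ExposureTable:
    """Convenience wrapper: estimate reach per stratum from microdata, count
    class intervals from the coding, then build the exposure table."""
    video_ids = [v.video_id for v in videos]
    reach = {s: mean_proportion_viewed(respondents, video_ids, s) for s in scheme}
    interval_counts = {c.label: total_content_intervals(videos, c) for c in classes}
    return build_exposure_table(
        reach, population, interval_counts, classes, scheme=scheme, metadata=metadata
    )


def build_percapita_chart_data(table: ExposureTable) -> pd.DataFrame:
    """Long-format per-capita records (age_band, gender, class, value) from
    the table's gender-split age-band rows — the chart-data surface."""
    gendered = [
        s for s in table.strata if s.gender in ("female", "male")
        and any(
            o.gender != s.gender and o.age_min == s.age_min and o.age_max == s.age_max
            for o in table.strata
        )
    ]
    bands = sorted(
        {(s.age_min, s.age_max) for s in gendered},
        key=lambda b: b[0],
    )
    # keep only proper bands (not the 11-18/19+ summary splits) when finer
    # bands are present alongside them
    fine = [b for b in bands if not any(o != b and o[0] >= b[0] and (b[1] is None or (o[1] is not None and o[1] <= b[1])) for o in bands)]
    use = fine or bands
    if not use:
        raise ValueError("exposure table contains no gender-split age-band rows")
    records = []
    for lo, hi in use:
        for g in ("female", "male"):
            s = Stratum(lo, hi, g)
            if s not in table.strata:
                raise ValueError(f"missing gender split: no row for {s.label!r}")
            for c in table.classes:
                r = table.results[(s, c.label)]
                records.append(
                    {
                        "age_band": s.age_label,
                        "gender": g,
                        "content_class": c.label,
                        "per_capita": r.per_capita,
                        "ci_low": r.pc_ci_low,
                        "ci_high": r.pc_ci_high,
                    }
                )
    return pd.DataFrame(records)


def per_video_table(
    videos: Sequence[CodedVideo],
    respondents: Sequence[Respondent],
    population: PopulationTable,
    classes: Sequence[ContentClass],
    strata: Sequence[Stratum] = (ADOLESCENTS, ADULTS),
) -> pd.DataFrame:
    """Video-level breakdown: per-video reach x population x per-video
    interval count, for each stratum and class (full precision)."""
    rows = []
    for v in videos:
        for s in strata:
            for c in classes:
                r = compute_video_impressions(v, respondents, population, s, c)
                rows.append(
                    {
                        "video_id": v.video_id,
                        "title": v.title,
                        "stratum": s.label,
                        "content_class": c.label,
                        "video_intervals": count_content_intervals(v, c),
                        "proportion_viewed": r.p_bar,
                        "gross_millions": r.gross,
                        "gross_ci_low": r.gross_ci_low,
                        "gross_ci_high": r.gross_ci_high,
                        "per_capita": r.per_capita,
                        "pc_ci_low": r.pc_ci_low,
                        "pc_ci_high": r.pc_ci_high,
                    }
                )
    return pd.DataFrame(rows)


def write_report(table: ExposureTable, out_dir, per_video: pd.DataFrame | None = None) -> None:
    """Write table1.csv / table1.json / figure1_data.csv / audit.json (and
    pervideo.csv when provided) into ``out_dir``."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.render_csv(out / "table1.csv")
    (out / "table1.json").write_text(
        table.to_frame().to_json(orient="records", indent=1)
    )
    try:
        chart = build_percapita_chart_data(table)
        chart.to_csv(out / "figure1_data.csv", index=False)
    except ValueError:
        pass  # no gender-split bands in this scheme
    (out / "audit.json").write_text(json.dumps(table.audit(), indent=1, default=str))
    if per_video is not None:
        per_video.to_csv(out / "pervideo.csv", index=False)
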