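"""Census mid-year population counts by age band and gender.

Holds the N (persons, in millions throughout the public interface) used in
every extrapolation.  A query stratum resolves either directly or as an
exact union of finer entries: e.g. adolescents 11-18 resolves as
11-12 + 13-15 + 16-18, and an 'all'-gender query may resolve as the sum of
its female and male entries.  Direct entries take precedence over covers,
so a table may carry a published aggregate that differs (by rounding) from
the sum of its published parts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .survey import Stratum

__all__ = ["PopulationTable", "population_for", "load_population", "write_population"]


class PopulationLookupError(KeyError):
    """Raised when a stratum cannot be resolved from a population table."""


@dataclass
class PopulationTable:
    """Persons (millions) by stratum, with a reference-period label."""

    entries: dict[Stratum, float]
    reference_period: str = ""

    def __post_init__(self) -> None:
        for s, v in self.entries.items():
            if not v > 0:
                raise ValueError(f"population for {s.label!r} must be positive, got {v}")

    def __getitem__(self, stratum: Stratum) -> float:
        return population_for(self, stratum)


def _cover_sum(
    entries: Mapping[Stratum, float], stratum: Stratum, gender: str
) -> float | None:
    """Sum of entries of the given gender exactly tiling the stratum's age
    range, or None if no exact tiling exists.  When both a coarse aggregate
    and its finer parts are present, the coarsest entry at each position is
    preferred (published aggregates over sums of rounded parts)."""
    candidates = [
        (s, v)
        for s, v in entries.items()
        if s.gender == gender
        and s.age_min >= stratum.age_min
        and (
            stratum.age_max is None
            or (s.age_max is not None and s.age_max <= stratum.age_max)
        )
    ]
    pos: int | None = stratum.age_min
    total = 0.0
    while pos != stratum.age_max:
        here = [(s, v) for s, v in candidates if s.age_min == pos]
        if not here:
            return None
        # widest span first; open-ended counts as widest
        s, v = max(
            here, key=lambda sv: math.inf if sv[0].age_max is None else sv[0].age_max
        )
        total += v
        pos = s.age_max
        if pos is None:
            break
    if pos != stratum.age_max:
        return None
    return total


def population_for(table: PopulationTable, stratum: Stratum) -> float:
    """Population (millions) for a stratum: direct value, or exact sum over
    constituent finer entries.  Raises :class:`PopulationLookupError`
    listing the available strata when unresolvable."""
    if stratum in table.entries:
        return table.entries[stratum]
    # exact age-band cover with the same gender
    total = _cover_sum(table.entries, stratum, stratum.gender)
    if total is not None:
        return total
    # an 'all'-gender query may split into female + male
    if stratum.gender == "all":
        f = _cover_sum(table.entries, stratum, "female")
        m = _cover_sum(table.entries, stratum, "male")
        if f is not None and m is not None:
            return f + m
    available = ", ".join(sorted(s.label for s in table.entries))
    raise PopulationLookupError(
        f"stratum {stratum.label!r} is not resolvable from the population table; "
        f"available strata: {available}"
    )


def load_population(path, reference_period: str = "") -> PopulationTable:
    """Read a population CSV with columns age_low, age_high, gender,
    persons_millions.  age_high is inclusive; 'plus' (or blank) marks an
    open-ended band such as 55+."""
    df = pd.read_csv(path)
    entries: dict[Stratum, float] = {}
    for _, row in df.iterrows():
        hi = row["age_high"]
        if pd.isna(hi) or str(hi).strip().lower() in ("plus", "+", ""):
            age_max = None
        else:
            age_max = int(hi) + 1
        s = Stratum(int(row["age_low"]), age_max, str(row["gender"]))
        entries[s] = float(row["persons_millions"])
    return PopulationTable(entries, reference_period=reference_period)


def write_population(table: PopulationTable, path) -> None:
    rows = []
    for s, v in table.entries.items():
        rows.append(
            {
                "age_low": s.age_min,
                "age_high": "plus" if s.age_max is None else s.age_max - 1,
                "gender": s.gender,
                "persons_millions": v,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
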