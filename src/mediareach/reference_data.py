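"""Published summary figures from the UK study of tobacco and alcohol
content in the 32 most popular YouTube music videos.

The underlying survey microdata are not public, so these printed summary
values serve two roles: (1) calibration targets for the synthetic-data
generator, and (2) inputs to arithmetic-identity checks — the estimator's
algebra (per-capita = gross / N; gross(tobacco)/gross(alcohol) =
I_tobacco/I_alcohol) reproduces printed cells from other printed cells.

All populations and gross impressions are in millions of persons /
impressions; per-capita values are impressions per person.
"""

from __future__ import annotations

from .population import PopulationTable
from .survey import Stratum

#: Content interval totals over the 32 surveyed videos (821 intervals).
TOTAL_INTERVALS = 821
N_VIDEOS = 32
ALCOHOL_INTERVALS = 233
TOBACCO_INTERVALS = 47
ECIG_INTERVALS = 6

#: Survey sample sizes (ever-seen surveys of the 32 videos).
N_ADOLESCENTS = 2068          # ages 11-18: 1010 boys, 1058 girls
N_ADOLESCENT_FEMALE = 1058
N_ADULTS = 2232               # ages 19+: 1052 males, 1180 females
N_ADULT_FEMALE = 1180

#: UK mid-year population estimates (2012-13), millions of persons.
_POP = {
    Stratum(11, 19): 5.91,
    Stratum(11, 19, "female"): 2.88,
    Stratum(11, 19, "male"): 3.03,
    Stratum(19, None): 49.20,
    Stratum(19, None, "female"): 25.18,
    Stratum(19, None, "male"): 24.02,
    Stratum(11, 13): 1.38,
    Stratum(13, 16): 2.21,
    Stratum(16, 19): 2.32,
    Stratum(19, 25): 5.12,
    Stratum(25, 35): 8.68,
    Stratum(35, 45): 8.46,
    Stratum(45, 55): 9.03,
    Stratum(55, None): 17.90,
}


def uk_mid_year_population() -> PopulationTable:
    """The published UK mid-year population margins by stratum."""
    return PopulationTable(dict(_POP), reference_period="UK mid-year 2012-13")


#: Published stratified reach: weighted proportion of the 32 videos ever
#: viewed, with 95% CI, by stratum label.
PUBLISHED_REACH: dict[str, tuple[float, float, float]] = {
    "11-18": (0.22, 0.19, 0.26),
    "11-18 female": (0.28, 0.23, 0.33),
    "11-18 male": (0.17, 0.14, 0.20),
    "19+": (0.06, 0.04, 0.08),
    "19+ female": (0.07, 0.05, 0.09),
    "19+ male": (0.05, 0.03, 0.06),
    "11-12": (0.19, 0.15, 0.23),
    "13-15": (0.24, 0.21, 0.28),
    "16-18": (0.22, 0.18, 0.27),
    "19-24": (0.15, 0.11, 0.19),
    "25-34": (0.10, 0.07, 0.13),
    "35-44": (0.07, 0.05, 0.09),
    "45-54": (0.04, 0.03, 0.06),
    "55+": (0.02, 0.01, 0.03),
    "11+": (0.14, 0.13, 0.14),
}

#: Published gross impressions in millions (value, ci_low, ci_high) keyed by
#: (stratum label, content class label).
PUBLISHED_GROSS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("11-18", "alcohol"): (308.19, 256.44, 359.93),
    ("11-18", "tobacco"): (62.17, 51.73, 72.60),
    ("11-18 female", "alcohol"): (186.35, 152.98, 219.71),
    ("11-18 female", "tobacco"): (37.59, 30.86, 44.32),
    ("11-18 male", "alcohol"): (118.14, 98.05, 138.23),
    ("11-18 male", "tobacco"): (23.83, 19.78, 27.88),
    ("19+", "alcohol"): (695.09, 502.38, 887.80),
    ("19+", "tobacco"): (140.21, 101.34, 179.08),
    ("19+ female", "alcohol"): (429.15, 311.65, 546.66),
    ("19+ female", "tobacco"): (86.57, 62.86, 110.27),
    ("19+ male", "alcohol"): (260.81, 184.23, 337.39),
    ("19+ male", "tobacco"): (52.61, 37.16, 68.06),
    ("11-12", "alcohol"): (61.96, 49.18, 74.75),
    ("11-12", "tobacco"): (12.50, 9.92, 15.08),
    ("13-15", "alcohol"): (125.87, 107.75, 144.00),
    ("13-15", "tobacco"): (25.39, 21.73, 29.05),
    ("16-18", "alcohol"): (120.94, 97.21, 144.67),
    ("16-18", "tobacco"): (24.40, 19.61, 29.18),
    ("19-24", "alcohol"): (178.34, 133.57, 223.10),
    ("19-24", "tobacco"): (35.97, 26.94, 45.00),
    ("25-34", "alcohol"): (205.92, 150.04, 261.80),
    ("25-34", "tobacco"): (41.54, 30.27, 52.81),
    ("35-44", "alcohol"): (138.48, 93.95, 183.02),
    ("35-44", "tobacco"): (27.93, 18.95, 36.92),
    ("45-54", "alcohol"): (93.62, 63.13, 124.11),
    ("45-54", "tobacco"): (18.88, 12.73, 25.03),
    ("55+", "alcohol"): (80.72, 53.14, 108.31),
    ("55+", "tobacco"): (16.28, 10.72, 21.85),
    ("11+", "alcohol"): (1005.86, 747.96, 1263.76),
    ("11+", "tobacco"): (202.90, 150.88, 254.92),
}

#: Published per-capita impressions (value, ci_low, ci_high) for the cells
#: used in identity checks.
PUBLISHED_PER_CAPITA: dict[tuple[str, str], tuple[float, float, float]] = {
    ("11-18", "alcohol"): (52.11, 43.36, 60.86),
    ("11-18", "tobacco"): (10.51, 8.75, 12.28),
    ("19+", "alcohol"): (14.13, 10.21, 18.05),
    ("19+", "tobacco"): (2.85, 2.06, 3.64),
    ("19+ female", "alcohol"): (17.04, 12.38, 21.71),
    ("19+ male", "alcohol"): (10.86, 7.67, 14.05),
    ("11+", "alcohol"): (18.25, 13.57, 22.93),
    ("11+", "tobacco"): (3.68, 2.74, 4.63),
}

#: Published video-level gross impressions in millions for the headline
#: videos: (total 11+, adolescent 11-18) with CIs where printed.
PUBLISHED_VIDEO_GROSS: dict[str, dict[str, tuple[float, float, float]]] = {
    # highest alcohol gross: 'Timber'
    "timber": {
        "total": (162.59, 145.47, 179.70),
        "adolescent": (44.47, 41.71, 47.22),
    },
    # highest tobacco gross: 'Trumpets'
    "trumpets": {
        "total": (36.80, 32.31, 41.30),
        "adolescent": (12.27, 11.46, 13.09),
    },
}
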