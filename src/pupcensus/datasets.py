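"""Published Australian fur seal census and trend results.

These are the published colony registry, the 2007/2013/2017 census
results and the fitted trend table for the species. They serve as
regression-test inputs for the pipeline: the census arithmetic, the
conversion factors, the between-census change columns and the
rate-of-change regression can all be recomputed from these values.

Coordinates are decimal degrees (south/east positive east, negative
latitude). ``None`` marks a site not surveyed in that census.
"""

from __future__ import annotations

import pandas as pd

from .abundance import AbundanceEstimate
from .trends import TrendFit

__all__ = [
    "registry_frame",
    "census_frame",
    "trend_frame",
    "published_estimates",
    "published_trend_fits",
    "most_recent_published_abundance",
    "KANOWNA_DIRECT_COUNTS",
    "KANOWNA_CONVERSION_FACTOR",
    "PUBLISHED_TOTALS",
]

_CBS = "Central Bass Strait"
_BON = "Bonney Upwelling"
_KIU = "Kangaroo Island upwelling"
_EPU = "Eyre Peninsula Upwelling"
_WTSU = "Western Tasmanian Shelf Upwelling"
_SASW = "Sub-Antarctic surface waters"
_EAC = "East Australian Current"


def _dms(deg: int, minutes: int) -> float:
    return deg + minutes / 60.0


# 21 colonies visited in the 2017 census (7 Victorian, 14 Tasmanian).
_REGISTRY = [
    # colony_id, name, state, region, lat, lon, area_ha, height_m
    ("DMI", "Deen Maar Island", "Victoria", _BON, -_dms(38, 25), _dms(142, 0), 150, 40),
    ("SR", "Seal Rocks", "Victoria", _CBS, -_dms(38, 30), _dms(145, 10), 8, 10),
    ("Kan", "Kanowna Island", "Victoria", _CBS, -_dms(39, 10), _dms(146, 18), 130, 90),
    ("Ske", "The Skerries", "Victoria", _EAC, -_dms(37, 45), _dms(149, 31), 8, 10),
    ("Rag", "Rag Island", "Victoria", _CBS, -_dms(38, 58), _dms(146, 42), 3, 15),
    ("CB", "Cape Bridgewater", "Victoria", _BON, -_dms(38, 23), _dms(141, 24), 1, 0),
    ("MarR", "Marengo Reef", "Victoria", _BON, -_dms(38, 46), _dms(143, 67), 1, 0),
    ("RR", "Reid Rocks", "Tasmania", _WTSU, -_dms(40, 14), _dms(144, 9), 10, 8),
    ("WM", "West Moncoeur", "Tasmania", _CBS, -_dms(39, 14), _dms(146, 30), 4, 30),
    ("JR", "Judgement Rocks", "Tasmania", _CBS, -_dms(39, 30), _dms(147, 7), 14, 50),
    ("TI", "Tenth Island", "Tasmania", _CBS, -_dms(40, 57), _dms(146, 59), 1, 8),
    ("MR", "Moriarty Rocks", "Tasmania", _EAC, -_dms(40, 35), _dms(148, 16), 4, 7),
    ("WR", "Wright Rocks", "Tasmania", _CBS, -_dms(39, 36), _dms(147, 33), 4, 30),
    ("DR", "Double Rocks", "Tasmania", _CBS, -_dms(40, 20), _dms(147, 55), 1, 15),
    ("BR", "Bull Rocks", "Tasmania", _WTSU, -_dms(40, 44), _dms(147, 17), 1, 5),
    ("Sloop", "Sloop Rocks", "Tasmania", _WTSU, -_dms(42, 18), _dms(145, 10), 2, 15),
    ("IdP", "Iles des Phoques", "Tasmania", _SASW, -_dms(42, 25), _dms(148, 9), 8, 7),
    ("Maat", "Maatsuyker Island", "Tasmania", _SASW, -_dms(43, 38), _dms(146, 17), 186, 284),
    ("Wen", "Wendar Island", "Tasmania", _SASW, -_dms(43, 24), _dms(145, 55), 5.8, 40),
    ("Nde", "Needle Rocks", "Tasmania", _SASW, -_dms(43, 39), _dms(146, 15), 10.5, 42),
    ("Wal", "Walker Island", "Tasmania", _SASW, -_dms(43, 37), _dms(146, 16), 15, 84),
]

# Census results: live pup estimates per season and the change columns as
# printed ("Na" entries become None). 26 sites appear across the three
# censuses; the Kanowna values are the converted (CMR-scale) estimates.
_CENSUS = [
    # colony_id, name, region, est_2007, est_2013, est_2017,
    #   printed change 2007-2013, printed change 2013-2017, 2017 method
    ("SR", "Seal Rocks", _CBS, 5660, 4092, 3865, "-28", "-6", "CMR"),
    ("Kan", "Kanowna Is.", _CBS, 3078, 3382, 3239, "+10", "-4", "converted_count"),
    ("JR", "Judgement Rocks", _CBS, 2387, 1710, 1752, "-28", "+2", "CMR"),
    ("Rag", "Rag Is.", _CBS, 277, 295, 351, "+7", "+19", "direct_count"),
    ("WR", "Wright Rocks", _CBS, 130, 187, 289, "+44", "+54", "direct_count"),
    ("TI", "Tenth Is.", _CBS, 448, 138, 240, "-69", "+74", "CMR"),
    ("DR", "Double Rocks", _CBS, 51, 157, 346, "+207", "+120", "direct_count"),
    ("WM", "West Moncoeur", _CBS, 204, 256, None, "+25", None, None),
    ("DMI", "Deen Maar Is.", _BON, 5574, 2659, 2866, "-52", "+8", "CMR"),
    ("CB", "Cape Bridgewater", _BON, 7, 120, 169, "+>1000", "+41", "direct_count"),
    ("MarR", "Marengo Reef", _BON, None, None, 5, None, None, "direct_count"),
    ("NC", "North Casuarina", _KIU, 28, 75, None, "+168", None, None),
    ("CG", "Cape Gantheaume", _KIU, 0, 1, 0, None, None, "incidental"),
    ("WI", "Williams Is.", _EPU, None, 2, None, None, None, None),
    ("RR", "Reid Rocks", _WTSU, 395, 1570, 1568, "+297", "0", "aerial"),
    ("Sloop", "Sloop Rocks", _WTSU, 0, 16, 31, None, "+94", "direct_count"),
    ("BR", "Bull Rocks", _WTSU, 7, 21, 44, "+200", "+109", "direct_count"),
    ("Bau", "Baudin Rocks", _WTSU, None, 6, None, None, None, None),
    ("IdP", "Iles des Phoques", _SASW, 0, 10, 31, None, "+210", "direct_count"),
    ("Nde", "Needles", _SASW, None, 0, 155, None, None, "direct_count"),
    ("Wal", "Walker Is.", _SASW, None, 0, 96, None, None, "direct_count"),
    ("Wen", "Wendar Is.", _SASW, None, 0, 45, None, None, "direct_count"),
    ("Maat", "Maatsuyker Is.", _SASW, 1, 0, 76, None, None, "direct_count"),
    ("MR", "Moriarty Rocks", _EAC, 598, 486, 82, "-19", "-83", "aerial"),
    ("Ske", "The Skerries", _EAC, 2705, 2254, 1611, "-17", "-28", "CMR"),
    ("Mon", "Montague Is.", _EAC, 2, 19, None, "+850", None, None),
]

PUBLISHED_TOTALS = {
    2007: 21_552,
    2013: 17_456,
    2017: 16_861,
    "production_2017": 19_836,
    "population_2017": 89_300,
    "change_2007_2013": "-19",
    "change_2013_2017": "-3",
}

# Direct counts at Kanowna Island (mean, se) and the site conversion factor.
KANOWNA_DIRECT_COUNTS = {2007: (1800, 6.96), 2013: (1978, 4.24), 2017: (1894, 8.24)}
KANOWNA_CONVERSION_FACTOR = 1.71

# Fitted NB-GLM trend table: df, slope per year, intercept, z, P,
# 95% CI bounds, percent deviance explained, dispersion.
_TRENDS = [
    ("SR", 6, 0.00, 1.15, 0.41, 0.69, -0.02, 0.02, 1.9, 24.2),
    ("Kan", 10, 0.01, -7.60, 1.15, 0.25, -0.01, 0.02, 10.7, 67.1),
    ("JR", 9, -0.01, 29.00, -2.00, 0.05, -0.02, 0.00, 26.6, 63.7),
    ("Rag", 4, 0.11, -217.74, 20.22, 0.00, 0.10, 0.12, 72.7, 1_200_253.7),
    ("WR", 9, 0.25, -500.52, 7.80, 0.00, 0.19, 0.33, 87.9, 2.0),
    ("TI", 8, -0.01, 34.29, -1.03, 0.30, -0.04, 0.01, 9.4, 9.5),
    ("DR", 3, 0.21, -420.79, 16.95, 0.00, 0.19, 0.24, 97.9, 536_596.3),
    ("WM", 9, -0.00, 6.94, -0.08, 0.94, -0.02, 0.02, 0.1, 24.8),
    ("DMI", 4, -0.04, 93.87, -3.40, 0.00, -0.07, -0.02, 67.6, 28.8),
    ("CB", 9, 0.23, -452.30, 8.23, 0.00, 0.17, 0.29, 87.6, 6.6),
    ("NC", 3, 0.22, -431.97, 7.58, 0.00, 0.16, 0.28, 93.5, 81_458.3),
    ("RR", 10, 0.01, -20.79, 0.60, 0.55, -0.02, 0.05, 4.1, 2.0),
    ("Sloop", 2, 0.04, -84.45, 2.16, 0.03, 0.01, 0.09, 64.9, 3_572.5),
    ("BR", 5, 0.17, -330.93, 7.90, 0.00, 0.13, 0.21, 94.8, 154_751.3),
    ("IdP", 5, 0.28, -562.33, 5.83, 0.00, 0.20, 0.39, 94.3, 49_309.4),
    ("MR", 10, -0.03, 71.44, -1.80, 0.07, -0.07, 0.01, 16.8, 3.3),
    ("Ske", 5, -0.01, 23.98, -0.85, 0.40, -0.03, 0.01, 9.7, 38.7),
    ("Mon", 5, 0.18, -361.16, 4.00, 0.00, 0.10, 0.28, 82.7, 10.0),
]


def registry_frame() -> pd.DataFrame:
    """The 21-colony 2017 registry as a dataframe (canonical CSV schema
    plus a ``state`` column)."""
    return pd.DataFrame(
        _REGISTRY,
        columns=["colony_id", "name", "state", "region", "lat", "lon",
                 "area_ha", "height_m"],
    )


def census_frame() -> pd.DataFrame:
    """Census results for all 26 sites across the three censuses."""
    return pd.DataFrame(
        _CENSUS,
        columns=["colony_id", "name", "region", "est_2007", "est_2013",
                 "est_2017", "printed_change_2007_2013",
                 "printed_change_2013_2017", "method_2017"],
    )


def trend_frame() -> pd.DataFrame:
    """The fitted per-colony trend table."""
    return pd.DataFrame(
        _TRENDS,
        columns=["colony_id", "df", "beta_year", "intercept", "z", "p",
                 "ci_low", "ci_high", "dev_exp", "theta"],
    )


def published_estimates(season_year: int) -> list[AbundanceEstimate]:
    """Published colony estimates for one census as pipeline objects.

    Kanowna Island enters as its raw direct count so the census assembly
    applies the site conversion factor itself; every other colony enters
    at its published value.
    """
    if season_year not in (2007, 2013, 2017):
        raise ValueError(f"no census in {season_year}")
    col = f"est_{season_year}"
    out: list[AbundanceEstimate] = []
    for row in census_frame().itertuples():
        est = getattr(row, col)
        if est is None or pd.isna(est):
            continue
        if row.colony_id == "Kan":
            mean, se = KANOWNA_DIRECT_COUNTS[season_year]
            out.append(
                AbundanceEstimate("Kan", season_year, float(mean), float(se) ** 2,
                                  "direct_count")
            )
        else:
            out.append(
                AbundanceEstimate(row.colony_id, season_year, float(est), 0.0, "CMR")
            )
    return out


def published_trend_fits() -> list[TrendFit]:
    """The published trend table as :class:`TrendFit` objects."""
    fits = []
    for row in trend_frame().itertuples():
        fits.append(
            TrendFit(
                colony_id=row.colony_id, n_obs=row.df + 2, df_resid=row.df,
                beta_year=row.beta_year, intercept=row.intercept, z=row.z,
                p_value=row.p, ci=(row.ci_low, row.ci_high),
                dev_exp=row.dev_exp, theta=row.theta,
                initial_theta=row.theta, converged=True,
            )
        )
    return fits


def most_recent_published_abundance() -> dict[str, int]:
    """Latest published estimate per site (2017 where surveyed, else the
    most recent earlier census)."""
    out: dict[str, int] = {}
    for row in census_frame().itertuples():
        for col in ("est_2017", "est_2013", "est_2007"):
            v = getattr(row, col)
            if v is not None and not pd.isna(v):
                out[row.colony_id] = int(v)
                break
    return out
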