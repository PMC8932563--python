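"""Census table assembly, conversion factors and between-census change.

A census table holds one live-pup estimate per colony for one breeding
season, plus derived totals: total live pups, total pup production after
an early-mortality correction, and total population size via a
pups-to-population multiplier.

The mortality correction is implemented as division: live pups are taken
to be (1 - mortality_fraction) of births, so production = live / (1 - f).
A multiplicative mode (live * (1 + f)) is available for sensitivity
analysis but is not the default because only the divisive reading
reproduces published production totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._util import round_half_away, round_to_nearest
from .abundance import AbundanceEstimate

__all__ = [
    "ConversionConfig",
    "CensusRow",
    "CensusTable",
    "PercentChange",
    "assemble_census",
    "production_from_live",
    "population_from_production",
    "percent_change",
    "annualized_percent_change",
    "classify_size",
    "change_table",
]

SIZE_BOUNDS = (600, 1700)  # small < 600 <= medium < 1700 <= large


@dataclass(frozen=True)
class ConversionConfig:
    """Factors converting live-pup totals to production and population."""

    mortality_fraction: float = 0.15
    mortality_mode: str = "divide"  # "divide" (default) or "multiply"
    population_multiplier: float = 4.5
    population_rounding: int = 100
    count_conversion_factors: Mapping[str, float] = field(
        default_factory=lambda: {"Kan": 1.71}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.mortality_fraction < 1:
            raise ValueError("mortality_fraction must be in [0, 1)")
        if self.population_multiplier <= 0:
            raise ValueError("population_multiplier must be positive")
        if self.mortality_mode not in ("divide", "multiply"):
            raise ValueError("mortality_mode must be 'divide' or 'multiply'")
        if any(f <= 0 for f in self.count_conversion_factors.values()):
            raise ValueError("count conversion factors must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConversionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class CensusRow:
    colony_id: str
    region: str
    estimate: int  # rounded reported estimate
    se: float | None
    size_category: str
    method: str


@dataclass(frozen=True)
class CensusTable:
    season_year: int
    rows: tuple[CensusRow, ...]
    total_live_pups: int
    total_production: int
    total_population: int

    def estimate_for(self, colony_id: str) -> int | None:
        for r in self.rows:
            if r.colony_id == colony_id:
                return r.estimate
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "colony_id": r.colony_id,
                    "region": r.region,
                    "season_year": self.season_year,
                    "estimate": r.estimate,
                    "se": r.se,
                    "size_category": r.size_category,
                    "method": r.method,
                }
                for r in self.rows
            ]
        )


@dataclass(frozen=True)
class PercentChange:
    """Raw and display forms of a between-census percent change."""

    raw: float
    rounded: int
    display: str


def production_from_live(total_live: int, mortality_fraction: float = 0.15,
                         mode: str = "divide") -> int:
    """Total pup production from the live-pup total.

    ``divide``: production = live / (1 - f), truncated to an integer —
    live pups are the surviving (1 - f) share of births.
    ``multiply``: production = live * (1 + f) (sensitivity mode only).
    """
    if not 0 <= mortality_fraction < 1:
        raise ValueError("mortality_fraction must be in [0, 1)")
    if total_live < 0:
        raise ValueError("total_live must be non-negative")
    if mode == "divide":
        return int(total_live / (1 - mortality_fraction))
    if mode == "multiply":
        return int(total_live * (1 + mortality_fraction))
    raise ValueError("mode must be 'divide' or 'multiply'")


def population_from_production(
    production: int, multiplier: float = 4.5, rounding: int = 100
) -> int:
    """Total population from pup production via the pup multiplier."""
    if production < 0:
        raise ValueError("production must be non-negative")
    return round_to_nearest(production * multiplier, rounding)


def percent_change(prev: float, curr: float, zero_floor: int = 1) -> PercentChange:
    """Percent change between two census estimates.

    Zero estimates are replaced by ``zero_floor`` so a change is always
    defined. The display form shows changes above +1000% as ``+>1000``.
    """
    if prev < 0 or curr < 0:
        raise ValueError("estimates must be non-negative")
    p = prev if prev > 0 else zero_floor
    c = curr if curr > 0 else zero_floor
    raw = 100.0 * (c - p) / p
    rounded = round_half_away(raw)
    if raw > 1000:
        display = "+>1000"
    elif rounded > 0:
        display = f"+{rounded}"
    else:
        display = str(rounded)
    return PercentChange(raw=raw, rounded=rounded, display=display)


def annualized_percent_change(n0: float, n1: float, years: int,
                              zero_floor: int = 1) -> float:
    """Geometric per-annum percent change between two estimates."""
    if years < 1:
        raise ValueError("years must be a positive integer")
    a = n0 if n0 > 0 else zero_floor
    b = n1 if n1 > 0 else zero_floor
    return 100.0 * ((b / a) ** (1.0 / years) - 1.0)


def classify_size(estimate: float) -> str:
    """Size category of a colony from its most recent estimate."""
    if estimate < 0:
        raise ValueError("estimate must be non-negative")
    if estimate < SIZE_BOUNDS[0]:
        return "small"
    if estimate < SIZE_BOUNDS[1]:
        return "medium"
    return "large"


def assemble_census(
    estimates: Iterable[AbundanceEstimate],
    season_year: int,
    config: ConversionConfig | None = None,
    regions: Mapping[str, str] | None = None,
) -> CensusTable:
    """Build a per-season census table from colony estimates.

    Count-conversion factors configured for a colony are applied to
    direct/aerial estimates before tabulation. Totals are sums of the
    rounded row estimates; production and population follow the
    configured conversion chain.
    """
    config = config or ConversionConfig()
    regions = regions or {}
    from .abundance import apply_count_conversion

    rows: list[CensusRow] = []
    seen: set[str] = set()
    for est in estimates:
        if est.season_year != season_year:
            raise ValueError(
                f"{est.colony_id}: estimate season {est.season_year} != {season_year}"
            )
        if est.colony_id in seen:
            raise ValueError(f"duplicate estimate for colony {est.colony_id}")
        seen.add(est.colony_id)
        factor = config.count_conversion_factors.get(est.colony_id)
        if factor is not None and est.method in ("direct_count", "aerial"):
            est = apply_count_conversion(est, factor)
        reported = est.reported
        rows.append(
            CensusRow(
                colony_id=est.colony_id,
                region=regions.get(est.colony_id, ""),
                estimate=reported,
                se=est.se if est.variance > 0 else None,
                size_category=classify_size(reported),
                method=est.method,
            )
        )
    rows.sort(key=lambda r: (r.region, -r.estimate))
    total_live = sum(r.estimate for r in rows)
    production = production_from_live(
        total_live, config.mortality_fraction, config.mortality_mode
    )
    population = population_from_production(
        production, config.population_multiplier, config.population_rounding
    )
    return CensusTable(
        season_year=season_year,
        rows=tuple(rows),
        total_live_pups=total_live,
        total_production=production,
        total_population=population,
    )


def change_table(prev: CensusTable, curr: CensusTable,
                 zero_floor: int = 1) -> pd.DataFrame:
    """Per-colony percent change between two censuses.

    Colonies missing an estimate in either census get a null change
    (displayed as "Na"); the overall row compares the two totals.
    """
    ids = [r.colony_id for r in curr.rows]
    ids += [r.colony_id for r in prev.rows if r.colony_id not in ids]
    records = []
    for cid in ids:
        a, b = prev.estimate_for(cid), curr.estimate_for(cid)
        if a is None or b is None:
            records.append(
                {"colony_id": cid, "prev": a, "curr": b,
                 "pct_change": None, "display": "Na"}
            )
        else:
            pc = percent_change(a, b, zero_floor)
            records.append(
                {"colony_id": cid, "prev": a, "curr": b,
                 "pct_change": pc.rounded, "display": pc.display}
            )
    overall = percent_change(prev.total_live_pups, curr.total_live_pups, zero_floor)
    records.append(
        {"colony_id": "TOTAL", "prev": prev.total_live_pups,
         "curr": curr.total_live_pups, "pct_change": overall.rounded,
         "display": overall.display}
    )
    return pd.DataFrame.from_records(records)
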