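"""Colony registry and survey record handling.

Canonical interchange is long-format CSV:

* ``colonies.csv``      colony_id,name,region,lat,lon,area_ha,height_m
* ``cmr_surveys.csv``   colony_id,date,subarea_id,marked_available,
                        total_resighted,marked_resighted,dead_marked,dead_clear
* ``count_surveys.csv`` colony_id,date,observer_id,count,method

``marked_available`` in the CSV is the raw number of pups marked; the
loader removes marked pups recorded dead before building tallies.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .abundance import (
    SubAreaResight,
    adjust_marked_for_deaths,
    chapman_estimate,
)

__all__ = [
    "REGIONS",
    "ColonyRecord",
    "ReplicateCounts",
    "SurveyRecord",
    "SchemaError",
    "ValidationError",
    "season_year_for",
    "load_registry",
    "load_surveys",
    "load_cmr_surveys",
    "load_count_surveys",
    "write_surveys",
    "validate_marking_fraction",
]

log = logging.getLogger("pupcensus")

REGIONS = frozenset(
    {
        "Central Bass Strait",
        "Bonney Upwelling",
        "Kangaroo Island upwelling",
        "Eyre Peninsula Upwelling",
        "Western Tasmanian Shelf Upwelling",
        "Sub-Antarctic surface waters",
        "East Australian Current",
    }
)

METHODS = ("CMR", "direct_count", "aerial", "incidental")


class SchemaError(ValueError):
    """A tabular input does not match its documented schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class ColonyRecord:
    colony_id: str
    name: str
    region: str
    latitude: float
    longitude: float
    area_ha: float | None = None
    height_m: float | None = None

    def __post_init__(self) -> None:
        if not self.colony_id:
            raise ValidationError("colony_id must be non-empty")
        if self.region not in REGIONS:
            raise ValidationError(
                f"unknown region {self.region!r}; allowed regions: "
                + ", ".join(sorted(REGIONS))
            )
        if not -90 <= self.latitude <= 90:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180 <= self.longitude <= 180:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class ReplicateCounts:
    """Per-observer replicate totals for a direct or aerial count."""

    totals: tuple[int, ...]
    observer_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.totals):
            raise ValidationError("replicate counts must be non-negative")
        if len(self.totals) < 2:
            raise ValidationError(
                "a valid direct count needs at least 2 replicate totals"
            )


@dataclass(frozen=True)
class SurveyRecord:
    colony_id: str
    date: _dt.date
    method: str
    payload: object  # list[SubAreaResight] | ReplicateCounts | int
    season_year: int = field(init=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; allowed: {', '.join(METHODS)}"
            )
        if self.method == "CMR":
            if not (
                isinstance(self.payload, (list, tuple))
                and all(isinstance(t, SubAreaResight) for t in self.payload)
            ):
                raise ValidationError("CMR survey payload must be SubAreaResight tallies")
        elif self.method == "incidental":
            if not isinstance(self.payload, int) or self.payload < 0:
                raise ValidationError("incidental survey payload must be a count >= 0")
        else:
            if not isinstance(self.payload, ReplicateCounts):
                raise ValidationError(
                    f"{self.method} survey payload must be ReplicateCounts"
                )
        object.__setattr__(self, "season_year", season_year_for(self.date))


def season_year_for(date: _dt.date) -> int:
    """Year of pup birth for a survey date.

    Pupping is Nov-Dec; surveys in January or February belong to the
    preceding birth year, all other months to the calendar year.
    """
    return date.year - 1 if date.month in (1, 2) else date.year


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s): {', '.join(missing)}")


def load_registry(path: str | Path) -> list[ColonyRecord]:
    """Read ``colonies.csv``; unknown regions and duplicate ids are errors."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(
        df, ["colony_id", "name", "region", "lat", "lon", "area_ha", "height_m"],
        str(path),
    )
    records: list[ColonyRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        cid = str(row["colony_id"]).strip()
        if cid in seen:
            raise ValidationError(f"duplicate colony_id {cid!r} in registry")
        seen.add(cid)
        records.append(
            ColonyRecord(
                colony_id=cid,
                name=str(row["name"]).strip(),
                region=str(row["region"]).strip(),
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                area_ha=float(row["area_ha"]) if pd.notna(row["area_ha"]) else None,
                height_m=float(row["height_m"]) if pd.notna(row["height_m"]) else None,
            )
        )
    return records


def _check_colony_ids(df: pd.DataFrame, registry: Sequence[ColonyRecord], what: str) -> None:
    known = {c.colony_id for c in registry}
    unknown = sorted(set(df["colony_id"].astype(str)) - known)
    if unknown:
        raise ValidationError(f"{what}: unknown colony_id(s): {', '.join(unknown)}")


def load_cmr_surveys(
    path: str | Path, registry: Sequence[ColonyRecord]
) -> list[SurveyRecord]:
    """Read one CMR survey per (colony, date) from a sub-area tally CSV."""
    df = pd.read_csv(path)
    _require_columns(
        df,
        [
            "colony_id", "date", "subarea_id", "marked_available",
            "total_resighted", "marked_resighted", "dead_marked", "dead_clear",
        ],
        str(path),
    )
    if df.empty:
        return []
    _check_colony_ids(df, registry, str(path))
    for col in (
        "marked_available", "total_resighted", "marked_resighted",
        "dead_marked", "dead_clear",
    ):
        if (df[col] < 0).any():
            raise ValidationError(f"{path}: negative tallies in column {col}")
    surveys: list[SurveyRecord] = []
    for (cid, date_s), grp in df.groupby(["colony_id", "date"], sort=True):
        tallies = []
        for _, row in grp.iterrows():
            m_avail = adjust_marked_for_deaths(
                int(row["marked_available"]), int(row["dead_marked"])
            )
            tallies.append(
                SubAreaResight(
                    M=m_avail,
                    n=int(row["total_resighted"]),
                    m=int(row["marked_resighted"]),
                    dead_marked=int(row["dead_marked"]),
                    dead_clear=int(row["dead_clear"]),
                    subarea_id=str(row["subarea_id"]),
                )
            )
        surveys.append(
            SurveyRecord(str(cid), _dt.date.fromisoformat(str(date_s)), "CMR", tallies)
        )
    return surveys


def load_count_surveys(
    path: str | Path, registry: Sequence[ColonyRecord]
) -> list[SurveyRecord]:
    """Read direct/aerial/incidental surveys from a replicate-count CSV."""
    df = pd.read_csv(path)
    _require_columns(df, ["colony_id", "date", "observer_id", "count", "method"], str(path))
    if df.empty:
        return []
    _check_colony_ids(df, registry, str(path))
    if (df["count"] < 0).any():
        raise ValidationError(f"{path}: negative counts")
    surveys: list[SurveyRecord] = []
    for (cid, date_s, method), grp in df.groupby(
        ["colony_id", "date", "method"], sort=True
    ):
        date = _dt.date.fromisoformat(str(date_s))
        if method == "incidental":
            payload: object = int(grp["count"].iloc[0])
        else:
            payload = ReplicateCounts(
                totals=tuple(int(c) for c in grp["count"]),
                observer_ids=tuple(str(o) for o in grp["observer_id"]),
            )
        surveys.append(SurveyRecord(str(cid), date, str(method), payload))
    return surveys


def load_surveys(
    directory: str | Path, registry: Sequence[ColonyRecord]
) -> list[SurveyRecord]:
    """Load every survey CSV present in ``directory``."""
    directory = Path(directory)
    surveys: list[SurveyRecord] = []
    cmr = directory / "cmr_surveys.csv"
    counts = directory / "count_surveys.csv"
    if cmr.exists():
        surveys.extend(load_cmr_surveys(cmr, registry))
    if counts.exists():
        surveys.extend(load_count_surveys(counts, registry))
    log.info("loaded %d surveys from %s", len(surveys), directory)
    return surveys


def write_surveys(surveys: Iterable[SurveyRecord], directory: str | Path) -> None:
    """Write surveys back out in the canonical CSV schemas (round-trippable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cmr_rows, count_rows = [], []
    for s in surveys:
        if s.method == "CMR":
            for t in s.payload:  # type: ignore[union-attr]
                cmr_rows.append(
                    {
                        "colony_id": s.colony_id,
                        "date": s.date.isoformat(),
                        "subarea_id": t.subarea_id,
                        "marked_available": t.M + t.dead_marked,
                        "total_resighted": t.n,
                        "marked_resighted": t.m,
                        "dead_marked": t.dead_marked,
                        "dead_clear": t.dead_clear,
                    }
                )
        elif s.method == "incidental":
            count_rows.append(
                {
                    "colony_id": s.colony_id,
                    "date": s.date.isoformat(),
                    "observer_id": "obs1",
                    "count": s.payload,
                    "method": s.method,
                }
            )
        else:
            rc: ReplicateCounts = s.payload  # type: ignore[assignment]
            obs = rc.observer_ids or tuple(f"obs{i+1}" for i in range(len(rc.totals)))
            for oid, c in zip(obs, rc.totals):
                count_rows.append(
                    {
                        "colony_id": s.colony_id,
                        "date": s.date.isoformat(),
                        "observer_id": oid,
                        "count": c,
                        "method": s.method,
                    }
                )
    cmr_cols = [
        "colony_id", "date", "subarea_id", "marked_available",
        "total_resighted", "marked_resighted", "dead_marked", "dead_clear",
    ]
    count_cols = ["colony_id", "date", "observer_id", "count", "method"]
    pd.DataFrame(cmr_rows, columns=cmr_cols).to_csv(
        directory / "cmr_surveys.csv", index=False
    )
    pd.DataFrame(count_rows, columns=count_cols).to_csv(
        directory / "count_surveys.csv", index=False
    )


def validate_marking_fraction(
    survey: SurveyRecord, low: float = 0.25, high: float = 0.50
) -> list[str]:
    """Check each sub-area's marked fraction against the field-protocol band.

    The fraction is M / N-hat using the sub-area Chapman estimate. Being
    outside (low, high) is a protocol deviation, not an error, so the
    result is a list of warning strings (empty when all sub-areas pass).
    """
    if survey.method != "CMR":
        raise ValueError("marking-fraction validation applies to CMR surveys only")
    import warnings as _warnings

    out: list[str] = []
    for tally in survey.payload:  # type: ignore[union-attr]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            n_hat, _ = chapman_estimate(tally)
        if n_hat <= 0:
            continue
        frac = tally.M / n_hat
        if frac <= low:
            out.append(
                f"{survey.colony_id}/{tally.subarea_id}: marked fraction "
                f"{frac:.2f} below {low:.2f}"
            )
        elif frac >= high:
            out.append(
                f"{survey.colony_id}/{tally.subarea_id}: marked fraction "
                f"{frac:.2f} above {high:.2f}"
            )
    for w in out:
        log.warning(w)
    return out
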