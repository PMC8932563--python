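"""Colony-level live-pup abundance estimation.

Two estimation routes are supported, matching standard pinniped census
practice:

* capture-mark-resight (CMR) per sub-area with the bias-corrected
  Chapman/Petersen estimator, summed over sub-areas;
* replicate direct counts by independent observers, averaged, optionally
  rescaled to the CMR scale with a site-specific conversion factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from statistics import mean as _mean, stdev as _stdev
from typing import Iterable, Sequence

from ._util import round_half_away

__all__ = [
    "SubAreaResight",
    "AbundanceEstimate",
    "LowRecaptureWarning",
    "TallyError",
    "adjust_marked_for_deaths",
    "chapman_estimate",
    "aggregate_subareas",
    "direct_count_estimate",
    "apply_count_conversion",
    "count_to_cmr_ratio",
    "mean_conversion_ratio",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class TallyError(ValueError):
    """An arithmetically impossible mark-resight tally."""


class LowRecaptureWarning(UserWarning):
    """Fewer than 5 marked pups resighted: estimate is unstable."""


@dataclass(frozen=True)
class SubAreaResight:
    """One mark-resight tally for one sub-area of a colony.

    ``M`` is the number of marked pups *available* at resight, i.e. after
    marked pups found dead have been removed (see
    :func:`adjust_marked_for_deaths`). ``n`` is the total number of pups
    counted at resight and ``m`` the marked pups among them.
    """

    M: int
    n: int
    m: int
    dead_marked: int = 0
    dead_clear: int = 0
    subarea_id: str = ""

    def __post_init__(self) -> None:
        for name in ("M", "n", "m", "dead_marked", "dead_clear"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TallyError(f"{name} must be an integer count, got {v!r}")
            if v < 0:
                raise TallyError(f"{name} must be non-negative, got {v}")
        if self.m > min(self.M, self.n):
            raise TallyError(
                f"marked resights m={self.m} exceed min(M={self.M}, n={self.n})"
            )


@dataclass(frozen=True)
class AbundanceEstimate:
    """A colony-level live pup estimate with its sampling uncertainty."""

    colony_id: str
    season_year: int
    mean: float
    variance: float
    method: str  # CMR | direct_count | aerial | converted_count
    se: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        if self.variance < 0 or math.isnan(self.variance):
            raise ValueError(f"variance must be >= 0, got {self.variance}")
        se = math.sqrt(self.variance)
        object.__setattr__(self, "se", se)
        lo = max(0.0, self.mean - Z_95 * se)
        hi = self.mean + Z_95 * se
        object.__setattr__(self, "ci95", (lo, hi))

    @property
    def reported(self) -> int:
        """Mean rounded half-away-from-zero, as presented in census tables."""
        return round_half_away(self.mean)


def adjust_marked_for_deaths(m_raw: int, dead_marked: int) -> int:
    """Remove marked pups found dead from the marked-available total."""
    if dead_marked < 0 or m_raw < 0:
        raise TallyError("counts must be non-negative")
    if dead_marked > m_raw:
        raise TallyError(
            f"dead marked pups ({dead_marked}) exceed marked total ({m_raw})"
        )
    return m_raw - dead_marked


def chapman_estimate(tally: SubAreaResight) -> tuple[float, float]:
    """Bias-corrected Petersen (Chapman) estimate for one sub-area.

    Returns ``(mean, variance)`` with

        mean = (M+1)(n+1)/(m+1) - 1
        var  = (M+1)(n+1)(M-m)(n-m) / [(m+1)^2 (m+2)]

    The estimate is defined for m = 0 but a :class:`LowRecaptureWarning`
    is emitted when m < 5.
    """
    M, n, m = tally.M, tally.n, tally.m
    if m < 5:
        warnings.warn(
            f"sub-area {tally.subarea_id or '?'}: only {m} marked pups resighted",
            LowRecaptureWarning,
            stacklevel=2,
        )
    mean = (M + 1) * (n + 1) / (m + 1) - 1
    var = (M + 1) * (n + 1) * (M - m) * (n - m) / ((m + 1) ** 2 * (m + 2))
    return mean, var


def aggregate_subareas(
    subarea_estimates: Iterable[tuple[float, float]],
    colony_id: str = "",
    season_year: int = 0,
    method: str = "CMR",
) -> AbundanceEstimate:
    """Sum sub-area means and variances into a colony estimate."""
    pairs = list(subarea_estimates)
    if not pairs:
        raise ValueError("cannot aggregate an empty list of sub-area estimates")
    total_mean = sum(p[0] for p in pairs)
    total_var = sum(p[1] for p in pairs)
    return AbundanceEstimate(colony_id, season_year, total_mean, total_var, method)


def estimate_cmr_colony(
    tallies: Sequence[SubAreaResight], colony_id: str = "", season_year: int = 0
) -> AbundanceEstimate:
    """Full CMR route: Chapman per sub-area, then aggregation."""
    return aggregate_subareas(
        (chapman_estimate(t) for t in tallies), colony_id, season_year, "CMR"
    )


def direct_count_estimate(
    totals: Sequence[int],
    colony_id: str = "",
    season_year: int = 0,
    method: str = "direct_count",
) -> AbundanceEstimate:
    """Average replicate observer totals; SE is the standard error of the mean.

    A single replicate yields an estimate with zero variance and
    ``n_replicates=1`` so downstream consumers can flag the undefined SE.
    """
    if not totals:
        raise ValueError("no replicate counts supplied")
    if any(t < 0 for t in totals):
        raise ValueError("replicate counts must be non-negative")
    k = len(totals)
    mu = _mean(totals)
    if k == 1:
        warnings.warn(
            f"{colony_id or 'colony'}: single replicate count, SE undefined",
            UserWarning,
            stacklevel=2,
        )
        var = 0.0
    else:
        sd = _stdev(totals)
        var = sd * sd / k
    return AbundanceEstimate(
        colony_id, season_year, float(mu), var, method, n_replicates=k
    )


def apply_count_conversion(
    estimate: AbundanceEstimate, factor: float
) -> AbundanceEstimate:
    """Rescale a direct/aerial count estimate to the CMR scale.

    Mean and SE are both multiplied by ``factor``; the method tag becomes
    ``converted_count``.
    """
    if factor <= 0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    if estimate.method not in ("direct_count", "aerial"):
        raise ValueError(
            f"conversion applies to direct_count/aerial estimates, not {estimate.method}"
        )
    return replace(
        estimate,
        mean=estimate.mean * factor,
        variance=estimate.variance * factor * factor,
        method="converted_count",
    )


def count_to_cmr_ratio(direct: AbundanceEstimate, cmr: AbundanceEstimate) -> float:
    """Ratio of a direct count to a paired CMR estimate (same colony/season)."""
    if direct.colony_id != cmr.colony_id or direct.season_year != cmr.season_year:
        raise ValueError("ratio requires estimates for the same colony and season")
    if cmr.mean <= 0:
        raise ZeroDivisionError("CMR mean must be positive to form a ratio")
    return direct.mean / cmr.mean


def mean_conversion_ratio(
    pairs: Iterable[tuple[AbundanceEstimate, AbundanceEstimate]]
) -> float:
    """Average count/CMR ratio over paired seasons."""
    ratios = [count_to_cmr_ratio(d, c) for d, c in pairs]
    if not ratios:
        raise ValueError("no paired estimates supplied")
    return _mean(ratios)
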