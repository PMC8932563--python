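"""Per-colony temporal trend fitting and metapopulation regressions.

Colony count series are fitted with a negative-binomial (NB2) GLM with a
log link, ``count ~ year``. The dispersion parameter theta is estimated
by alternating between the GLM slope fit at fixed theta and maximum
likelihood in theta at fixed means, in the style of classic ``glm.nb``
implementations. A moment-based starting value ("initial theta") is
reported alongside the converged value because highly inflated
dispersion estimates flag unreliable trends.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special, stats

from .census import percent_change

__all__ = [
    "CountSeries",
    "TrendFit",
    "PolyFit",
    "OLSResult",
    "fit_nb_glm",
    "classify_reliability",
    "fit_cubic",
    "ols_regression",
    "rate_vs_abundance",
    "most_recent_abundance",
    "category_change_trend",
]

P_SIGNIFICANT = 0.10
DEV_EXP_RELIABLE = 50.0
THETA_RELIABLE = 10.0

_THETA_LO, _THETA_HI = 1e-3, 1e8


@dataclass(frozen=True)
class CountSeries:
    """A colony's live-pup abundance history, one method throughout."""

    colony_id: str
    years: tuple[int, ...]
    counts: tuple[int, ...]
    method: str = "CMR"

    def __post_init__(self) -> None:
        if len(self.years) != len(self.counts):
            raise ValueError("years and counts must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")


@dataclass(frozen=True)
class TrendFit:
    colony_id: str
    n_obs: int
    df_resid: int
    beta_year: float | None
    intercept: float | None
    z: float | None
    p_value: float | None
    ci: tuple[float, float] | None
    dev_exp: float | None
    theta: float | None
    initial_theta: float | None = None
    converged: bool = False
    reliability: str = "unclassified"


@dataclass(frozen=True)
class PolyFit:
    colony_id: str
    n_obs: int
    coefficients: tuple[float, ...]  # intercept first, centred-year basis
    r_squared: float | None
    p_value: float | None  # overall F test
    cubic_term_p: float | None
    good_fit: bool
    insufficient_data: bool = False


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    slope_ci: tuple[float, float]
    n: int


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood (mean/dispersion parameterization)."""
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta)
            + y * np.log(np.maximum(mu, 1e-12))
            - (theta + y) * np.log(theta + mu)
        )
    )


def _theta_ml(y: np.ndarray, mu: np.ndarray, start: float) -> float:
    """Maximize the NB2 likelihood in theta at fixed means."""
    def nll(log_t: float) -> float:
        return -_nb_loglik(y, mu, math.exp(log_t))

    res = optimize.minimize_scalar(
        nll,
        bounds=(math.log(_THETA_LO), math.log(_THETA_HI)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(math.exp(res.x))


def _theta_moment(y: np.ndarray, mu: np.ndarray, df_resid: int) -> float:
    """Moment estimator: solve sum((y-mu)^2 / (mu + mu^2/t)) = df_resid."""
    df_resid = max(df_resid, 1)

    def g(t: float) -> float:
        return float(np.sum((y - mu) ** 2 / (mu + mu * mu / t))) - df_resid

    # g is increasing in t; if even huge theta leaves g < 0 the data are
    # under-dispersed and the Poisson limit is returned.
    if g(_THETA_HI) <= 0:
        return _THETA_HI
    if g(_THETA_LO) >= 0:
        return _THETA_LO
    return float(optimize.brentq(g, _THETA_LO, _THETA_HI, xtol=1e-6, rtol=1e-10))


def _design(years: np.ndarray, degree: int) -> np.ndarray:
    cols = [years**d for d in range(1, degree + 1)]
    return sm.add_constant(np.column_stack(cols))


def fit_nb_glm(
    series: CountSeries,
    degree: int = 1,
    theta: float | None = None,
    max_iter: int = 30,
    tol: float = 1e-6,
) -> TrendFit:
    """Fit ``count ~ year`` as an NB2 GLM with log link.

    Series with fewer than 3 observations (or fewer than 2 distinct
    years) are not fitted and come back flagged ``insufficient_data``.
    ``theta=None`` (default) estimates dispersion by alternating
    maximization; passing a value fixes it.

    ``dev_exp`` is 100 * (1 - residual deviance / null deviance) at the
    final dispersion, floored at 0.
    """
    y = np.asarray(series.counts, dtype=float)
    yrs = np.asarray(series.years, dtype=float)
    n = len(y)
    if n < 3 or len(set(series.years)) < 2:
        return TrendFit(
            colony_id=series.colony_id, n_obs=n, df_resid=max(n - 2, 0),
            beta_year=None, intercept=None, z=None, p_value=None, ci=None,
            dev_exp=None, theta=None, reliability="insufficient_data",
        )
    X = _design(yrs, degree)
    p = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            mu = np.asarray(pois.fittedvalues)
            initial_theta = _theta_moment(y, mu, n - p)
            if theta is not None:
                th = float(theta)
                fit = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=1.0 / th)
                ).fit()
                converged = True
            else:
                th = min(max(initial_theta, _THETA_LO), _THETA_HI)
                fit = pois
                converged = False
                for _ in range(max_iter):
                    fit = sm.GLM(
                        y, X, family=sm.families.NegativeBinomial(alpha=1.0 / th)
                    ).fit()
                    mu = np.asarray(fit.fittedvalues)
                    th_new = _theta_ml(y, mu, th)
                    # convergence judged on the alpha = 1/theta scale so the
                    # Poisson limit (theta at its upper bound) terminates too
                    if abs(1.0 / th_new - 1.0 / th) < 1e-8 + tol / th:
                        th = th_new
                        converged = True
                        break
                    th = th_new
                fit = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=1.0 / th)
                ).fit()
    except Exception:  # numerical failure: report what we can, unconverged
        return TrendFit(
            colony_id=series.colony_id, n_obs=n, df_resid=n - p,
            beta_year=None, intercept=None, z=None, p_value=None, ci=None,
            dev_exp=None, theta=None, initial_theta=None,
            converged=False, reliability="not_converged",
        )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta / se if se > 0 else math.inf * np.sign(beta or 1.0)
    p_val = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    # t critical value: with the short series typical here (3-12 points)
    # the plain z interval under-covers noticeably
    crit = float(stats.t.ppf(0.975, max(n - p, 1)))
    ci = (beta - crit * se, beta + crit * se)
    null_dev = float(fit.null_deviance)
    dev_exp = (
        max(0.0, 100.0 * (1.0 - float(fit.deviance) / null_dev))
        if null_dev > 0
        else 0.0
    )
    out = TrendFit(
        colony_id=series.colony_id, n_obs=n, df_resid=n - p,
        beta_year=beta, intercept=float(fit.params[0]), z=z, p_value=p_val,
        ci=ci, dev_exp=dev_exp, theta=th, initial_theta=initial_theta,
        converged=converged,
    )
    return replace(out, reliability=classify_reliability(out))


def classify_reliability(
    fit: TrendFit,
    mode: str = "caption_or",
    p_threshold: float = P_SIGNIFICANT,
    dev_exp_threshold: float = DEV_EXP_RELIABLE,
    theta_threshold: float = THETA_RELIABLE,
) -> str:
    """Classify a fitted trend's reliability.

    ``caption_or`` (default) calls a significant trend reliable when
    deviance explained exceeds the threshold OR theta is small;
    ``strict_and`` requires both. Published reliability narratives are
    internally inconsistent between the two readings, so both are
    provided and neither is privileged beyond the default.
    """
    if mode not in ("caption_or", "strict_and"):
        raise ValueError("mode must be 'caption_or' or 'strict_and'")
    if fit.reliability in ("insufficient_data", "not_converged"):
        return fit.reliability
    if fit.p_value is None or fit.dev_exp is None or fit.theta is None:
        return "not_converged"
    if fit.p_value >= p_threshold:
        return "not_significant"
    dev_ok = fit.dev_exp > dev_exp_threshold
    theta_ok = fit.theta <= theta_threshold
    ok = (dev_ok and theta_ok) if mode == "strict_and" else (dev_ok or theta_ok)
    return "reliable" if ok else "significant_unreliable"


def fit_cubic(series: CountSeries) -> PolyFit:
    """OLS cubic (counts on centred year, year^2, year^3).

    Needs at least 5 observations. ``good_fit`` requires overall-F
    p < 0.10 and r^2 > 0.5; the cubic coefficient's own t-test p-value
    is exposed separately.
    """
    y = np.asarray(series.counts, dtype=float)
    yrs = np.asarray(series.years, dtype=float)
    n = len(y)
    if n < 5:
        return PolyFit(
            colony_id=series.colony_id, n_obs=n, coefficients=(),
            r_squared=None, p_value=None, cubic_term_p=None,
            good_fit=False, insufficient_data=True,
        )
    x = yrs - yrs.mean()
    X = sm.add_constant(np.column_stack([x, x**2, x**3]))
    fit = sm.OLS(y, X).fit()
    r2 = float(fit.rsquared)
    p_overall = float(fit.f_pvalue)
    return PolyFit(
        colony_id=series.colony_id, n_obs=n,
        coefficients=tuple(float(c) for c in fit.params),
        r_squared=r2, p_value=p_overall,
        cubic_term_p=float(fit.pvalues[3]),
        good_fit=(p_overall < P_SIGNIFICANT and r2 > 0.5),
    )


def ols_regression(x: Sequence[float], y: Sequence[float]) -> OLSResult:
    """Simple least-squares regression of y on x with Wald CI on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    if np.ptp(y) == 0:
        # degenerate but well-defined response: flat line, no fit statistics
        return OLSResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            f_statistic=0.0, df=(1, n - 2), p_value=1.0,
            slope_ci=(0.0, 0.0), n=n,
        )
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    df2 = n - 2
    f = r2 / (1.0 - r2) * df2 if r2 < 1.0 else math.inf
    tcrit = stats.t.ppf(0.975, df2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return OLSResult(
        slope=float(res.slope), intercept=float(res.intercept), r_squared=r2,
        f_statistic=float(f), df=(1, df2), p_value=float(res.pvalue),
        slope_ci=ci, n=n,
    )


def most_recent_abundance(censuses: Iterable) -> dict[str, int]:
    """Latest available estimate per colony across census tables."""
    best: dict[str, tuple[int, int]] = {}
    for table in censuses:
        for row in table.rows:
            year_est = (table.season_year, row.estimate)
            if row.colony_id not in best or year_est[0] > best[row.colony_id][0]:
                best[row.colony_id] = year_est
    return {cid: est for cid, (_, est) in best.items()}


def rate_vs_abundance(
    fits: Iterable[TrendFit], abundance: Mapping[str, float]
) -> OLSResult:
    """Regress per-colony growth rates on their most recent abundance.

    Colonies without a converged slope or an abundance value are dropped.
    """
    xs, ys = [], []
    for fit in fits:
        if fit.beta_year is None:
            continue
        ab = abundance.get(fit.colony_id)
        if ab is None:
            continue
        xs.append(float(ab))
        ys.append(fit.beta_year)
    return ols_regression(xs, ys)


@dataclass(frozen=True)
class CategoryTrend:
    category: str
    fit: OLSResult | None
    n_changes: int
    n_sites: int
    warning: str | None = None


def category_change_trend(
    series_by_colony: Mapping[str, Sequence[tuple[int, float]]],
    category_by_colony: Mapping[str, str],
    zero_floor: int = 1,
) -> dict[str, CategoryTrend]:
    """Linear fits of consecutive-survey % change on year, by size category.

    Each site's consecutive-survey percent changes (zero-floored) are
    assigned to the year of the later survey and pooled by the site's
    size category; a simple OLS per category gives the category trend.
    """
    pooled: dict[str, list[tuple[int, float]]] = {}
    sites: dict[str, set[str]] = {}
    for cid, obs in series_by_colony.items():
        cat = category_by_colony.get(cid)
        if cat is None:
            continue
        obs = sorted(obs)
        for (y0, c0), (y1, c1) in zip(obs, obs[1:]):
            pc = percent_change(c0, c1, zero_floor)
            pooled.setdefault(cat, []).append((y1, pc.raw))
            sites.setdefault(cat, set()).add(cid)
    out: dict[str, CategoryTrend] = {}
    for cat, points in pooled.items():
        n_sites = len(sites[cat])
        warning = None
        if n_sites < 2:
            warning = f"category {cat!r} has a single site; df are limited"
        xs = [p[0] for p in points]
        ys = [p[1] for p in points]
        try:
            fit = ols_regression(xs, ys)
        except ValueError as exc:
            fit = None
            warning = str(exc)
        out[cat] = CategoryTrend(
            category=cat, fit=fit, n_changes=len(points),
            n_sites=n_sites, warning=warning,
        )
    return out
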