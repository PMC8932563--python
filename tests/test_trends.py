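import dataclasses
import math

import numpy as np
import pytest
import statsmodels.api as sm

from pupcensus.census import classify_size
from pupcensus.simulate import (
    MetapopColonyConfig,
    MetapopSimConfig,
    simulate_metapopulation,
)
from pupcensus.trends import (
    CountSeries,
    TrendFit,
    category_change_trend,
    classify_reliability,
    fit_cubic,
    fit_nb_glm,
    most_recent_abundance,
    ols_regression,
    rate_vs_abundance,
)


def _series(years, counts, colony="X"):
    return CountSeries(colony_id=colony, years=tuple(years), counts=tuple(counts))


class TestCountSeries:
    def test_years_strictly_increasing(self):
        with pytest.raises(ValueError):
            _series([2000, 2000], [1, 2])

    def test_counts_non_negative(self):
        with pytest.raises(ValueError):
            _series([2000, 2001], [1, -2])


class TestFitNbGlm:
    def test_constant_series_flat(self):
        fit = fit_nb_glm(_series(range(2000, 2004), [1000] * 4))
        assert fit.beta_year == pytest.approx(0, abs=1e-8)
        assert fit.dev_exp == pytest.approx(0, abs=1e-6)
        assert fit.converged

    def test_two_points_insufficient(self):
        fit = fit_nb_glm(_series([2000, 2001], [10, 20]))
        assert fit.reliability == "insufficient_data"
        assert fit.beta_year is None

    def test_repeated_single_year_insufficient(self):
        fit = fit_nb_glm(
            CountSeries("X", years=(2000, 2001, 2002), counts=(3, 3, 3))
        )
        assert fit.converged  # sanity: three distinct years do fit
        assert fit_nb_glm(_series([2000, 2001], [3, 3])).reliability == "insufficient_data"

    def test_year_shift_invariance(self):
        counts = [120, 150, 130, 210, 260, 240]
        a = fit_nb_glm(_series(range(2000, 2006), counts))
        b = fit_nb_glm(_series(range(1000, 1006), counts))
        assert a.beta_year == pytest.approx(b.beta_year, abs=1e-6)
        assert a.dev_exp == pytest.approx(b.dev_exp, abs=1e-4)

    def test_agrees_with_poisson_oracle_in_low_dispersion_limit(self, rng):
        years = np.arange(2000, 2012)
        mu = 400 * np.exp(0.08 * (years - years[0]))
        counts = rng.poisson(mu)
        fit = fit_nb_glm(_series(years, counts), theta=1e7)
        X = sm.add_constant(years.astype(float))
        oracle = sm.GLM(counts.astype(float), X, family=sm.families.Poisson()).fit()
        assert fit.beta_year == pytest.approx(float(oracle.params[1]), abs=1e-4)

    def test_estimated_theta_large_for_poisson_data(self, rng):
        years = np.arange(2000, 2012)
        counts = rng.poisson(500, size=len(years))
        fit = fit_nb_glm(_series(years, counts))
        assert fit.theta > 100  # near-Poisson data push dispersion high

    def test_dev_exp_nondecreasing_with_quadratic(self):
        series = _series(range(2000, 2010), [50, 60, 80, 120, 150, 170, 160, 140, 100, 80])
        lin = fit_nb_glm(series, degree=1, theta=10.0)
        quad = fit_nb_glm(series, degree=2, theta=10.0)
        assert quad.dev_exp >= lin.dev_exp - 1e-9
        assert 0 <= lin.dev_exp <= 100

    def test_ci_contains_beta(self):
        fit = fit_nb_glm(_series(range(2000, 2008), [100, 120, 90, 140, 160, 150, 180, 200]))
        assert fit.ci[0] <= fit.beta_year <= fit.ci[1]

    def test_recovery_with_ci_coverage(self):
        # growth 0.11/yr from 200 pups, theta 50, 6 yearly points: the
        # generative slope should fall in its own 95% CI most of the time
        hits, reps = 0, 500
        for seed in range(reps):
            cfg = MetapopSimConfig(
                colonies=(MetapopColonyConfig("c", 200, 0.11, 50.0),),
                years=tuple(range(2010, 2016)),
                seed=seed,
            )
            (series,) = simulate_metapopulation(cfg)
            fit = fit_nb_glm(series)
            if fit.converged and fit.ci[0] <= 0.11 <= fit.ci[1]:
                hits += 1
        assert hits / reps >= 0.85


class TestClassifyReliability:
    def _fit(self, p, dev_exp, theta):
        return TrendFit(
            colony_id="X", n_obs=8, df_resid=6, beta_year=0.1, intercept=0.0,
            z=1.0, p_value=p, ci=(0.0, 0.2), dev_exp=dev_exp, theta=theta,
            converged=True,
        )

    def test_not_significant(self):
        assert classify_reliability(self._fit(0.69, 1.9, 24.2)) == "not_significant"

    def test_reliable_under_both_modes(self):
        fit = self._fit(0.001, 87.9, 2.0)
        assert classify_reliability(fit, "caption_or") == "reliable"
        assert classify_reliability(fit, "strict_and") == "reliable"

    def test_mode_dependent_case(self):
        fit = self._fit(0.001, 67.6, 28.8)
        assert classify_reliability(fit, "caption_or") == "reliable"
        assert classify_reliability(fit, "strict_and") == "significant_unreliable"

    def test_unreliable_under_both(self):
        fit = self._fit(0.05, 30.0, 100.0)
        assert classify_reliability(fit, "caption_or") == "significant_unreliable"

    def test_insufficient_passthrough(self):
        fit = TrendFit(
            colony_id="X", n_obs=2, df_resid=0, beta_year=None, intercept=None,
            z=None, p_value=None, ci=None, dev_exp=None, theta=None,
            reliability="insufficient_data",
        )
        assert classify_reliability(fit) == "insufficient_data"

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            classify_reliability(self._fit(0.05, 60, 5), mode="sometimes")


class TestFitCubic:
    def test_exact_cubic_interpolates(self):
        years = np.arange(2000, 2008)
        x = years - years.mean()
        counts = np.rint(500 + 10 * x + 3 * x**2 - 0.8 * x**3).astype(int)
        fit = fit_cubic(_series(years, counts))
        # counts are rounded to integers, so interpolation is near-exact
        assert fit.r_squared == pytest.approx(1.0, abs=1e-3)
        assert fit.good_fit

    def test_too_few_points(self):
        fit = fit_cubic(_series(range(2000, 2004), [1, 2, 3, 4]))
        assert fit.insufficient_data
        assert not fit.good_fit

    def test_flat_noise_rarely_called_good(self, rng):
        # slope-0 data with noise: the cubic should rarely pass the
        # p < 0.10 and r^2 > 0.5 bar
        years = np.arange(2000, 2010)
        good = 0
        reps = 200
        for _ in range(reps):
            counts = np.maximum(rng.normal(500, 50, size=len(years)), 0).astype(int)
            good += fit_cubic(_series(years, counts)).good_fit
        assert good / reps <= 0.15

    def test_rise_then_decline_prefers_cubic(self, rng):
        # growth to a peak followed by decline: cubic r^2 should beat the
        # log-linear GLM's deviance explained
        years = np.arange(1990, 2018, 3)
        x = (years - years.min()).astype(float)
        mu = 2000 * np.exp(0.15 * x) / (1 + np.exp(0.3 * (x - 14)))
        counts = rng.poisson(mu)
        series = _series(years, counts)
        cubic = fit_cubic(series)
        glm = fit_nb_glm(series)
        assert cubic.r_squared > glm.dev_exp / 100


class TestOlsRegression:
    def test_perfect_line(self):
        x = [0.0, 1, 2, 3, 4]
        res = ols_regression(x, [2 * v + 1 for v in x])
        assert res.slope == pytest.approx(2)
        assert res.intercept == pytest.approx(1)
        assert res.r_squared == pytest.approx(1)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ols_regression([1, 1, 1], [1, 2, 3])

    def test_permuted_response_r2_near_null_expectation(self, rng):
        # under the null, E[r^2] = 1/(n-1)
        n = 10
        x = np.arange(n, dtype=float)
        y = rng.normal(size=n)
        r2s = []
        for _ in range(1000):
            r2s.append(ols_regression(x, rng.permutation(y)).r_squared)
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.03)

    def test_published_rate_vs_abundance_regression(self):
        from pupcensus import datasets

        res = rate_vs_abundance(
            datasets.published_trend_fits(),
            datasets.most_recent_published_abundance(),
        )
        assert res.n == 18
        assert res.slope < 0
        assert res.r_squared == pytest.approx(0.308, abs=0.01)


class TestRateVsAbundance:
    def _fit(self, colony, beta):
        return TrendFit(
            colony_id=colony, n_obs=8, df_resid=6, beta_year=beta, intercept=0.0,
            z=1.0, p_value=0.05, ci=(beta - 0.1, beta + 0.1), dev_exp=60.0,
            theta=5.0, converged=True,
        )

    def test_degenerate_response(self):
        fits = [self._fit(f"C{i}", 0.0) for i in range(5)]
        abundance = {f"C{i}": 100 * (i + 1) for i in range(5)}
        res = rate_vs_abundance(fits, abundance)
        assert res.slope == 0
        assert res.p_value == 1.0

    def test_negative_structure_recovered(self, rng):
        # large colonies decline, small grow
        fits, abundance = [], {}
        for i in range(12):
            ab = 100 * 2**i
            fits.append(self._fit(f"C{i}", 0.2 - 0.05 * math.log10(ab) + rng.normal(0, 0.01)))
            abundance[f"C{i}"] = ab
        res = rate_vs_abundance(fits, abundance)
        assert res.slope < 0

    def test_unfitted_colonies_dropped(self):
        fits = [self._fit("A", 0.1), self._fit("B", -0.1),
                dataclasses.replace(self._fit("C", 0.0), beta_year=None)]
        res = rate_vs_abundance(fits + [self._fit("D", 0.05)],
                                {"A": 10, "B": 500, "D": 90})
        assert res.n == 3


class TestMostRecentAbundance:
    def test_latest_census_wins(self):
        from pupcensus.abundance import AbundanceEstimate
        from pupcensus.census import assemble_census

        t13 = assemble_census(
            [AbundanceEstimate("SR", 2013, 4092.0, 0.0, "CMR"),
             AbundanceEstimate("WM", 2013, 256.0, 0.0, "CMR")], 2013
        )
        t17 = assemble_census([AbundanceEstimate("SR", 2017, 3865.0, 0.0, "CMR")], 2017)
        ab = most_recent_abundance([t13, t17])
        assert ab == {"SR": 3865, "WM": 256}


class TestCategoryChangeTrend:
    def test_constant_histories_flat(self):
        series = {"A": [(2002, 2000), (2007, 2000), (2013, 2000), (2017, 2000)],
                  "B": [(2002, 100), (2007, 100), (2013, 100), (2017, 100)]}
        cats = {"A": "large", "B": "small"}
        out = category_change_trend(series, cats)
        assert out["large"].fit.slope == 0
        assert out["small"].fit.slope == 0

    def test_signs_recovered(self, rng):
        # large sites grow early then decline (percent change per survey
        # decreasing over time); small sites accelerate upward
        series, cats = {}, {}
        years = [2002, 2007, 2013, 2017]

        def _traj(n0, rates):
            counts, n = [(years[0], n0)], n0
            for y0, y1, r in zip(years, years[1:], rates):
                n = n * math.exp(r * (y1 - y0)) * rng.uniform(0.99, 1.01)
                counts.append((y1, n))
            return counts

        for i in range(6):
            series[f"L{i}"] = _traj(5000 + 100 * i, [0.08, -0.05, -0.06])
            cats[f"L{i}"] = "large"
            series[f"S{i}"] = _traj(50 + 10 * i, [-0.02, 0.08, 0.12])
            cats[f"S{i}"] = "small"
        out = category_change_trend(series, cats)
        assert out["large"].fit.slope < 0
        assert out["small"].fit.slope >= 0

    def test_single_site_category_warns(self):
        out = category_change_trend(
            {"A": [(2002, 90), (2007, 100), (2013, 150), (2017, 120)]},
            {"A": "medium"},
        )
        assert out["medium"].n_sites == 1
        assert "single site" in out["medium"].warning

    def test_categories_follow_size_rule(self):
        assert classify_size(1752) == "large"
        assert classify_size(240) == "small"
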