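"""Distribution fitting and goodness-of-fit tests."""

import math

import numpy as np
import pytest
from scipy import stats

from proctol import (
    LogNormalParams,
    WeibullParams,
    compare_distributions,
    fit_lognormal,
    fit_weibull,
    pearson_chisq_gof,
    probability_plot_coords,
    shapiro_power_sim,
    shapiro_wilk,
)
from proctol.fit import FitError, auto_bins


class TestFitLognormal:
    def test_two_point_closed_form(self):
        params = fit_lognormal([1.0, math.e**2])
        assert params.mu == pytest.approx(1.0, rel=1e-12)
        assert params.sigma == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_degenerate_all_equal_errors(self):
        with pytest.raises(FitError):
            fit_lognormal([math.e] * 3)

    def test_nonpositive_errors(self):
        with pytest.raises(FitError):
            fit_lognormal([1.0, 0.0, 2.0])

    def test_equals_normal_fit_of_logs(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(0.5, 0.3, size=200))
        params = fit_lognormal(x)
        logs = np.log(x)
        assert params.mu == np.mean(logs)
        assert params.sigma == np.std(logs, ddof=1)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(12)
        mu, sigma, n = 0.7793, 0.195, 100_000
        x = np.exp(rng.normal(mu, sigma, size=n))
        params = fit_lognormal(x)
        assert abs(params.mu - mu) < 3 * sigma / math.sqrt(n)
        assert abs(params.sigma - sigma) < 3 * sigma / math.sqrt(2 * n)

    def test_derived_accessors(self):
        params = LogNormalParams(mu=math.log(2.18), sigma=0.1951)
        assert params.median == pytest.approx(2.18)
        assert params.cv == pytest.approx(0.197, abs=5e-4)


class TestFitWeibull:
    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(3)
        x = 3.0 * rng.weibull(2.0, size=100_000)
        params = fit_weibull(x)
        assert params.shape == pytest.approx(2.0, rel=0.02)
        assert params.scale == pytest.approx(3.0, rel=0.02)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        x = 2.0 * rng.weibull(1.5, size=500)
        base, scaled = fit_weibull(x), fit_weibull(7.0 * x)
        assert scaled.shape == pytest.approx(base.shape, rel=1e-7)
        assert scaled.scale == pytest.approx(7.0 * base.scale, rel=1e-7)

    def test_exponential_special_case(self):
        # shape MLE asymptotic SD is shape*sqrt(6)/(pi*sqrt(n))
        n = 100_000
        rng = np.random.default_rng(5)
        x = rng.exponential(2.0, size=n)
        params = fit_weibull(x)
        assert abs(params.shape - 1.0) < 3 * math.sqrt(6) / (math.pi * math.sqrt(n))

    def test_agrees_with_reference_mle(self):
        rng = np.random.default_rng(6)
        x = 2.5 * rng.weibull(1.8, size=2000)
        params = fit_weibull(x)
        c_ref, _, scale_ref = stats.weibull_min.fit(x, floc=0)
        assert params.shape == pytest.approx(c_ref, rel=1e-4)
        assert params.scale == pytest.approx(scale_ref, rel=1e-4)

    def test_degenerate_errors(self):
        with pytest.raises(FitError):
            fit_weibull([2.0, 2.0, 2.0])


class TestShapiroWilk:
    def test_matches_reference_implementation(self):
        # cross-implementation oracle at n = 50
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.standard_normal(50)
            mine = shapiro_wilk(x)
            ref = stats.shapiro(x)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-4)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-4)

    @pytest.mark.parametrize("n", [3, 4, 5, 7, 11, 12, 200, 1500])
    def test_matches_reference_across_sizes(self, n):
        x = np.random.default_rng(n).standard_normal(n)
        mine, ref = shapiro_wilk(x), stats.shapiro(x)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-4)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-4)

    def test_perfect_normal_scores_give_high_w(self):
        n = 40
        x = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        assert shapiro_wilk(x).statistic > 0.99

    def test_sample_size_range_enforced(self):
        with pytest.raises(FitError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(FitError):
            shapiro_wilk(np.arange(5001, dtype=float))

    def test_null_pvalues_approximately_uniform(self):
        # Kolmogorov distance of the p-value distribution under the null.
        rng = np.random.default_rng(21)
        pvals = np.array(
            [shapiro_wilk(rng.standard_normal(46)).p_value for _ in range(2000)]
        )
        grid = np.sort(pvals)
        ks = np.max(np.abs(grid - np.arange(1, 2001) / 2000))
        assert ks < 0.05


class TestPearsonChisq:
    def test_equal_probability_bins_by_construction(self):
        # Feed data placed at known quantiles and recompute the statistic by hand.
        params = LogNormalParams(mu=0.0, sigma=0.5)
        rng = np.random.default_rng(8)
        x = np.exp(rng.normal(0.0, 0.5, size=45))
        result = pearson_chisq_gof(x, "lognormal", params, n_bins=9)
        dist = stats.lognorm(s=0.5, scale=1.0)
        edges = dist.ppf(np.arange(1, 9) / 9)
        observed = np.histogram(x, bins=np.concatenate([[0], edges, [np.inf]]))[0]
        expected = 45 / 9
        assert result.statistic == pytest.approx(
            np.sum((observed - expected) ** 2 / expected)
        )
        assert result.df == 9 - 1 - 2

    def test_auto_bin_rule(self):
        assert auto_bins(46) == 9
        assert auto_bins(20) == 4
        assert auto_bins(1000) == 10

    def test_small_n_auto_errors(self):
        with pytest.raises(FitError):
            pearson_chisq_gof(np.ones(10) + np.arange(10), "lognormal", LogNormalParams(0, 1))

    def test_expected_below_one_errors(self):
        x = np.exp(np.random.default_rng(0).normal(size=25))
        with pytest.raises(FitError):
            pearson_chisq_gof(x, "lognormal", LogNormalParams(0, 1), n_bins=30)

    def test_type_one_error_conservative_with_refit(self):
        # Correct-model simulation with parameters re-fitted per cohort.
        rng = np.random.default_rng(9)
        n_sims, rejections = 1000, 0
        for _ in range(n_sims):
            x = np.exp(rng.normal(0.78, 0.2, size=46))
            params = fit_lognormal(x)
            if pearson_chisq_gof(x, "lognormal", params).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sims)


class TestProbabilityPlot:
    def test_exact_quantiles_give_unit_correlation(self):
        params = LogNormalParams(mu=0.5, sigma=0.3)
        n = 30
        p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
        values = stats.lognorm(s=0.3, scale=math.exp(0.5)).ppf(p)
        theo, ordered = probability_plot_coords(values, "lognormal", params)
        assert np.corrcoef(theo, ordered)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_lognormal_straighter_than_normal_for_lognormal_data(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.exp(rng.normal(0.78, 0.2, size=46))
            r2 = {}
            for label, params in {
                "lognormal": fit_lognormal(x),
                "normal": (float(np.mean(x)), float(np.std(x, ddof=1))),
            }.items():
                theo, ordered = probability_plot_coords(x, label, params)
                r2[label] = np.corrcoef(theo, ordered)[0, 1] ** 2
            wins += r2["lognormal"] > r2["normal"]
        assert wins > 10

    def test_ties_preserved(self):
        x = [1.0, 2.0, 2.0, 2.0, 3.0]
        theo, ordered = probability_plot_coords(x, "lognormal", LogNormalParams(0.5, 0.4))
        assert len(theo) == len(ordered) == 5


class TestShapiroPower:
    def test_null_rejection_matches_alpha(self):
        power, se = shapiro_power_sim(
            lambda rng, n: rng.standard_normal(n), n=30, alpha=0.10, n_sims=800, seed=1
        )
        assert abs(power - 0.10) < 3 * math.sqrt(0.10 * 0.90 / 800)

    def test_power_increases_with_n(self):
        alt = lambda rng, n: np.exp(rng.normal(0.0, 0.5, size=n))
        small, _ = shapiro_power_sim(alt, n=20, alpha=0.10, n_sims=600, seed=2)
        large, _ = shapiro_power_sim(alt, n=80, alpha=0.10, n_sims=600, seed=2)
        assert large > small

    def test_consistency_against_strong_skew(self):
        alt = lambda rng, n: np.exp(rng.normal(0.0, 1.0, size=n))
        power, _ = shapiro_power_sim(alt, n=200, alpha=0.05, n_sims=200, seed=3)
        assert power > 0.99


class TestCompareDistributions:
    def test_winner_ordering_on_study_cohort(self, study_cohort):
        from proctol import filter_by_experience

        times = filter_by_experience(study_cohort, 5).times()
        report = compare_distributions(times)
        assert report.winner == "lognormal"
        sw = {
            label: next(
                (t for t in tests if t.test_name == "shapiro_wilk"), None
            )
            for label, (params, tests) in report.entries.items()
        }
        assert sw["lognormal"].transform == "log"
        assert sw["lognormal"].statistic > sw["normal"].statistic

    def test_ordering_reproduced_on_generated_cohorts(self):
        # the study's ordering: W(log) > W(raw) and chi2 p(lognormal) > p(weibull)
        from proctol import GeneratorConfig, filter_by_experience, generate_cohort

        w_wins, chi_wins, n_seeds = 0, 0, 40
        for seed in range(n_seeds):
            cohort = filter_by_experience(generate_cohort(GeneratorConfig(seed=seed)), 5)
            report = compare_distributions(cohort.times())
            tests = {
                label: {t.test_name: t for t in entry[1]}
                for label, entry in report.entries.items()
            }
            w_wins += (
                tests["lognormal"]["shapiro_wilk"].statistic
                > tests["normal"]["shapiro_wilk"].statistic
            )
            chi_wins += (
                tests["lognormal"]["pearson_chisq"].p_value
                > tests["weibull"]["pearson_chisq"].p_value
            )
        assert w_wins > n_seeds / 2
        assert chi_wins > n_seeds / 2
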