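"""Monte Carlo engine: skewness, outlier filtering, CLT sizing, propagation."""

import numpy as np
import pytest

from silvocarbon import (
    SamplingPlan,
    clt_sample_size,
    default_distributions,
    filter_outliers,
    run_monte_carlo,
    skewness,
    summarize,
)
from silvocarbon.errors import (
    ConfigError,
    DegenerateSampleError,
    FilterCollapseError,
)
from silvocarbon.montecarlo import ParameterDistribution, point, uniform
from silvocarbon.silvoarable import PARAM_NAMES


def moment_skewness(x):
    # brute-force central-moment oracle
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    return m3 / m2**1.5


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness([1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_moment_oracle(self):
        sample = [1, 1, 1, 10]
        assert skewness(sample) == pytest.approx(moment_skewness(sample), rel=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            skewness([5, 5, 5, 5])

    def test_too_small_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            skewness([1, 2])


class TestFilterOutliers:
    def test_clean_symmetric_sample_unchanged(self):
        kept, report = filter_outliers([10, 11, 12, 13, 14])
        assert list(kept) == [10, 11, 12, 13, 14]
        assert report.method == "trimmed_mean"
        assert report.removed == []

    def test_median_tolerance_removes_far_value(self):
        sample = [10, 11, 12, 13, 140]
        # hand evaluation: median 12, raw MAD 1, band 12 +/- 3
        assert abs(moment_skewness(sample)) > 1.0
        kept, report = filter_outliers(sample)
        assert report.method == "median_mad"
        assert (report.lower, report.upper) == (9.0, 15.0)
        assert report.removed == [140.0]
        assert list(kept) == [10, 11, 12, 13]

    def test_idempotent_within_regime(self):
        sample = [10.0, 11, 12, 13, 140, 11.5, 12.5]
        kept, report = filter_outliers(sample)
        kept2, report2 = filter_outliers(kept, method=report.method)
        assert list(kept2) == list(kept)

    def test_removing_everything_raises(self):
        # skewed sample where the median band rejects >40% of the values
        sample = [10, 10.05, 10.1, 10.15, 200, 500, 5000]
        with pytest.raises(FilterCollapseError):
            filter_outliers(sample)

    def test_never_removes_more_than_forty_percent(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(50, 5, size=40)
            x[:10] = rng.uniform(500, 1000, size=10)
            try:
                kept, _ = filter_outliers(x)
            except FilterCollapseError:
                continue
            assert len(kept) >= 0.6 * len(x)

    def test_small_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            filter_outliers([1, 2, 3, 4])


class TestCLTSampleSize:
    def test_matches_normal_quantile_oracle(self):
        # n = ceil((z * sd / margin)^2) with the published pilot sd
        plan = SamplingPlan(margin_of_error=0.5, confidence=0.95, n_min=1, n_max=10**7)
        assert clt_sample_size(13.40, plan) == 2760

    def test_zero_sd_clamps_to_n_min(self):
        plan = SamplingPlan(margin_of_error=0.5, confidence=0.95)
        assert clt_sample_size(0.0, plan) == plan.n_min

    def test_quadratic_in_sd(self):
        plan = SamplingPlan(margin_of_error=0.1, confidence=0.9, n_min=1, n_max=10**9)
        n1 = clt_sample_size(7.0, plan)
        n4 = clt_sample_size(14.0, plan)
        assert n4 == pytest.approx(4 * n1, abs=3)

    def test_clamps_to_n_max(self):
        plan = SamplingPlan(margin_of_error=0.001, confidence=0.99,
                            n_min=1000, n_max=5000)
        assert clt_sample_size(100.0, plan) == 5000


class TestRunMonteCarlo:
    def test_degenerate_distributions_collapse_to_point(self):
        from silvocarbon import BiophysicalParams, silvoarable_cs

        vals = {"PH": 10.0, "DBH": 0.3, "WD": 0.6, "TD": 100.0, "SOCt": 40.0}
        dists = {k: point(k, v) for k, v in vals.items()}
        dists.update({k: point(k, 0.0) for k in PARAM_NAMES if k not in dists})
        sample = run_monte_carlo(dists, n=100, seed=1)
        expected = silvoarable_cs(BiophysicalParams(**vals)).total
        assert np.allclose(sample, expected)

    def test_uniform_soct_mean_converges_to_midpoint(self):
        dists = {k: point(k, 0.0) for k in PARAM_NAMES}
        dists["SOCt"] = uniform("SOCt", 30.0, 50.0)
        n = 40_000
        sample = run_monte_carlo(dists, n=n, seed=2)
        se = (20.0 / np.sqrt(12.0)) / np.sqrt(n)
        assert sample.mean() == pytest.approx(40.0, abs=3 * se)

    def test_same_seed_identical_samples(self):
        d = default_distributions()
        a = run_monte_carlo(d, n=500, seed=7)
        b = run_monte_carlo(d, n=500, seed=7)
        assert np.array_equal(a, b)

    def test_missing_parameters_warn_and_fix_at_zero(self):
        with pytest.warns(UserWarning, match="fixed at 0"):
            sample = run_monte_carlo({"SOCt": uniform("SOCt", 10, 20)}, n=50, seed=3)
        assert ((sample >= 10) & (sample <= 20)).all()

    def test_invalid_support_is_config_error(self):
        with pytest.raises(ConfigError):
            ParameterDistribution(name="SOCt", lower=5.0, upper=1.0)

    def test_unknown_parameter_name_rejected(self):
        with pytest.raises(ConfigError):
            ParameterDistribution(name="XX", lower=0, upper=1)

    def test_triangular_and_empirical_families(self):
        rng = np.random.default_rng(0)
        tri = ParameterDistribution(name="SOCt", family="triangular",
                                    lower=0, upper=10, mode=5)
        x = tri.sample(20_000, rng)
        assert x.mean() == pytest.approx(5.0, abs=0.15)
        emp = ParameterDistribution(name="SOCw", family="empirical",
                                    values=[1.0, 2.0, 3.0])
        y = emp.sample(1000, rng)
        assert set(np.unique(y)) == {1.0, 2.0, 3.0}


class TestSummarize:
    def test_constant_sample(self):
        s = summarize([4.2, 4.2, 4.2])
        assert (s.min, s.mean, s.median, s.max) == (4.2, 4.2, 4.2, 4.2)
        assert s.ci_lower == s.ci_upper == 4.2
        assert s.sd == 0.0

    def test_normal_sample_recovers_known_distribution(self):
        rng = np.random.default_rng(42)
        n = 200_000
        x = rng.normal(75.0, 13.4, size=n)
        s = summarize(x)
        se = 13.4 / np.sqrt(n)
        assert s.mean == pytest.approx(75.0, abs=3 * se)
        assert s.sd == pytest.approx(13.4, rel=0.01)
        # empirical percentile CI approximates mu +/- 1.96 sigma
        assert s.ci_lower == pytest.approx(75.0 - 1.96 * 13.4, abs=0.3)
        assert s.ci_upper == pytest.approx(75.0 + 1.96 * 13.4, abs=0.3)

    def test_reports_the_seven_standard_metrics(self):
        s = summarize([1.0, 2.0, 3.0])
        assert list(s.to_dict()) == [
            "Min", "Mean", "Median", "Max", "Standard Deviation",
            "95% CI Lower", "95% CI Upper",
        ]

    def test_order_invariant_min_ci_median_max(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(1.0, 0.8, size=5000)
        s = summarize(x)
        assert s.min <= s.ci_lower <= s.median <= s.ci_upper <= s.max

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateSampleError):
            summarize([1.0])

    def test_ci_narrows_with_ci_level(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=20_000)
        wide = summarize(x, ci_level=0.99)
        narrow = summarize(x, ci_level=0.5)
        assert (narrow.ci_upper - narrow.ci_lower) < (wide.ci_upper - wide.ci_lower)


class TestEngineComposition:
    def test_degenerate_distributions_give_zero_width_ci(self):
        dists = {k: point(k, 1.0) for k in PARAM_NAMES}
        s = summarize(run_monte_carlo(dists, n=200, seed=5))
        assert s.ci_lower == s.ci_upper
        assert s.mean == pytest.approx(s.ci_lower, rel=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_percentile_ci_narrows_as_n_grows(self):
        # CI half-width of the *mean's* sampling distribution shrinks; for the
        # distribution CI we instead check stabilisation: quantile estimates
        # at larger n vary less across seeds.
        dists = default_distributions()
        def spread(n):
            los = [summarize(run_monte_carlo(dists, n=n, seed=s)).ci_lower
                   for s in range(6)]
            return np.std(los)
        assert spread(8000) < spread(200)
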