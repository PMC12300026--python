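import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.power import TTestPower

from rootvol import (
    EstimationError,
    InputError,
    PairedSeries,
    agreement_report,
    bayes_linreg,
    bland_altman,
    ks_normality,
    paired_t,
    pearson,
    posthoc_power_paired_t,
    required_n_paired_t,
)


def series(a, b, la="a", lb="b"):
    return PairedSeries(la, lb, np.asarray(a, float), np.asarray(b, float))


class TestPairedSeries:
    def test_length_mismatch(self):
        with pytest.raises(InputError, match="length mismatch"):
            series([1, 2, 3], [1, 2])

    def test_missing_values_rejected(self):
        with pytest.raises(InputError, match="finite"):
            series([1, np.nan, 3], [1, 2, 3])

    def test_needs_two_pairs(self):
        with pytest.raises(InputError, match="n >= 2"):
            series([1], [2])


class TestPairedT:
    def test_identical_series_warns_nan(self):
        with pytest.warns(UserWarning, match="zero variance"):
            result = paired_t(series([1, 2, 3], [1, 2, 3]))
        assert np.isnan(result.t) and np.isnan(result.p)
        assert result.df == 2

    def test_constant_nonzero_difference_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            result = paired_t(series([1, 2, 3], [0, 1, 2]))
        assert np.isnan(result.p)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=30), rng.normal(size=30)
        result = paired_t(series(a, b))
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert result.t == pytest.approx(t_ref)
        assert result.p == pytest.approx(p_ref)
        assert result.df == 29

    def test_swap_flips_t_keeps_p(self):
        rng = np.random.default_rng(3)
        s = series(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        fwd, rev = paired_t(s), paired_t(s.swapped())
        assert rev.t == pytest.approx(-fwd.t)
        assert rev.p == pytest.approx(fwd.p)


class TestPearson:
    def test_perfect_linear(self):
        b = np.arange(1.0, 11.0)
        r, _ = pearson(series(2 * b, b))
        assert r == pytest.approx(1.0)

    def test_anti_linear(self):
        b = np.arange(1.0, 11.0)
        r, _ = pearson(series(-b, b))
        assert r == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(InputError, match="zero-variance"):
            pearson(series([1, 1, 1], [1, 2, 3]))

    def test_surface_volume_correlation_on_reference_cohort(self, cohort):
        s = series(cohort.pr_surfaces(), cohort.df["true_volume_mm3"].to_numpy())
        r, p = pearson(s)
        assert r > 0.6
        assert p < 0.01


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman(series([1, 2, 3], [1, 2, 3]))
        assert ba.bias == 0.0
        assert ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset(self):
        ba = bland_altman(series([4, 5, 6], [1, 2, 3]))
        assert ba.bias == pytest.approx(3.0)
        assert ba.loa_low == pytest.approx(3.0)
        assert ba.loa_high == pytest.approx(3.0)

    def test_plot_pairs_definition(self):
        s = series([2.0, 4.0], [1.0, 3.0])
        ba = bland_altman(s)
        assert ba.means == pytest.approx([1.5, 3.5])
        assert ba.differences == pytest.approx([1.0, 1.0])

    @given(
        diffs=st.lists(
            st.floats(min_value=-100, max_value=100), min_size=3, max_size=30
        ),
        mult=st.floats(min_value=0.5, max_value=3.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_loa_span_identity(self, diffs, mult):
        """loa_high - loa_low = 2 * multiplier * sd_diff exactly."""
        a = np.asarray(diffs, float)
        ba = bland_altman(series(a, np.zeros_like(a)), loa_multiplier=mult)
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * mult * ba.sd_diff, abs=1e-9)
        assert ba.loa_low <= ba.bias <= ba.loa_high


class TestNormality:
    def test_null_true_high_p(self):
        x = np.random.default_rng(42).normal(size=500)
        _, p = ks_normality(x)
        assert p > 0.05

    def test_exponential_rejected(self):
        x = np.random.default_rng(42).exponential(size=500)
        _, p = ks_normality(x)
        assert p < 0.05

    def test_plain_ks_less_powerful_than_lilliefors(self):
        # same skewed sample: Lilliefors p is never above the plain-KS p
        x = np.random.default_rng(7).exponential(size=100)
        _, p_lillie = ks_normality(x, method="lilliefors")
        _, p_plain = ks_normality(x, method="ks")
        assert p_lillie <= p_plain

    def test_input_validation(self):
        with pytest.raises(InputError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(InputError):
            ks_normality([1.0] * 10)
        with pytest.raises(InputError, match="method"):
            ks_normality(np.arange(10.0), method="shapiro")


class TestPower:
    def test_reported_posthoc_power(self):
        # tiny effect: power collapses to the significance level
        assert posthoc_power_paired_t(0.0008, 27, 0.05) == pytest.approx(0.05, abs=0.003)

    def test_zero_effect_gives_alpha_exactly(self):
        for alpha in (0.01, 0.05, 0.2):
            assert posthoc_power_paired_t(0.0, 27, alpha) == pytest.approx(
                alpha, abs=1e-9
            )

    def test_large_effect_near_one(self):
        assert posthoc_power_paired_t(1.0, 27, 0.05) > 0.99

    def test_monotone_in_effect_and_n(self):
        dzs = [0.1, 0.3, 0.5, 0.8]
        powers = [posthoc_power_paired_t(dz, 20) for dz in dzs]
        assert all(p2 > p1 for p1, p2 in zip(powers, powers[1:]))
        ns = [5, 10, 20, 40]
        powers_n = [posthoc_power_paired_t(0.5, n) for n in ns]
        assert all(p2 > p1 for p1, p2 in zip(powers_n, powers_n[1:]))

    def test_matches_statsmodels(self):
        for dz, n in [(0.2, 15), (0.5, 34), (0.8, 10)]:
            ref = TTestPower().power(
                effect_size=dz, nobs=n, alpha=0.05, alternative="two-sided"
            )
            assert posthoc_power_paired_t(dz, n) == pytest.approx(ref, abs=1e-6)

    def test_monte_carlo_oracle(self):
        """Simulated paired-t rejection rates match noncentral-t power within 3 SEs."""
        rng = np.random.default_rng(123)
        reps = 10_000
        for dz, n in [(0.3, 20), (0.5, 34), (0.8, 12)]:
            draws = rng.normal(loc=dz, scale=1.0, size=(reps, n))
            t = draws.mean(axis=1) / (draws.std(axis=1, ddof=1) / np.sqrt(n))
            crit = stats.t.ppf(0.975, n - 1)
            rate = np.mean(np.abs(t) > crit)
            expected = posthoc_power_paired_t(dz, n)
            se = np.sqrt(expected * (1 - expected) / reps)
            assert abs(rate - expected) < 3 * se

    def test_input_validation(self):
        with pytest.raises(InputError):
            posthoc_power_paired_t(0.5, 1)
        with pytest.raises(InputError):
            posthoc_power_paired_t(0.5, 20, alpha=1.5)


class TestRequiredN:
    def test_medium_effect_standard_answer(self):
        n = required_n_paired_t(0.5, power=0.80, alpha=0.05)
        assert n == 34
        assert posthoc_power_paired_t(0.5, 34) >= 0.80
        assert posthoc_power_paired_t(0.5, 33) < 0.80

    def test_tiny_effect_order_of_magnitude(self):
        n = required_n_paired_t(0.0008, power=0.80, alpha=0.05)
        assert 10**7 <= n <= 1.3 * 10**7

    def test_quartering_under_doubled_effect(self):
        n1 = required_n_paired_t(0.1, 0.80)
        n2 = required_n_paired_t(0.2, 0.80)
        assert n1 / n2 == pytest.approx(4.0, rel=0.05)

    def test_inverts_power(self):
        for dz in (0.3, 0.6):
            n = required_n_paired_t(dz, power=0.9)
            assert posthoc_power_paired_t(dz, n) >= 0.9 > posthoc_power_paired_t(
                dz, n - 1
            )

    def test_zero_effect_rejected(self):
        with pytest.raises(InputError, match="finite"):
            required_n_paired_t(0.0)


class TestBayesLinreg:
    def test_noiseless_recovery(self):
        x = np.linspace(1, 10, 12)
        res = bayes_linreg(x, 2 * x)
        assert res.slope_mean == pytest.approx(2.0, abs=1e-3)
        assert res.intercept_mean == pytest.approx(0.0, abs=1e-2)

    def test_vanishing_prior_matches_ols(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 50)
        y = 3.0 + 1.5 * x + rng.normal(0, 2, 50)
        res = bayes_linreg(x, y, prior_scale=(1e8, 1e8))
        slope_ols, intercept_ols = np.polyfit(x, y, 1)
        assert res.intercept_mean == pytest.approx(intercept_ols, rel=1e-6)
        assert res.slope_mean == pytest.approx(slope_ols, rel=1e-6)

    def test_parameter_recovery_coverage(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 50, 200)
        y = 100.0 + 5.0 * x + rng.normal(0, 20, 200)
        res = bayes_linreg(x, y)
        assert res.intercept_ci95[0] < 100.0 < res.intercept_ci95[1]
        assert res.slope_ci95[0] < 5.0 < res.slope_ci95[1]

    def test_reference_cohort_regression(self, cohort):
        """Frozen regression check: surface predicts volume with a positive
        slope and an intercept in the low hundreds."""
        res = bayes_linreg(
            cohort.pr_surfaces(), cohort.df["true_volume_mm3"].to_numpy()
        )
        assert res.slope_mean > 0
        assert 100 < res.intercept_mean < 350
        assert res.method == "conjugate"

    def test_constant_x_rejected(self):
        with pytest.raises(EstimationError, match="constant"):
            bayes_linreg([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_mcmc_requires_seed_and_agrees_with_conjugate(self):
        pytest.importorskip("emcee")
        pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 40)
        y = 1.0 + 2.0 * x + rng.normal(0, 1, 40)
        with pytest.raises(InputError, match="seed"):
            bayes_linreg(x, y, method="mcmc")
        res = bayes_linreg(x, y, method="mcmc", seed=9, n_samples=4000)
        ref = bayes_linreg(x, y)
        assert res.slope_mean == pytest.approx(ref.slope_mean, abs=0.1)
        assert res.rhat is not None and all(v < 1.05 for v in res.rhat.values())


class TestAgreementReport:
    def test_full_report_fields(self, cohort, applied_constant):
        applied = cohort.pr_surfaces() * applied_constant
        s = series(
            applied, cohort.df["true_volume_mm3"].to_numpy(), "pr_applied", "cbct_true"
        )
        report = agreement_report(s)
        assert report.n == 27
        assert report.df == 26
        assert not report.significant
        assert report.loa_low <= report.bias <= report.loa_high
        d = report.to_dict()
        assert d["paired_t"]["p"] == pytest.approx(report.p_value)
        assert set(d["bland_altman"]) >= {"bias", "loa_low", "loa_high"}
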