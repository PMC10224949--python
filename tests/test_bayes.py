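"""Directional Bayes-factor engine: prior rule, Welch summaries, quadrature."""

import numpy as np
import pytest
from scipy import stats

from outlierlift import (
    HypothesisPair,
    SummaryStats,
    bayes_factor,
    classify,
    combined_comparison,
    combined_scale,
    hn_scale,
    welch_summary,
)
from outlierlift.power import batch_bayes_factor
from outlierlift.reported import REPORTED_COMPARISONS


class TestPriorScale:
    def test_decrease_scale_from_strong_reference(self):
        # 99% of the half-normal mass must fall within the 89.1-point range
        assert hn_scale(89.1, "decrease") == pytest.approx(34.58, abs=0.05)

    def test_increase_scale_from_weak_reference(self):
        assert hn_scale(59.5, "increase") == pytest.approx(15.71, abs=0.05)

    def test_increase_scale_from_strong_reference(self):
        assert hn_scale(89.1, "increase") == pytest.approx(4.24, abs=0.05)

    def test_99_percent_mass_in_range(self):
        sigma = hn_scale(89.1, "decrease")
        # half-normal on the negative half-line: P(|delta| < 89.1)
        assert 2 * (stats.norm.cdf(89.1 / sigma) - 0.5) == pytest.approx(0.99, abs=1e-12)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            hn_scale(100.0, "increase")

    def test_combined_scale_is_root_mean_variance(self):
        assert combined_scale(4.24, 15.71) == pytest.approx(11.51, abs=0.01)


class TestWelchSummary:
    def test_identical_groups_zero_diff(self, rng):
        x = rng.normal(size=20)
        s = welch_summary(x, x)
        assert s.mean_diff == 0.0

    def test_equal_variances_reduce_to_pooled_df(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20) * (a.std(ddof=1) / rng.normal(5, 1, 20).std(ddof=1))
        # force exactly equal sample variances
        b = (b - b.mean()) * (a.std(ddof=1) / b.std(ddof=1)) + 5
        s = welch_summary(a, b)
        assert s.df == pytest.approx(38.0, abs=1e-9)

    def test_matches_textbook_formulas(self, rng):
        for _ in range(100):
            a = rng.normal(0, rng.uniform(1, 30), rng.integers(5, 40))
            b = rng.normal(10, rng.uniform(1, 30), rng.integers(5, 40))
            s = welch_summary(a, b)
            ra, rb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            assert s.se_diff == pytest.approx(np.sqrt(ra + rb), abs=1e-10)
            df = (ra + rb) ** 2 / (ra**2 / (len(a) - 1) + rb**2 / (len(b) - 1))
            assert s.df == pytest.approx(df, abs=1e-10)
            assert s.mean_diff == pytest.approx(b.mean() - a.mean(), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_summary([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


def _tol(reported):
    # agreement to the printed precision: 1% relative or half a printed ulp
    return max(0.01 * reported, 0.005)


class TestBayesFactor:
    def test_strongest_published_comparison(self):
        res = bayes_factor(
            SummaryStats(-45.41, 10.45, 29.25), HypothesisPair(34.58, "decrease")
        )
        assert res.b10 == pytest.approx(494.92, abs=_tol(494.92))

    def test_vanishing_prior_scale_collapses_to_null(self):
        res = bayes_factor(SummaryStats(10.0, 5.0, 30.0), HypothesisPair(1e-4, "increase"))
        assert res.b10 == pytest.approx(1.0, abs=1e-3)

    def test_matches_monte_carlo_prior_averaging(self, rng):
        s = SummaryStats(-20.0, 9.0, 28.0)
        sigma = 30.0
        res = bayes_factor(s, HypothesisPair(sigma, "decrease"))
        draws = -np.abs(rng.normal(0, sigma, 400_000))
        lik = stats.t.pdf((s.mean_diff - draws) / s.se_diff, s.df) / s.se_diff
        mc = lik.mean() / (stats.t.pdf(s.mean_diff / s.se_diff, s.df) / s.se_diff)
        mc_se = lik.std(ddof=1) / np.sqrt(len(draws)) / (
            stats.t.pdf(s.mean_diff / s.se_diff, s.df) / s.se_diff
        )
        assert abs(res.b10 - mc) < 3 * mc_se

    def test_sign_symmetry(self):
        for d in (3.0, 17.5, -42.0):
            a = bayes_factor(SummaryStats(d, 8.0, 25.0), HypothesisPair(20.0, "decrease")).b10
            b = bayes_factor(SummaryStats(-d, 8.0, 25.0), HypothesisPair(20.0, "increase")).b10
            assert a == pytest.approx(b, rel=1e-9)

    def test_monotone_in_effect_along_prior_direction(self):
        b10s = [
            bayes_factor(SummaryStats(d, 10.0, 30.0), HypothesisPair(15.0, "increase")).b10
            for d in (5.0, 10.0, 20.0, 40.0)
        ]
        assert all(x < y for x, y in zip(b10s, b10s[1:]))

    def test_batch_engine_agrees_with_adaptive_quadrature(self, rng):
        d = rng.uniform(-50, 50, 25)
        se = rng.uniform(4, 15, 25)
        df = rng.uniform(10, 80, 25)
        for sigma, direction in ((34.58, "decrease"), (15.71, "increase")):
            batch = batch_bayes_factor(d, se, df, sigma, direction)
            exact = np.array([
                bayes_factor(SummaryStats(*args), HypothesisPair(sigma, direction)).b10
                for args in zip(d, se, df)
            ])
            assert np.max(np.abs(batch - exact) / exact) < 1e-5


class TestPublishedComparisons:
    @pytest.mark.parametrize(
        "comp", REPORTED_COMPARISONS, ids=lambda c: f"{c.condition}-{c.direction}"
    )
    def test_reproduces_published_b10(self, comp):
        res = bayes_factor(comp.summary, comp.hypothesis)
        assert res.b10 == pytest.approx(comp.reported_b10, abs=_tol(comp.reported_b10))


class TestClassification:
    @pytest.mark.parametrize(
        "b10,label",
        [
            (0.25, "moderate evidence for H0"),
            (494.92, "extreme evidence for H1"),
            (1.7, "anecdotal evidence for H1"),
            (17.33, "strong evidence for H1"),
            (50.0, "very strong evidence for H1"),
            (7.8, "moderate evidence for H1"),
            (0.05, "strong evidence for H0"),
            (1.0, "no evidence"),
        ],
    )
    def test_wagenmakers_bands(self, b10, label):
        assert classify(b10) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify(0.0)


class TestCombinedComparison:
    def test_published_pooled_comparison(self, rng):
        # centering identity: pooled reference mean is exactly zero
        c1 = rng.normal(99, 25, 20)
        r1 = rng.normal(89, 25, 20)
        c2 = rng.normal(71, 30, 20)
        r2 = rng.normal(59, 30, 20)
        res, summary, hyp = combined_comparison(
            (c1, r1, 4.24), (c2, r2, 15.71), "increase"
        )
        assert hyp.sigma == pytest.approx(11.51, abs=0.01)
        pooled_ref = np.concatenate([r1 - r1.mean(), r2 - r2.mean()])
        assert pooled_ref.mean() == pytest.approx(0.0, abs=1e-12)
        assert summary.df > 20  # pooled groups of 40

    def test_published_pooled_inputs_give_published_b10(self):
        res = bayes_factor(
            SummaryStats(10.95, 7.25, 78.00), HypothesisPair(11.51, "increase")
        )
        assert res.b10 == pytest.approx(2.16, abs=_tol(2.16))
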