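"""Truncation numerics: rectangle probabilities, sequential thresholds,
Tallis first moments and univariate intensities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from breedopt import (
    TruncationProblem,
    rect_prob,
    selected_mean,
    solve_thresholds,
    univariate_intensity,
)
from breedopt.gain import nested_correlation_with_h
from breedopt.trunc_mvn import collapse_duplicate_stages
from conftest import mc_truncated_mean


def random_corr(dim, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(dim, dim + 2))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestRectProb:
    def test_univariate(self):
        assert rect_prob(np.eye(1), [0.0]) == pytest.approx(0.5, abs=1e-12)
        assert rect_prob(np.eye(1), [1.0]) == pytest.approx(norm.sf(1.0), abs=1e-12)

    def test_independent_bivariate_orthant(self):
        assert rect_prob(np.eye(2), [0.0, 0.0]) == pytest.approx(0.25, abs=1e-8)

    @pytest.mark.parametrize("rho", [-0.6, 0.3, 0.5, 0.8, 0.95])
    def test_bivariate_orthant_closed_form(self, rho):
        """P(X>0, Y>0) = 1/4 + arcsin(ρ)/(2π); ρ=0.5 gives exactly 1/3."""
        R = np.array([[1.0, rho], [rho, 1.0]])
        expected = 0.25 + math.asin(rho) / (2 * math.pi)
        assert rect_prob(R, [0.0, 0.0]) == pytest.approx(expected, abs=1e-6)

    def test_trivariate_equicorrelated_orthant(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        expected = 0.125 + 3 * math.asin(0.5) / (4 * math.pi)
        assert rect_prob(R, [0.0, 0.0, 0.0]) == pytest.approx(expected, abs=2e-6)

    def test_conservation_limits(self):
        R = random_corr(3, 1)
        assert rect_prob(R, [-np.inf] * 3) == 1.0
        assert rect_prob(R, [np.inf, -np.inf, -np.inf]) == 0.0
        # an infinite bound marginalises the variable out
        assert rect_prob(R, [0.3, -np.inf, -np.inf]) == pytest.approx(
            norm.sf(0.3), abs=1e-10
        )

    @pytest.mark.parametrize("dim,seed", [(2, 0), (3, 1), (4, 2)])
    def test_against_monte_carlo(self, dim, seed):
        R = random_corr(dim, seed)
        rng = np.random.default_rng(seed + 100)
        lo = rng.uniform(-1, 1, size=dim)
        X = rng.multivariate_normal(np.zeros(dim), R, size=400_000, method="cholesky")
        mc = np.mean(np.all(X > lo, axis=1))
        se = math.sqrt(mc * (1 - mc) / 400_000)
        assert rect_prob(R, lo) == pytest.approx(mc, abs=4 * se)

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            rect_prob(R, [0.0, 0.0])

    def test_deterministic(self):
        R = random_corr(4, 9)
        lo = [0.1, -0.4, 0.8, 0.0]
        assert rect_prob(R, lo) == rect_prob(R, lo)


class TestSolveThresholds:
    def test_single_stage_median(self):
        t = solve_thresholds(np.eye(1), [0.5])
        assert t[0] == pytest.approx(0.0, abs=1e-10)

    def test_independent_stages_are_marginal_quantiles(self):
        p = [0.3, 0.6, 0.12]
        t = solve_thresholds(np.eye(3), p)
        assert np.allclose(t, norm.isf(p), atol=1e-8)

    def test_correlated_two_stage_vs_bisection(self):
        """Independent bisection oracle for the second threshold."""
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        t = solve_thresholds(R, [0.5, 0.5])
        lo, hi = -8.0, 8.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if rect_prob(R, [t[0], mid]) > 0.25:
                lo = mid
            else:
                hi = mid
        assert t[1] == pytest.approx(0.5 * (lo + hi), abs=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_sequential_consistency(self, seed):
        """The product of the stage proportions is recovered by the joint
        probability at the solved thresholds."""
        rng = np.random.default_rng(seed)
        dim = int(rng.integers(2, 5))
        R = random_corr(dim, seed + 50)
        p = rng.uniform(0.05, 0.9, size=dim)
        t = solve_thresholds(R, p)
        assert rect_prob(R, t) == pytest.approx(np.prod(p), abs=1e-7)

    def test_unused_stage_gets_no_threshold(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        t = solve_thresholds(R, [1.0, 0.3])
        assert t[0] == -np.inf
        assert t[1] == pytest.approx(norm.isf(0.3), abs=1e-9)


class TestSelectedMean:
    def test_univariate_closed_form(self, trait):
        """One stage: z = r·φ(t)/p."""
        r, p = 0.6, 0.1
        R = np.array([[1.0, r], [r, 1.0]])
        prob = TruncationProblem.solve(R, [p])
        t = norm.isf(p)
        expected = r * norm.pdf(t) / p * trait.sigma_a
        assert selected_mean(prob, trait.sigma_a) == pytest.approx(expected, abs=1e-10)

    def test_no_selection_gives_zero(self, trait):
        R = nested_correlation_with_h([0.4, 0.7])
        prob = TruncationProblem.solve(R, [1.0, 1.0])
        assert selected_mean(prob, trait.sigma_a) == pytest.approx(0.0, abs=1e-12)

    def test_three_stage_against_monte_carlo(self, trait):
        R = nested_correlation_with_h([0.4, 0.6, 0.9])
        p = [0.2, 0.3, 0.33]
        prob = TruncationProblem.solve(R, p)
        z = selected_mean(prob, trait.sigma_a)
        mc, se = mc_truncated_mean(R, prob.thresholds, trait.sigma_a,
                                   n_draws=1_000_000, seed=2024)
        assert z == pytest.approx(mc, abs=3 * se)

    def test_more_intense_selection_raises_the_mean(self, trait):
        R = nested_correlation_with_h([0.5, 0.8])
        base = selected_mean(TruncationProblem.solve(R, [0.3, 0.4]), trait.sigma_a)
        tighter1 = selected_mean(TruncationProblem.solve(R, [0.2, 0.4]), trait.sigma_a)
        tighter2 = selected_mean(TruncationProblem.solve(R, [0.3, 0.3]), trait.sigma_a)
        assert tighter1 > base > 0.0
        assert tighter2 > base

    def test_extreme_selection_rejected(self, trait):
        R = nested_correlation_with_h([0.5])
        prob = TruncationProblem(R, np.array([40.0]), np.array([1e-13]))
        with pytest.raises(ValueError, match="extreme"):
            selected_mean(prob, trait.sigma_a)


class TestUnivariateIntensity:
    @pytest.mark.parametrize(
        "p,expected",
        [(1.0, 0.0), (0.5, norm.pdf(0.0) / 0.5), (0.01, 2.6652), (0.1, 1.7550)],
    )
    def test_closed_form_values(self, p, expected):
        assert univariate_intensity(p) == pytest.approx(expected, abs=1e-4)

    def test_invalid_proportion(self):
        with pytest.raises(ValueError):
            univariate_intensity(0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_tallis_reduces_to_univariate(self, p):
        """For a single stage the Tallis formula equals the closed form."""
        r = 0.7
        R = np.array([[1.0, r], [r, 1.0]])
        prob = TruncationProblem.solve(R, [p])
        z = selected_mean(prob, 1.0)
        assert z == pytest.approx(r * norm.pdf(norm.isf(p)) / p, abs=1e-10)


class TestCollapseDuplicates:
    def test_merges_equal_accuracies(self):
        a, p = collapse_duplicate_stages([0.5, 0.5, 0.8], [0.4, 0.5, 0.3])
        assert np.allclose(a, [0.5, 0.8])
        assert np.allclose(p, [0.2, 0.3])

    def test_leaves_distinct_stages_alone(self):
        a, p = collapse_duplicate_stages([0.4, 0.7], [0.5, 0.5])
        assert np.allclose(a, [0.4, 0.7])
        assert np.allclose(p, [0.5, 0.5])
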