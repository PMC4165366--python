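"""Freeman-Tukey transform, bias maps, and beta-binomial sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from asekit.distributions import (
    BetaBinomialSpec,
    BiasSpec,
    betabin_sample,
    bias_adjusted_mu,
    bias_invert_mu,
    ft_backtransform,
    ft_transform,
)


def ft_oracle(x: int, n: int) -> float:
    # independent evaluation of the double-arcsine formula
    return math.asin(math.sqrt(x / (n + 1))) + math.asin(math.sqrt((x + 1) / (n + 1)))


class TestFtTransform:
    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (5, 10, math.pi / 2),  # asin(sqrt(a)) + asin(sqrt(1-a)) = pi/2
            (0, 10, 0.3062773691696695),  # direct evaluation of the formula
            (15, 20, ft_oracle(15, 20)),
        ],
    )
    def test_known_values(self, x, n, expected):
        ft = ft_transform(x, n)
        assert ft.z == pytest.approx(expected, abs=1e-12)
        assert ft.variance == pytest.approx(1.0 / (n + 0.5))

    def test_symmetry_about_half_pi(self):
        for n in (7, 10, 33):
            lo = ft_transform(0, n).z
            hi = ft_transform(n, n).z
            assert lo + hi == pytest.approx(math.pi, abs=1e-12)

    def test_overdispersion_inflates_variance(self):
        base = ft_transform(5, 20).variance
        inflated = ft_transform(5, 20, rho=0.01).variance
        assert inflated == pytest.approx(base * (0.01 * 19 + 1))

    @pytest.mark.parametrize("x,n", [(11, 10), (-1, 10), (0, 0)])
    def test_domain_errors(self, x, n):
        with pytest.raises(ValueError):
            ft_transform(x, n)

    @given(n=st.integers(10, 500), x_frac=st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_x_and_near_smoothed_arcsine(self, n, x_frac):
        x = int(round(x_frac * n))
        z = ft_transform(x, n).z
        if x < n:
            assert ft_transform(x + 1, n).z > z
        smoothed = 2 * math.asin(math.sqrt((x + 0.5) / (n + 1)))
        assert abs(z - smoothed) < 0.15

    @given(n=st.integers(10, 200), x_frac=st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_backtransform_brackets_count_fraction(self, n, x_frac):
        x = int(round(x_frac * n))
        p = ft_backtransform(ft_transform(x, n).z)
        assert x / (n + 1) - 1e-9 <= p <= (x + 1) / (n + 1) + 1e-9


class TestBacktransform:
    def test_half_pi_maps_to_half(self):
        assert ft_backtransform(math.pi / 2) == pytest.approx(0.5)

    def test_exact_inverse_of_mean_map(self):
        z = 2 * math.asin(math.sqrt(0.8))
        assert ft_backtransform(z) == pytest.approx(0.8)

    def test_clipping(self):
        assert ft_backtransform(4.0) == 1.0
        assert ft_backtransform(-1.0) == 0.0


class TestBiasMaps:
    @pytest.mark.parametrize(
        "maf,f,expected",
        [
            (0.8, 0.5, 0.8),  # no-bias identity
            (0.8, 0.6, 0.48 / 0.56),  # odds-weighting, hand evaluation
            (0.5, 0.6, 0.6),  # balanced expression exposes the raw bias
        ],
    )
    def test_adjusted_mu(self, maf, f, expected):
        assert bias_adjusted_mu(maf, f) == pytest.approx(expected, abs=1e-12)

    def test_invert_mu_examples(self):
        assert bias_invert_mu(0.48 / 0.56, 0.6) == pytest.approx(0.8, abs=1e-10)
        assert bias_invert_mu(0.6, 0.6) == pytest.approx(0.5, abs=1e-12)
        assert bias_invert_mu(0.37, 0.5) == pytest.approx(0.37, abs=1e-12)

    def test_mutually_inverse_on_grid(self):
        grid = np.linspace(0.01, 0.99, 41)
        for f in (0.3, 0.5, 0.6, 0.9):
            roundtrip = bias_invert_mu(bias_adjusted_mu(grid, f), f)
            assert np.max(np.abs(roundtrip - grid)) < 1e-10

    def test_boundary_rejection(self):
        with pytest.raises(ValueError):
            bias_adjusted_mu(0.0, 0.5)
        with pytest.raises(ValueError):
            bias_invert_mu(0.5, 1.0)


class TestBetaBinomial:
    def test_spec_moments(self):
        spec = BetaBinomialSpec(n=20, mu=0.5, rho=0.004)
        assert spec.mean == pytest.approx(10.0)
        assert spec.variance == pytest.approx(0.25 * 20 * (0.004 * 19 + 1))

    def test_rho_zero_is_binomial(self):
        draws = betabin_sample(BetaBinomialSpec(n=20, mu=0.5, rho=0.0), 100_000, seed=7)
        # compare the full distribution against Binomial(20, 0.5)
        obs = np.bincount(draws, minlength=21) / len(draws)
        exp = stats.binom.pmf(np.arange(21), 20, 0.5)
        assert np.max(np.abs(obs - exp)) < 0.005

    @pytest.mark.parametrize("n,mu,rho", [(20, 0.5, 0.004), (50, 0.8, 0.02), (30, 0.3, 0.0)])
    def test_sampled_moments_match_formulas(self, n, mu, rho):
        spec = BetaBinomialSpec(n=n, mu=mu, rho=rho)
        draws = betabin_sample(spec, 100_000, seed=11)
        se_mean = math.sqrt(spec.variance / len(draws))
        assert abs(draws.mean() - spec.mean) < 4 * se_mean
        assert abs(draws.var() - spec.variance) / spec.variance < 0.05

    def test_reproducible_under_seed(self):
        spec = BetaBinomialSpec(n=20, mu=0.5, rho=0.004)
        a = betabin_sample(spec, 1000, seed=3)
        b = betabin_sample(spec, 1000, seed=3)
        assert np.array_equal(a, b)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BetaBinomialSpec(n=20, mu=1.0, rho=0.0)
        with pytest.raises(ValueError):
            BetaBinomialSpec(n=0, mu=0.5, rho=0.0)
        with pytest.raises(ValueError):
            BiasSpec(0.0)
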