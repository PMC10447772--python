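"""Sampler contracts, convergence diagnostics, and interval summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import digamma

from gunpanel import (
    PanelTable,
    PriorConfig,
    SamplerConfig,
    build_model_data,
    diagnostics,
    effective_sample_size,
    equal_tailed_interval,
    hpdi,
    sample_posterior,
    split_rhat,
    summarize,
)
from gunpanel.exceptions import ConfigurationError, InsufficientDataError


def brute_force_hpdi(draws, mass):
    """Exhaustive shortest-window oracle (independent of the implementation)."""
    s = sorted(draws)
    n = len(s)
    m = math.ceil(mass * n)
    best = None
    for i in range(n - m + 1):
        width = s[i + m - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + m - 1])
    return best[1], best[2]


class TestHpdi:
    def test_integer_ramp_window(self):
        iv = hpdi(np.arange(1, 101, dtype=float), mass=0.89)
        # 12 candidate windows of 89 draws, all width 88; lowest wins
        assert (iv.lower, iv.upper) == (1.0, 89.0)

    def test_all_equal_draws(self):
        iv = hpdi(np.full(50, 3.25))
        assert (iv.lower, iv.upper) == (3.25, 3.25)

    def test_symmetric_sample_centered_on_mean(self, rng):
        draws = rng.standard_normal(20_000)
        iv = hpdi(draws, 0.89)
        mid = 0.5 * (iv.lower + iv.upper)
        assert abs(mid - draws.mean()) < 0.05 * draws.std()

    def test_short_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            hpdi(np.arange(5.0))

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=10, max_size=500),
        st.floats(0.05, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_search(self, values, mass):
        iv = hpdi(np.array(values), mass)
        lo, hi = brute_force_hpdi(values, mass)
        assert (iv.lower, iv.upper) == (lo, hi)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=10, max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_never_wider_than_equal_tailed(self, values):
        draws = np.array(values)
        assert hpdi(draws, 0.89).width <= equal_tailed_interval(
            draws, 0.89
        ).width + 1e-12

    def test_contains_at_least_mass_fraction(self, rng):
        draws = rng.gamma(2.0, size=997)
        iv = hpdi(draws, 0.89)
        inside = np.mean((draws >= iv.lower) & (draws <= iv.upper))
        assert inside >= 0.89


class TestSplitRhat:
    def test_converged_chains_near_one(self, rng):
        draws = rng.standard_normal((2, 10_000))
        assert 1.0 - 1e-6 <= split_rhat(draws) <= 1.01

    def test_separated_chains_flagged(self, rng):
        a = 1e-6 * rng.standard_normal(100)
        b = 10.0 + 1e-6 * rng.standard_normal(100)
        value = split_rhat(np.stack([a, b]))
        # direct evaluation of the W/B formula on this input
        assert value > 1.5

    def test_formula_on_constructed_input(self):
        draws = np.array([[0.0, 1.0, 2.0, 3.0], [1.0, 3.0, 5.0, 7.0]])
        halves = [[0.0, 1.0], [2.0, 3.0], [1.0, 3.0], [5.0, 7.0]]
        W = np.mean([np.var(h, ddof=1) for h in halves])
        B = 2 * np.var([np.mean(h) for h in halves], ddof=1)
        expected = math.sqrt(((2 - 1) / 2 * W + B / 2) / W)
        assert split_rhat(draws) == pytest.approx(expected)

    def test_constant_chains_give_sentinel(self):
        assert np.isnan(split_rhat(np.ones((2, 100))))

    def test_agrees_with_arviz_split_variant(self, rng):
        import arviz as az

        draws = np.cumsum(rng.standard_normal((4, 500)), axis=1) * 0.05 + \
            rng.standard_normal((4, 500))
        expected = float(az.rhat(az.convert_to_dataset(draws),
                                 method="split")["x"])
        assert split_rhat(draws) == pytest.approx(expected, rel=1e-6)

    def test_rank_normalized_option(self, rng):
        draws = rng.lognormal(size=(2, 400))
        plain = split_rhat(draws)
        ranked = split_rhat(draws, rank_normalized=True)
        assert np.isfinite(ranked) and ranked != plain


class TestEffectiveSampleSize:
    def test_independent_draws(self, rng):
        ess = effective_sample_size(rng.standard_normal((4, 500)))
        assert 1600 <= ess <= 2400

    def test_ar1_scaling(self, rng):
        rho = 0.9
        n, m = 4, 20_000
        x = np.empty((n, m))
        x[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, m)) * math.sqrt(1 - rho**2)
        for t in range(1, m):
            x[:, t] = rho * x[:, t - 1] + innov[:, t]
        ess = effective_sample_size(x)
        expected = n * m * (1 - rho) / (1 + rho)  # closed-form AR(1) oracle
        assert expected / 2 <= ess <= expected * 2

    def test_constant_chains_give_sentinel(self):
        assert np.isnan(effective_sample_size(np.zeros((2, 50))))


class TestSummarize:
    def test_degenerate_draws(self, small_model_data):
        from gunpanel.inference import PosteriorDraws

        post = PosteriorDraws(
            draws=np.full((2, 50, 1), 0.5),
            parameter_names=["beta_gun"],
            config=SamplerConfig(n_chains=2),
        )
        s = summarize(post, "beta_gun")
        assert (s.mean, s.se) == (0.5, 0.0)
        assert (s.interval.lower, s.interval.upper) == (0.5, 0.5)

    def test_triple_matches_independent_computation(self, rng):
        from gunpanel.inference import PosteriorDraws

        draws = rng.gamma(3.0, size=(2, 500, 1))
        post = PosteriorDraws(draws=draws, parameter_names=["phi"],
                              config=SamplerConfig(n_chains=2))
        s = summarize(post, "phi", 0.89)
        flat = draws.ravel()
        assert s.mean == pytest.approx(flat.mean())
        assert s.se == pytest.approx(flat.std(ddof=1))
        lo, hi = brute_force_hpdi(flat, 0.89)
        assert (s.interval.lower, s.interval.upper) == (lo, hi)

    def test_unknown_parameter(self, rng):
        from gunpanel.inference import PosteriorDraws

        post = PosteriorDraws(draws=np.zeros((2, 20, 1)),
                              parameter_names=["phi"],
                              config=SamplerConfig(n_chains=2))
        with pytest.raises(KeyError, match="nope"):
            summarize(post, "nope")


@pytest.fixture(scope="module")
def poisson_limit_fit():
    """Single-state panel, phi pinned huge, nearly flat intercept prior."""
    rng = np.random.default_rng(0)
    pop, n = 1_000_000, 30
    lam = pop * math.exp(-10.0)
    df = pd.DataFrame(
        {
            "state": "A",
            "year": np.arange(2000, 2000 + n),
            "deaths": rng.poisson(lam, n),
            "population": pop,
            "gun_ownership": np.linspace(30, 50, n),
            "violent_crime_rate": 300.0,
            "property_crime_rate": 3000.0,
        }
    )
    panel = PanelTable(df)
    data = build_model_data(panel, "fixed_effects", adjusted=False)
    config = SamplerConfig(n_chains=2, n_warmup=500, n_samples=1000, seed=3,
                           fix_phi=1e8)
    post = sample_posterior(data, config,
                            priors=PriorConfig(fe_alpha_scale=10.0))
    return df, post


class TestSamplePosterior:
    def test_conjugate_poisson_gamma_oracle(self, poisson_limit_fit):
        df, post = poisson_limit_fit
        s = summarize(post, "alpha[A]")
        # flat-prior conjugate posterior: rate ~ Gamma(sum y, total exposure)
        S = df["deaths"].sum()
        P = df["population"].sum()
        analytic_mean = digamma(S) - math.log(P)
        ess = effective_sample_size(post.get("alpha[A]"))
        mc_se = s.se / math.sqrt(ess)
        assert abs(s.mean - analytic_mean) < 3 * mc_se + 1e-4

    def test_fixed_phi_is_constant(self, poisson_limit_fit):
        _, post = poisson_limit_fit
        assert np.ptp(post.get("phi")) == 0.0

    def test_same_seed_bitwise_identical(self, small_model_data):
        config = SamplerConfig(n_chains=2, n_warmup=100, n_samples=100, seed=9)
        p1 = sample_posterior(small_model_data, config)
        p2 = sample_posterior(small_model_data, config)
        np.testing.assert_array_equal(p1.draws, p2.draws)

    def test_different_seeds_differ(self, small_model_data):
        p1 = sample_posterior(small_model_data,
                              SamplerConfig(n_chains=2, n_warmup=50,
                                            n_samples=50, seed=1))
        p2 = sample_posterior(small_model_data,
                              SamplerConfig(n_chains=2, n_warmup=50,
                                            n_samples=50, seed=2))
        assert not np.array_equal(p1.draws, p2.draws)

    def test_draw_shapes_and_positivity(self, small_model_data):
        config = SamplerConfig(n_chains=3, n_warmup=100, n_samples=80, seed=5)
        post = sample_posterior(small_model_data, config)
        assert post.draws.shape == (
            3, 80, len(post.parameter_names)
        )
        assert np.all(np.isfinite(post.draws))
        assert np.all(post.get("tau") > 0)
        assert np.all(post.get("phi") > 0)

    def test_single_chain_rejected(self):
        with pytest.raises(ConfigurationError):
            SamplerConfig(n_chains=1)

    def test_external_backend_agrees_with_built_in(self, small_model_data):
        data = small_model_data
        built = sample_posterior(
            data, SamplerConfig(n_chains=2, n_warmup=800, n_samples=800,
                                seed=4)
        )
        ext = sample_posterior(
            data, SamplerConfig(n_chains=2, n_warmup=2000, n_samples=400,
                                seed=4, backend="external")
        )
        for name in ("beta_gun", "alpha_bar", "phi"):
            sb, se = summarize(built, name), summarize(ext, name)
            scale = max(sb.se, se.se)
            assert abs(sb.mean - se.mean) < 4 * scale / math.sqrt(10)

    def test_diagnostics_cover_all_parameters(self, small_model_data):
        post = sample_posterior(
            small_model_data,
            SamplerConfig(n_chains=2, n_warmup=200, n_samples=200, seed=6),
        )
        diag = diagnostics(post)
        assert set(diag.rhat) == set(post.parameter_names)
        finite = [v for v in diag.rhat.values() if np.isfinite(v)]
        assert all(v >= 1 - 1e-6 for v in finite)
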