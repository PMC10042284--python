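"""Hierarchical model: posterior density, sampler, summaries, pooling."""

import numpy as np
import pytest

from ricenc.bhm import (
    BHMConfig,
    BHMData,
    gelman_rubin,
    kde_mode,
    log_posterior,
    pool_posteriors,
    posterior_summary,
    run_mcmc,
    summarize_param,
)
from ricenc.exceptions import ConfigError, InsufficientDrawsError
from ricenc.synthetic import SyntheticConfig, generate_trial

SMALL = dict(n_adapt=400, n_sample=400, n_chains=2, thin=2)


def two_date_data():
    return BHMData.from_arrays(
        [
            (np.array([1.8, 2.0, 2.1, 2.2]), np.array([2.0, 2.8, 3.4, 4.0])),
            (np.array([5.1, 6.0, 6.3, 6.2]), np.array([1.2, 1.8, 2.2, 2.6])),
        ]
    )


class TestLogPosterior:
    def test_outside_prior_support_is_minus_inf(self):
        data = two_date_data()
        cfg = BHMConfig(**SMALL)
        params = {
            "a": 3.5, "b": 1.5, "sigma": 0.3,
            "plateau": np.array([2.2, 6.3]), "slope": np.array([1.0, 2.0]),
        }
        assert log_posterior(params, data, cfg) == -np.inf

    def test_single_exact_observation_standard_normal_density(self):
        # one observation at its model mean with sigma = 1
        data = BHMData.from_arrays([(np.array([4.0]), np.array([5.0]))])
        cfg = BHMConfig(**SMALL)
        params = {
            "a": 3.0, "b": 0.3, "sigma": 1.0,
            "plateau": np.array([4.0]), "slope": np.array([1.0]),
        }
        # N above critical: mu = plateau = 4.0 exactly
        assert log_posterior(params, data, cfg) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_symmetric_residual_pair_matches_scaled_single(self):
        r, sigma = 0.37, 0.8
        base = {"a": 3.0, "b": 0.3, "sigma": sigma, "slope": np.array([1.0])}
        pair = BHMData.from_arrays(
            [(np.array([5.0 + r, 5.0 - r]), np.array([4.0, 4.0]))]
        )
        single = BHMData.from_arrays(
            [(np.array([5.0 + r * np.sqrt(2)]), np.array([4.0]))]
        )
        cfg = BHMConfig(**SMALL)
        lp_pair = log_posterior({**base, "plateau": np.array([5.0])}, pair, cfg)
        lp_single = log_posterior(
            {**base, "plateau": np.array([5.0])}, single, cfg
        )
        # same total squared residual; densities differ only by the
        # per-observation normalising constant
        assert lp_pair - lp_single == pytest.approx(
            -0.5 * np.log(2 * np.pi) - np.log(sigma)
        )


class TestSampler:
    def test_same_seed_identical_draws(self):
        data = two_date_data()
        cfg = BHMConfig(seed=5, **SMALL)
        d1 = run_mcmc(data, cfg)
        d2 = run_mcmc(data, cfg)
        np.testing.assert_array_equal(d1.a, d2.a)
        np.testing.assert_array_equal(d1.b, d2.b)
        np.testing.assert_array_equal(d1.sigma, d2.sigma)

    def test_draws_respect_prior_support(self):
        cfg_t = SyntheticConfig(n_groups=1, dw_noise_sd=0.15, seed=21)
        samples, _ = generate_trial(cfg_t)
        data = BHMData.from_samples(samples)
        draws = run_mcmc(data, BHMConfig(seed=3, **SMALL))
        assert np.all((draws.a_flat > 0) & (draws.a_flat < 6))
        assert np.all((draws.b_flat > 0) & (draws.b_flat < 1))

    def test_prior_dominates_under_huge_noise(self):
        # uninformative data: posterior of a approaches Uniform(0, 6)
        rng = np.random.default_rng(0)
        data = BHMData.from_arrays(
            [
                (rng.uniform(0.1, 40.0, 12), rng.uniform(0.5, 5.0, 12)),
                (rng.uniform(0.1, 40.0, 12), rng.uniform(0.5, 5.0, 12)),
            ]
        )
        cfg = BHMConfig(
            n_adapt=3000, n_sample=3000, n_chains=2, thin=2, seed=9,
            sigma_max=500.0,
        )
        draws = run_mcmc(data, cfg)
        assert np.mean(draws.a_flat) == pytest.approx(3.0, abs=0.6)

    def test_interval_tightens_with_more_observations(self):
        widths = []
        for reps in (2, 8):
            cfg_t = SyntheticConfig(
                n_groups=1, n_replicates=reps, pop_sd_a=0, pop_sd_b=0,
                dw_noise_sd=0.15, n_noise_sd=0.05, seed=33,
            )
            samples, _ = generate_trial(cfg_t)
            draws = run_mcmc(
                BHMData.from_samples(samples),
                BHMConfig(n_adapt=2000, n_sample=2000, n_chains=2,
                          thin=2, seed=4),
            )
            s = posterior_summary(draws)
            widths.append(s.a.ci95[1] - s.a.ci95[0])
        assert widths[1] < widths[0]


class TestSummaries:
    def test_symmetric_sample_all_summaries_agree(self, rng):
        draws = rng.normal(3.5, 0.1, 100_000)
        s = summarize_param(draws)
        assert s.mean == pytest.approx(3.5, abs=0.01)
        assert s.median == pytest.approx(3.5, abs=0.01)
        assert s.mpn == pytest.approx(3.5, abs=0.01)
        assert s.ci95[0] < s.median < s.ci95[1]

    def test_mixture_mpn_tracks_dominant_mode(self, rng):
        # bimodal posterior: the KDE mode sits on the heavy component
        # while the mean is pulled between modes (MPN > median > mean)
        draws = np.concatenate(
            [rng.normal(3.6, 0.05, 70_000), rng.normal(2.6, 0.3, 30_000)]
        )
        s = summarize_param(draws)
        assert s.mpn == pytest.approx(3.6, abs=0.05)
        assert 3.2 < s.mean < 3.4
        assert s.mpn > s.median > s.mean

    def test_mode_matches_brute_force_density_grid(self, rng):
        draws = np.concatenate(
            [rng.normal(3.6, 0.05, 7000), rng.normal(2.6, 0.3, 3000)]
        )
        # independent oracle: explicit Gaussian-sum density with the
        # Silverman bandwidth h = (3n/4)^(-1/5) * sd on the same grid
        h = (3 * draws.size / 4) ** (-1 / 5) * draws.std(ddof=1)
        grid = np.linspace(draws.min(), draws.max(), 512)
        dens = np.exp(
            -0.5 * ((grid[:, None] - draws[None, :]) / h) ** 2
        ).sum(axis=1)
        step = grid[1] - grid[0]
        assert abs(kde_mode(draws) - grid[np.argmax(dens)]) <= step

    def test_constant_draws(self):
        s = summarize_param(np.full(200, 2.71))
        assert s.mean == s.median == s.mpn == 2.71

    def test_too_few_draws_rejected(self):
        with pytest.raises(InsufficientDrawsError):
            summarize_param(np.arange(50.0))


class TestPooling:
    @staticmethod
    def _draws(a_loc, b_loc, n=1000, seed=0, spread=0.01):
        rng = np.random.default_rng(seed)
        mk = lambda loc: rng.normal(loc, spread, (2, n // 2))
        from ricenc.bhm import PosteriorDraws

        return PosteriorDraws(
            a=mk(a_loc), b=mk(b_loc), sigma=mk(0.3),
            plateau=np.zeros((2, n // 2, 1)), slope=np.zeros((2, n // 2, 1)),
            acceptance={}, rhat={},
        )

    def test_equal_quota_bookkeeping(self):
        groups = [self._draws(3.0, 0.3, n=400), self._draws(4.0, 0.4, n=1000)]
        pooled = pool_posteriors(groups)
        assert pooled["a"].size == 2 * 400

    def test_two_component_mixture_mean_and_mode(self):
        groups = [
            self._draws(3.0, 0.30, seed=1),
            self._draws(4.0, 0.40, seed=2),
        ]
        pooled = pool_posteriors(groups)
        s = posterior_summary(pooled)
        assert s.a.mean == pytest.approx(3.5, abs=0.01)
        # equally dense modes: MPN must land on one of them
        assert min(abs(s.a.mpn - 3.0), abs(s.a.mpn - 4.0)) < 0.05

    def test_identical_groups_match_single_group(self):
        g = self._draws(3.4, 0.33, seed=3)
        pooled = pool_posteriors([g, g])
        s_pool = posterior_summary(pooled)
        s_one = posterior_summary(g)
        assert s_pool.a.mean == pytest.approx(s_one.a.mean, abs=1e-9)
        assert s_pool.a.median == pytest.approx(s_one.a.median, abs=1e-3)

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            pool_posteriors([self._draws(3.0, 0.3)])


def test_gelman_rubin_detects_disagreement(rng):
    same = rng.normal(0, 1, (3, 2000))
    apart = same + np.array([[0.0], [5.0], [10.0]])
    assert gelman_rubin(same) < 1.05
    assert gelman_rubin(apart) > 2.0
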