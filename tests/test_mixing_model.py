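import numpy as np
import pytest
from scipy import stats

from dietmix import mixing_model as mm

from conftest import grid_posterior_two_sources


def two_source_data(mu=(-14.0, -22.0), sigma=(0.1, 0.1), consumers=None):
    x = np.empty((0, 1)) if consumers is None else np.asarray(consumers, dtype=float).reshape(-1, 1)
    return mm.MixingData(
        consumers=x,
        source_means=np.array([[mu[0]], [mu[1]]]),
        source_sds=np.array([[sigma[0]], [sigma[1]]]),
        tdf_means=np.zeros((2, 1)),
        tdf_sds=np.zeros((2, 1)),
        isotope_names=["d13C"],
    )


class TestMixtureMoments:
    def test_single_source_degenerate(self):
        data = mm.MixingData(
            consumers=np.empty((0, 2)),
            source_means=[[-16.0, 12.0]],
            source_sds=[[0.5, 0.8]],
            tdf_means=[1.0, 1.6],
            tdf_sds=[0.4, 0.5],
        )
        m, v = mm.mixture_moments([1.0], data)
        assert m == pytest.approx([-15.0, 13.6])
        assert v == pytest.approx([0.5**2 + 0.4**2, 0.8**2 + 0.5**2])

    def test_equal_mix_is_convex_combination(self):
        data = two_source_data(mu=(-16.0, -18.0), sigma=(0.0, 0.0))
        m, v = mm.mixture_moments([0.5, 0.5], data)
        assert m[0] == pytest.approx(-17.0)
        assert v[0] == pytest.approx(0.0)

    def test_quadratic_form_variance(self):
        data = two_source_data(mu=(0.0, 4.0), sigma=(2.0, 2.0))
        m, v = mm.mixture_moments([0.25, 0.75], data)
        assert m[0] == pytest.approx(3.0)
        assert v[0] == pytest.approx((0.0625 + 0.5625) * 4.0)  # 2.5

    def test_off_simplex_rejected(self):
        data = two_source_data()
        with pytest.raises(ValueError):
            mm.mixture_moments([0.7, 0.7], data)


class TestLogPosterior:
    def test_standard_normal_at_its_mean(self):
        # one consumer exactly at the mixture mean with total sd 1
        data = two_source_data(mu=(-16.0, -18.0), sigma=(0.0, 0.0), consumers=[-17.0])
        config = mm.ModelConfig(residual_error=True, residual_sd_upper=np.array([2.0]))
        lp = mm.log_posterior(np.array([0.5, 0.5]), np.array([1.0]), data, config)
        assert lp == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_flat_prior_differences_equal_likelihood_differences(self):
        rng = np.random.default_rng(4)
        data = two_source_data(consumers=rng.normal(-17, 1, size=5))
        config = mm.ModelConfig(residual_error=False)

        def loglik(p1):
            p = np.array([p1, 1 - p1])
            m = p @ data.corrected_means
            s = np.sqrt((p**2) @ data.corrected_vars)
            return stats.norm(m, s).logpdf(data.consumers[:, 0]).sum()

        lp1 = mm.log_posterior(np.array([0.3, 0.7]), None, data, config)
        lp2 = mm.log_posterior(np.array([0.6, 0.4]), None, data, config)
        assert lp1 - lp2 == pytest.approx(loglik(0.3) - loglik(0.6))

    def test_matches_independent_density_sum(self):
        """Direct oracle: sum of scipy normal log-densities plus the
        Dirichlet log prior, on a small two-isotope fixture."""
        data = mm.MixingData(
            consumers=[[-16.5, 13.0], [-17.0, 12.5], [-16.0, 14.0]],
            source_means=[[-15.0, 15.0], [-19.0, 10.0]],
            source_sds=[[0.5, 0.6], [0.7, 0.8]],
            tdf_means=[1.0, 1.6],
            tdf_sds=[0.4, 0.5],
        )
        config = mm.ModelConfig(prior_alpha=np.array([2.0, 3.0]),
                                residual_error=True, residual_sd_upper=np.array([3.0, 3.0]))
        p = np.array([0.4, 0.6])
        xi = np.array([0.3, 0.2])
        m, v = mm.mixture_moments(p, data)
        expected = 0.0
        for j in range(2):
            expected += stats.norm(m[j], np.sqrt(v[j] + xi[j] ** 2)).logpdf(
                data.consumers[:, j]
            ).sum()
        expected += stats.dirichlet(config.prior_alpha).logpdf(p)
        got = mm.log_posterior(p, xi, data, config)
        # the implementation drops the constant Dirichlet normaliser
        const = stats.dirichlet(config.prior_alpha).logpdf([0.5, 0.5]) - float(
            (config.prior_alpha - 1) @ np.log([0.5, 0.5])
        )
        assert got + const == pytest.approx(expected)

    def test_residual_outside_prior_support(self):
        data = two_source_data(consumers=[-17.0])
        config = mm.ModelConfig(residual_error=True, residual_sd_upper=np.array([1.0]))
        assert mm.log_posterior(np.array([0.5, 0.5]), np.array([5.0]), data, config) == -np.inf


class TestRunMcmc:
    def test_identical_sources_give_symmetric_posterior(self):
        rng = np.random.default_rng(0)
        data = two_source_data(mu=(-17.0, -17.0), sigma=(0.5, 0.5),
                               consumers=rng.normal(-17, 0.5, size=30))
        post = mm.run_mcmc(data, mm.ModelConfig(burn_in=2000, samples=2000,
                                                residual_error=False, seed=10))
        means = post.flat_p.mean(axis=0)
        assert means[0] == pytest.approx(0.5, abs=0.05)

    def test_prior_recovery_without_consumers(self):
        data = two_source_data(consumers=None)
        alpha = np.array([2.0, 6.0])
        post = mm.run_mcmc(
            data,
            mm.ModelConfig(burn_in=2000, samples=4000, prior_alpha=alpha,
                           residual_error=False, seed=12),
        )
        assert post.flat_p.mean(axis=0) == pytest.approx(alpha / alpha.sum(), abs=0.03)

    def test_every_draw_on_the_simplex(self):
        rng = np.random.default_rng(2)
        data = two_source_data(consumers=rng.normal(-17, 0.5, size=10))
        post = mm.run_mcmc(data, mm.ModelConfig(burn_in=500, samples=500, seed=3))
        assert np.allclose(post.p_draws.sum(axis=2), 1.0, atol=1e-10)
        assert (post.p_draws >= 0).all()
        assert (post.xi_draws >= 0).all()

    def test_posterior_matches_grid_integration(self, tdf_fixture):
        """Mean and sd of p1 agree with brute-force 1-D quadrature of the
        same posterior (no-residual two-source toy)."""
        rng = np.random.default_rng(42)
        true_mix = 0.7 * -14.0 + 0.3 * -22.0
        sd_mix = np.sqrt(0.49 * 0.01 + 0.09 * 0.01)
        x = rng.normal(true_mix, sd_mix, size=50)
        data = two_source_data(consumers=x)
        post = mm.run_mcmc(data, mm.ModelConfig(burn_in=5000, samples=5000,
                                                residual_error=False, seed=6))
        grid_mean, grid_sd = grid_posterior_two_sources(data)
        draws = post.flat_p[:, 0]
        import arviz

        ess = max(float(arviz.ess(post.p_draws[:, :, 0])), 100.0)
        mcse_mean = draws.std(ddof=1) / np.sqrt(ess)
        mcse_sd = draws.std(ddof=1) / np.sqrt(2 * ess)
        assert abs(draws.mean() - grid_mean) < 3 * mcse_mean + 1e-4
        assert abs(draws.std(ddof=1) - grid_sd) < 3 * mcse_sd + 1e-4

    def test_uninformative_isotope_leaves_posterior_unchanged(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(-16.4, 0.3, size=40)
        data1 = two_source_data(mu=(-14.0, -22.0), sigma=(0.5, 0.5), consumers=x1)
        # add a second isotope on which both sources are identical
        x2 = np.column_stack([x1, rng.normal(10.0, 0.5, size=40)])
        data2 = mm.MixingData(
            consumers=x2,
            source_means=[[-14.0, 10.0], [-22.0, 10.0]],
            source_sds=[[0.5, 0.5], [0.5, 0.5]],
            tdf_means=[0.0, 0.0],
            tdf_sds=[0.0, 0.0],
        )
        cfg = dict(burn_in=3000, samples=4000, residual_error=False)
        m1 = mm.run_mcmc(data1, mm.ModelConfig(seed=21, **cfg)).flat_p[:, 0].mean()
        m2 = mm.run_mcmc(data2, mm.ModelConfig(seed=22, **cfg)).flat_p[:, 0].mean()
        assert abs(m1 - m2) < 0.03

    def test_single_source_rejected(self):
        data = mm.MixingData(
            consumers=np.empty((0, 1)),
            source_means=[[-16.0]],
            source_sds=[[0.5]],
            tdf_means=[0.0],
            tdf_sds=[0.0],
        )
        with pytest.raises(ValueError):
            mm.run_mcmc(data, mm.ModelConfig(burn_in=10, samples=10))


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(1)
        chain = rng.normal(size=1000)
        rhat = mm.gelman_rubin(np.stack([chain, chain, chain]))
        assert rhat == pytest.approx(1.0, abs=1e-6)

    def test_converged_chains_stay_below_1_05(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(4, 5000))
        assert mm.gelman_rubin(draws) < 1.05

    def test_shifted_chains_blow_up(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(3, 500)) + np.array([[0.0], [5.0], [10.0]])
        assert mm.gelman_rubin(draws) > 2.0

    def test_zero_variance_chains_warn_and_return_unity(self):
        with pytest.warns(RuntimeWarning):
            assert mm.gelman_rubin(np.ones((2, 100))) == 1.0

    def test_agrees_with_arviz_rank_normalised_on_good_chains(self):
        import arviz

        rng = np.random.default_rng(9)
        draws = rng.normal(size=(4, 2000))
        ours = mm.gelman_rubin(draws)
        theirs = float(arviz.rhat(draws))
        assert abs(ours - theirs) < 0.01


class TestSummarizePosterior:
    def _posterior(self, draws):
        return mm.MixingPosterior(
            p_draws=draws, xi_draws=None, acceptance={},
            source_names=[f"g{i}" for i in range(draws.shape[2])],
            isotope_names=["d13C"],
        )

    def test_constant_draws_degenerate_intervals(self):
        draws = np.full((2, 100, 2), 0.5)
        s = mm.summarize_posterior(self._posterior(draws))
        assert (s.lo95 == 0.5).all() and (s.hi95 == 0.5).all()

    def test_uniform_draws_recover_closed_form_quantiles(self):
        rng = np.random.default_rng(11)
        u = rng.uniform(size=(1, 100_000, 1))
        draws = np.concatenate([u, 1 - u], axis=2)
        s = mm.summarize_posterior(self._posterior(draws))
        assert s.lo95.iloc[0] == pytest.approx(0.025, abs=0.005)
        assert s.hi95.iloc[0] == pytest.approx(0.975, abs=0.005)

    def test_intervals_are_nested(self):
        rng = np.random.default_rng(12)
        draws = rng.dirichlet([2, 3, 4], size=(2, 500)).reshape(2, 500, 3)
        s = mm.summarize_posterior(self._posterior(draws))
        assert ((s.lo95 <= s.lo75) & (s.lo75 <= s.lo50)).all()
        assert ((s.hi50 <= s.hi75) & (s.hi75 <= s.hi95)).all()
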