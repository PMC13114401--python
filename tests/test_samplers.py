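"""Ensemble MCMC: stretch moves, pCN, FES and initialisation."""

import numpy as np
import pytest

from scatterbayes.bayes_core import PriorSpec
from scatterbayes.samplers import (
    ChainRecord,
    FESConfig,
    InitializationError,
    aies_run,
    fes_run,
    init_ensemble,
    pcn_run,
    pcn_step,
    stretch_draw,
    stretch_log_accept,
)
from scatterbayes.wave_forward import ConfigurationError


def gauss_lp(var):
    var = np.asarray(var, dtype=float)

    def lp(nu):
        nu = np.atleast_2d(nu)
        out = -0.5 * np.sum(nu**2 / var, axis=1)
        return out if out.size > 1 else float(out[0])

    return lp


class TestStretchMove:
    def test_draw_range_and_cdf(self):
        u = np.linspace(0.0, 1.0, 1001)
        z = stretch_draw(u, a=2.0)
        assert z.min() == pytest.approx(0.5)
        assert z.max() == pytest.approx(2.0)
        # inverse transform of g(z) ~ 1/sqrt(z): CDF(z) = (sqrt(az)-1)/(a-1)
        cdf = (np.sqrt(2.0 * z) - 1.0) / (2.0 - 1.0)
        np.testing.assert_allclose(cdf, u, atol=1e-12)

    def test_single_decision_closed_form(self):
        # z = 1.3, N = 4, log-ratio = -1.0: log alpha = 3 log 1.3 - 1.0
        got = stretch_log_accept(1.3, lp_prop=-2.0, lp_cur=-1.0, dim=4)
        assert got == pytest.approx(3 * np.log(1.3) - 1.0)
        assert stretch_log_accept(1.0, 5.0, 0.0, 3) == 0.0  # capped at prob 1
        # shrinking move with z < 1 is penalised by z^(N-1)
        got = stretch_log_accept(0.6, lp_prop=0.0, lp_cur=0.0, dim=5)
        assert got == pytest.approx(4 * np.log(0.6))


class TestAIES:
    def test_recovers_standard_normal_moments(self):
        chain = aies_run(gauss_lp([1.0, 1.0]), _init(16, 2, 123), 4000, seed=9, vectorized=True)
        flat = chain.flat()
        n_eff = flat.shape[0] / (2 * _act(chain))
        assert np.all(np.abs(flat.mean(0)) < 3.0 / np.sqrt(n_eff))
        assert np.all(np.abs(flat.var(0) - 1.0) < 0.1)

    def test_affine_invariance_of_acceptance(self):
        # badly scaled target vs its whitened image: same decisions at fixed
        # seed, because stretch moves are equivariant under linear maps
        scale = np.array([1.0, 100.0])
        lp_iso = gauss_lp([1.0, 1.0])

        def lp_aniso(nu):
            nu = np.atleast_2d(nu)
            out = -0.5 * np.sum((nu / scale) ** 2, axis=1)
            return out if out.size > 1 else float(out[0])

        init = _init(16, 2, 7)
        c_iso = aies_run(lp_iso, init, 2000, seed=11, vectorized=True)
        c_aniso = aies_run(lp_aniso, init * scale, 2000, seed=11, vectorized=True)
        # decisions agree up to floating round-off flips, so the rates
        # match to within a couple of points
        assert c_iso.acceptance_rate == pytest.approx(c_aniso.acceptance_rate, abs=0.02)

    def test_matches_emcee_on_shared_target(self):
        # independent reference implementation of the same stretch move
        emcee = pytest.importorskip("emcee")
        var = np.array([1.0, 25.0])
        init = _init(20, 2, 3) * np.sqrt(var)
        ours = aies_run(gauss_lp(var), init, 3000, seed=5, vectorized=True).flat()
        sampler = emcee.EnsembleSampler(20, 2, lambda nu: float(gauss_lp(var)(nu)))
        state = emcee.State(init, random_state=np.random.RandomState(5).get_state())
        sampler.run_mcmc(state, 3000)
        theirs = sampler.get_chain(discard=600, flat=True)
        for k in range(2):
            assert ours[:, k].var() == pytest.approx(var[k], rel=0.15)
            assert theirs[:, k].var() == pytest.approx(var[k], rel=0.15)

    def test_ensemble_size_rule(self):
        with pytest.raises(ConfigurationError):
            aies_run(gauss_lp([1.0] * 8), _init(16, 8, 0), 10)

    def test_infeasible_initial_walker_reported(self):
        def lp(nu):
            return -np.inf if nu[0] < 0 else 0.0

        init = _init(8, 1, 1)
        init[3, 0] = -5.0
        with pytest.raises(InitializationError, match="3"):
            aies_run(lp, init, 10)

    def test_seed_determinism(self):
        a = aies_run(gauss_lp([1.0, 1.0]), _init(10, 2, 2), 200, seed=77)
        b = aies_run(gauss_lp([1.0, 1.0]), _init(10, 2, 2), 200, seed=77)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.log_posts, b.log_posts)

    def test_stationary_distribution_on_1d_target(self):
        # long-run histogram matches the target within total variation 0.05
        chain = aies_run(gauss_lp([1.0]), _init(8, 1, 21), 20_000, seed=13, vectorized=True)
        x = chain.flat().ravel()
        edges = np.linspace(-4, 4, 33)
        emp, _ = np.histogram(x, bins=edges)
        emp = emp / x.size
        from scipy.stats import norm

        target = np.diff(norm.cdf(edges))
        target /= target.sum()
        assert 0.5 * np.abs(emp - target).sum() < 0.05


class TestPCN:
    def test_beta_one_is_independent_prior_draw(self, rng):
        x = rng.normal(size=(5, 3))
        xi = rng.normal(size=(5, 3))
        np.testing.assert_allclose(pcn_step(x, xi, beta=1.0), xi, atol=1e-12)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ConfigurationError):
            pcn_step(np.zeros(2), np.zeros(2), beta=0.0)
        with pytest.raises(ConfigurationError):
            pcn_run(lambda nu: 0.0, np.ones(2), np.zeros((4, 2)), 10, beta=1.5)

    def test_constant_likelihood_accepts_everything(self):
        std = np.array([2.0, 1.0, 0.5])
        chain = pcn_run(lambda nu: 0.0, std, np.zeros((6, 3)), 400, beta=0.5, seed=8)
        assert chain.acceptance_rate == 1.0

    def test_prior_invariance_of_marginal_variance(self):
        std = np.sqrt(np.array([4.0, 1.0, 0.25]))
        chain = pcn_run(lambda nu: 0.0, std, np.zeros((16, 3)), 3000, beta=0.9, seed=8)
        emp = chain.flat().var(axis=0)
        np.testing.assert_allclose(emp, std**2, rtol=0.05)

    def test_seed_determinism(self):
        args = (lambda nu: 0.1 * float(nu @ nu), np.ones(4), np.zeros((5, 4)), 100)
        a = pcn_run(*args, beta=0.3, seed=1)
        b = pcn_run(*args, beta=0.3, seed=1)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestFES:
    def phi(self, nu):
        return 0.5 * float(np.sum(nu)) ** 2

    def test_reduces_to_pcn_without_low_modes(self):
        std = np.linspace(2.0, 0.5, 6)
        init = np.zeros((8, 6))
        pcn = pcn_run(self.phi, std, init, 300, beta=0.4, seed=42)
        fes = fes_run(self.phi, std, FESConfig(n_low=0, beta=0.4), init, 300, seed=42)
        np.testing.assert_array_equal(pcn.samples, fes.samples)
        np.testing.assert_array_equal(pcn.log_posts, fes.log_posts)
        np.testing.assert_array_equal(pcn.accepted, fes.accepted)

    def test_gaussian_target_variance_recovery(self):
        # prior N(0, diag(std^2)) with a rank-one likelihood contraction:
        # exact posterior covariance available in closed form
        std = np.array([1.5, 1.0, 0.8, 0.6, 0.5, 0.4, 0.3, 0.25])
        w = np.ones(8)
        sigma2_like = 4.0

        def phi(nu):
            return 0.5 * float(nu @ w) ** 2 / sigma2_like

        C = np.diag(std**2)
        post_cov = C - (C @ np.outer(w, w) @ C) / (sigma2_like + w @ C @ w)
        init = np.random.default_rng(0).normal(size=(40, 8)) * std
        chain = fes_run(phi, std, FESConfig(n_low=2, beta=0.7), init, 6000, seed=3)
        emp = np.cov(chain.flat().T)
        assert np.abs(np.diag(emp) / np.diag(post_cov) - 1.0).max() < 0.1

    def test_low_block_exceeding_dimension_rejected(self):
        with pytest.raises(ConfigurationError):
            fes_run(self.phi, np.ones(4), FESConfig(n_low=5), np.zeros((24, 4)), 10)

    def test_walker_rule_for_low_block(self):
        with pytest.raises(ConfigurationError):
            fes_run(self.phi, np.ones(6), FESConfig(n_low=3), np.zeros((6, 6)), 10)

    def test_seed_determinism(self):
        std = np.linspace(1.0, 0.2, 5)
        init = _init(12, 5, 9) * std
        a = fes_run(self.phi, std, FESConfig(n_low=2, beta=0.5), init, 150, seed=6)
        b = fes_run(self.phi, std, FESConfig(n_low=2, beta=0.5), init, 150, seed=6)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_degenerate_ensemble_span_warned(self):
        with pytest.warns(UserWarning, match="zero spread"):
            fes_run(self.phi, np.ones(4), FESConfig(n_low=2), np.zeros((12, 4)), 5)


class TestInitEnsemble:
    def test_unconstrained_prior_returns_raw_draws(self):
        prior = PriorSpec(np.zeros(3), np.ones(3))
        ens = init_ensemble(prior, 9, seed=4)
        np.testing.assert_array_equal(ens, prior.sample(np.random.default_rng(4), 9))

    def test_rejection_resampling_respects_constraint(self):
        prior = PriorSpec(np.zeros(2), np.ones(2), constraint=lambda nu: nu[0] > 0)
        ens = init_ensemble(prior, 20, seed=0)
        assert ens.shape == (20, 2)
        assert np.all(ens[:, 0] > 0)

    def test_degenerate_constraint_fails_with_diagnostics(self):
        prior = PriorSpec(np.zeros(2), np.ones(2), constraint=lambda nu: nu[0] > 50.0)
        with pytest.raises(InitializationError, match="prior"):
            init_ensemble(prior, 4, seed=0, max_tries=5)


class TestChainRecord:
    def make(self):
        samples = np.arange(24, dtype=float).reshape(3, 4, 2)
        lps = np.array([[0.0, 1.0, 0.5, 0.2], [2.0, 0.1, 0.3, 0.4], [0.9, 2.0, 0.8, 0.1]])
        return ChainRecord(samples, lps, np.ones((2, 4), dtype=bool))

    def test_map_sample_earliest_tie(self):
        chain = self.make()
        nu, lp = chain.map_sample()
        assert lp == 2.0
        np.testing.assert_array_equal(nu, chain.samples[1, 0])  # step 1 beats step 2

    def test_flat_respects_burn_in(self):
        chain = self.make()
        assert chain.flat(burn_in=1).shape == (8, 2)
        with pytest.raises(ConfigurationError):
            chain.burn_in_steps(5)

    def test_acceptance_rate(self):
        assert self.make().acceptance_rate == 1.0


def _init(W, N, seed):
    return np.random.default_rng(seed).normal(size=(W, N))


def _act(chain, max_lag=200):
    """Crude integrated autocorrelation time of the first coordinate."""
    x = chain.samples[:, :, 0].mean(axis=1)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[x.size - 1 :]
    acf /= acf[0]
    tau = 1.0
    for k in range(1, min(max_lag, x.size)):
        if acf[k] < 0.05:
            break
        tau += 2.0 * acf[k]
    return tau
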