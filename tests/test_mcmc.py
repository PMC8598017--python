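"""Sampler tests: posterior evaluation, Metropolis kernel, tuning, diagnostics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from humpback_assess import (
    AbundanceObs,
    CatchSeries,
    Dataset,
    GrowthObs,
    MCMCConfig,
    PriorSpec,
    ProcessParams,
    backproject_K,
    gelman_rubin,
    log_posterior,
    project,
    run_chain,
    total_loglik,
)
from humpback_assess.mcmc import proposal_scale_update, run_mcmc


@pytest.fixture(scope="module")
def flat_setup(zero_catches):
    """No observations and no catches: the posterior is the uniform prior box."""
    return Dataset(catches=zero_catches), PriorSpec()


class TestLogPosterior:
    def test_outside_prior_box_is_neg_inf(self, flat_setup):
        data, spec = flat_setup
        assert log_posterior(
            ProcessParams(r_max=0.2, n_ref=5000.0), data, spec
        ) == -np.inf
        assert log_posterior(
            ProcessParams(r_max=0.05, n_ref=30_000.0), data, spec
        ) == -np.inf

    def test_flat_prior_inside_box_is_zero(self, flat_setup):
        data, spec = flat_setup
        assert log_posterior(
            ProcessParams(r_max=0.05, n_ref=5000.0), data, spec
        ) == 0.0

    def test_equals_total_loglik_component_oracle(self, zero_catches):
        spec = PriorSpec()
        params = ProcessParams(r_max=0.05, n_ref=9_500.0)
        data = Dataset(
            catches=zero_catches,
            abundance_obs=(AbundanceObs(2005, 9_000.0, 0.17),),
            growth_obs=(GrowthObs(1995, 1998, 0.01, 0.446),),
        )
        K = backproject_K(params.r_max, params.n_ref, zero_catches)
        traj = project(params, K, zero_catches, end_year=2040)
        assert log_posterior(params, data, spec) == pytest.approx(
            total_loglik(data, traj), rel=1e-10
        )


class TestRunChain:
    def test_missing_covariance_raises(self, flat_setup):
        data, spec = flat_setup
        with pytest.raises(ValueError, match="covariance"):
            run_chain(data, spec, MCMCConfig(seed=1))

    def test_bad_start_value_raises(self, flat_setup):
        data, spec = flat_setup
        cfg = MCMCConfig(seed=1, start_values=((50_000.0, 0.01),) * 3,
                         proposal_cov=np.diag([1e4, 1e-4]))
        with pytest.raises(ValueError, match="zero posterior"):
            run_chain(data, spec, cfg)

    def test_fixed_seed_bit_identical(self, flat_setup):
        data, spec = flat_setup
        cfg = MCMCConfig(n_burn=100, n_iter=500, thin=5, seed=13,
                         proposal_cov=np.diag([2e6, 1e-3]))
        d1, n1, a1 = run_chain(data, spec, cfg)
        d2, n2, a2 = run_chain(data, spec, cfg)
        assert np.array_equal(d1, d2)
        assert np.array_equal(n1, n2)
        assert a1 == a2

    def test_flat_target_recovers_uniform_prior(self, flat_setup):
        """With no data the retained draws must match the uniform priors
        (KS at alpha = 0.01, draws subsampled to reduce autocorrelation)."""
        data, spec = flat_setup
        cfg = MCMCConfig(n_burn=2_000, n_iter=40_000, thin=20, seed=5,
                         proposal_cov=np.diag([9e6, 2.5e-3]))
        draws, _, acc = run_chain(data, spec, cfg)
        assert 0.05 < acc < 0.95
        sub = draws[::2]
        ks_n = stats.kstest(sub[:, 0], stats.uniform(500.0, 21_500.0).cdf)
        ks_r = stats.kstest(sub[:, 1], stats.uniform(0.0, 0.106).cdf)
        assert ks_n.pvalue > 0.01
        assert ks_r.pvalue > 0.01

    def test_analytic_bivariate_normal_target(self, flat_setup):
        """Substituting a known bivariate normal for the posterior, the
        sampler's moments match the analytic ones within MC error."""
        data, spec = flat_setup
        mu = np.array([3.0, -2.0])
        sd = np.array([2.0, 0.5])
        rho = 0.3
        cov = np.array([
            [sd[0] ** 2, rho * sd[0] * sd[1]],
            [rho * sd[0] * sd[1], sd[1] ** 2],
        ])
        prec = np.linalg.inv(cov)

        def log_target(x, y):
            d = np.array([x, y]) - mu
            return -0.5 * d @ prec @ d

        cfg = MCMCConfig(
            n_burn=2_000, n_iter=60_000, thin=10, seed=3,
            start_values=((3.0, -2.0),) * 3,
            proposal_cov=(2.4**2 / 2) * cov,
        )
        draws, _, acc = run_chain(data, spec, cfg, log_target=log_target)
        n = len(draws)
        # ~weakly correlated retained draws; allow 3x the iid standard error
        # inflated by an autocorrelation factor of 4
        for j in range(2):
            se = sd[j] / math.sqrt(n) * 2.0
            assert draws[:, j].mean() == pytest.approx(mu[j], abs=3 * se)
            assert draws[:, j].std() == pytest.approx(sd[j], rel=0.1)
        r_emp = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert r_emp == pytest.approx(rho, abs=0.1)

    def test_detailed_balance_two_state(self, flat_setup):
        """Two-bin target: transition frequencies of the chain match a direct
        Monte-Carlo simulation of one Metropolis step from each bin."""
        data, spec = flat_setup
        lo_w, hi_w = 1.0, 3.0  # unnormalized bin weights on [-1,0) and [0,1)

        def log_target(x, y):
            if -1.0 <= x < 0.0:
                return math.log(lo_w)
            if 0.0 <= x < 1.0:
                return math.log(hi_w)
            return -math.inf

        prop_sd = 0.8
        cfg = MCMCConfig(
            n_burn=1_000, n_iter=40_000, thin=1, seed=21,
            start_values=((0.5, 0.0),) * 3,
            proposal_cov=np.diag([prop_sd**2, 1.0]),
        )
        draws, _, _ = run_chain(data, spec, cfg, log_target=log_target)
        x = draws[:, 0]
        in_a = x < 0.0
        # empirical transition frequency A -> B
        trans_ab = np.mean(~in_a[1:][in_a[:-1]])
        trans_ba = np.mean(in_a[1:][~in_a[:-1]])

        rng = np.random.default_rng(77)
        m = 200_000
        # within a bin the stationary density is uniform, so start uniform
        for start_lo, p_emp in ((True, trans_ab), (False, trans_ba)):
            x0 = rng.uniform(-1.0, 0.0, m) if start_lo else rng.uniform(0, 1, m)
            xp = x0 + rng.normal(0.0, prop_sd, m)
            lp0 = np.where(x0 < 0, math.log(lo_w), math.log(hi_w))
            lpp = np.full(m, -np.inf)
            inside = (xp >= -1.0) & (xp < 1.0)
            lpp[inside] = np.where(xp[inside] < 0, math.log(lo_w),
                                   math.log(hi_w))
            accept = np.log(rng.uniform(size=m)) < lpp - lp0
            xn = np.where(accept, xp, x0)
            p_oracle = np.mean(xn >= 0) if start_lo else np.mean(xn < 0)
            se = math.sqrt(p_oracle * (1 - p_oracle) / (len(x) * 0.25))
            assert p_emp == pytest.approx(p_oracle, abs=4 * se + 0.01)


class TestProposalTuning:
    def test_scale_update_rule_scripted(self):
        """Documented rule: halve when rejection-heavy, double when
        acceptance-heavy, hold inside the band."""
        assert proposal_scale_update(1.0, 0.05) == 0.5
        assert proposal_scale_update(2.0, 0.19) == 1.0
        assert proposal_scale_update(1.0, 0.85) == 2.0
        assert proposal_scale_update(4.0, 0.41) == 8.0
        assert proposal_scale_update(1.0, 0.30) == 1.0
        assert proposal_scale_update(1.0, 0.2) == 1.0  # band edges inclusive
        assert proposal_scale_update(1.0, 0.4) == 1.0

    def test_repeated_rejection_shrinks_scale(self):
        scale = 64.0
        for _ in range(5):
            scale = proposal_scale_update(scale, 0.01)
        assert scale == 2.0


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        chain = np.random.default_rng(0).normal(size=5_000)
        assert gelman_rubin([chain, chain, chain]) == pytest.approx(1.0,
                                                                    abs=1e-3)

    def test_same_distribution_converges(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) < 1.05

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, 2_000)
        b = rng.normal(100.0, 1.0, 2_000)
        assert gelman_rubin([a, b]) > 10.0

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.zeros(100), np.zeros(101)])

    def test_short_chains_raise(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((2, 5)))


class TestRunMcmc:
    def test_full_run_reproducible(self, pool, prior):
        from humpback_assess.scenarios import build_scenario

        data, _ = build_scenario("sa5", pool)
        cfg = MCMCConfig(n_burn=200, n_iter=1_000, thin=10, seed=99,
                         proposal_cov=np.diag([9e6, 2.5e-3]))
        d1 = run_mcmc(data, prior, cfg)
        d2 = run_mcmc(data, prior, cfg)
        assert d1.params.equals(d2.params)
        assert np.array_equal(d1.N, d2.N)
        assert d1.acceptance == d2.acceptance

    def test_draw_count_and_support(self, scenario_fits, prior):
        draws = scenario_fits["updated"]
        assert draws.n_draws == 3 * 1_000
        n_lo, n_hi = prior.n2005_bounds
        r_lo, r_hi = prior.rmax_bounds
        assert draws.params.n2005.between(n_lo, n_hi).all()
        assert draws.params.rmax.between(r_lo, r_hi).all()
        assert set(draws.params.chain) == {0, 1, 2}
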