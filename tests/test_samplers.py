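import math

import numpy as np
import pytest
from scipy import stats

import jointbhm as j
from jointbhm.chains import RunConfig
from jointbhm.exceptions import InvalidArgumentError, UnsupportedPriorError
from jointbhm.model import ModelFrame, ModelSpec, ParameterState
from jointbhm.priors import InverseGammaSigma2, InverseWishart, PriorConfig
from jointbhm.samplers import (
    ProposalConfig,
    draw_latent_y2star,
    leapfrog,
    metropolis_hastings_kernel,
    run_gibbs,
    run_hmc,
    run_metropolis_hastings,
    run_sampler,
)

from .conftest import (
    conjugate_gaussian_spec,
    conjugate_posterior,
    make_empty_dataset,
    mcse_mean,
    single_row_dataset,
)


# ---------------------------------------------------------------------------
# leapfrog
# ---------------------------------------------------------------------------
class TestLeapfrog:
    grad = staticmethod(lambda x: -x)  # standard normal target

    def test_zero_steps_identity(self):
        x, p = leapfrog(np.array([1.0, 2.0]), np.array([0.5, -0.5]), 0.1, 0, self.grad)
        np.testing.assert_array_equal(x, [1.0, 2.0])
        np.testing.assert_array_equal(p, [0.5, -0.5])

    def test_reversibility(self):
        rng = np.random.default_rng(0)
        x0 = rng.standard_normal(5)
        p0 = rng.standard_normal(5)
        x1, p1 = leapfrog(x0, p0, 0.05, 30, self.grad)
        x2, p2 = leapfrog(x1, -p1, 0.05, 30, self.grad)
        np.testing.assert_allclose(x2, x0, atol=1e-8)
        np.testing.assert_allclose(-p2, p0, atol=1e-8)

    def test_energy_error_bound(self):
        # 1-D standard normal, eps = 0.1, L = 10: |dH| < 0.01 for 99% of starts
        rng = np.random.default_rng(1)
        bad = 0
        trials = 300
        for _ in range(trials):
            x0 = rng.standard_normal(1)
            p0 = rng.standard_normal(1)
            h0 = 0.5 * x0[0] ** 2 + 0.5 * p0[0] ** 2
            x1, p1 = leapfrog(x0, p0, 0.1, 10, self.grad)
            h1 = 0.5 * x1[0] ** 2 + 0.5 * p1[0] ** 2
            if abs(h1 - h0) >= 0.01:
                bad += 1
        assert bad / trials <= 0.01

    def test_invalid_args(self):
        with pytest.raises(InvalidArgumentError):
            leapfrog(np.zeros(1), np.zeros(1), -0.1, 1, self.grad)


# ---------------------------------------------------------------------------
# generic MH kernel
# ---------------------------------------------------------------------------
class TestMHKernel:
    def test_tiny_scale_accepts_everything(self):
        rng = np.random.default_rng(2)
        draws, st = metropolis_hastings_kernel(
            lambda x: -0.5 * float(x @ x), np.zeros(2), rng,
            n_iterations=500, scales=[1e-8],
        )
        assert st["acceptance"][0] > 0.9999
        assert np.ptp(draws) < 1e-4  # chain barely moves

    def test_independence_proposal_equal_to_target(self):
        rng = np.random.default_rng(3)
        draws, st = metropolis_hastings_kernel(
            lambda x: float(stats.norm.logpdf(x[0])),
            np.zeros(1), rng, n_iterations=2000,
            q_sample=lambda r, x: r.standard_normal(1),
            q_logpdf=lambda x_from, x_to: float(stats.norm.logpdf(x_to[0])),
        )
        assert st["acceptance"][0] == 1.0  # ratio is exactly 1

    def test_standard_normal_target(self):
        rng = np.random.default_rng(4)
        draws, _ = metropolis_hastings_kernel(
            lambda x: -0.5 * float(x @ x), np.zeros(1), rng,
            n_iterations=50000, burn_in=2000, scales=[2.4],
        )
        x = draws.ravel()
        assert abs(x.mean()) < 3 * mcse_mean(x)
        assert abs(x.var(ddof=1) - 1.0) < 0.05

    def test_discrete_detailed_balance(self):
        # 5-state fixture target via rounded coordinates and symmetric +/-1 moves
        p = np.array([0.35, 0.1, 0.25, 0.05, 0.25])
        logp = np.log(p)

        def log_target(x):
            s = int(round(x[0]))
            return float(logp[s]) if 0 <= s <= 4 else -math.inf

        rng = np.random.default_rng(5)
        n = 1_000_000
        draws, _ = metropolis_hastings_kernel(
            log_target, np.array([2.0]), rng, n_iterations=n, burn_in=1000,
            q_sample=lambda r, x: x + (1.0 if r.random() < 0.5 else -1.0),
            q_logpdf=lambda a, b: math.log(0.5),
        )
        states = np.round(draws.ravel()).astype(int)
        freq = np.bincount(states, minlength=5) / len(states)
        for s in range(5):
            se = math.sqrt(p[s] * (1 - p[s]) / len(states))
            # autocorrelated chain: inflate the i.i.d. SE by a mixing factor
            assert abs(freq[s] - p[s]) < 3 * se * 8, (s, freq[s], p[s])


# ---------------------------------------------------------------------------
# model-level MH
# ---------------------------------------------------------------------------
class TestRunMH:
    def test_conjugate_posterior_recovery(self, tiny_data):
        covs = ("intercept", "ultrasound")
        spec = conjugate_gaussian_spec(covs=covs)
        run = RunConfig(n_chains=2, n_iterations=8000, burn_in=2000, thinning=2, seed=1)
        fit = run_metropolis_hastings(tiny_data, spec, run=run)
        mean, cov = conjugate_posterior(tiny_data, covs, 1.0, 1.0)
        for i, c in enumerate(covs):
            x = fit.get(f"beta_y1[{c}]")
            err = abs(x.mean() - mean[i])
            assert err < 3 * max(mcse_mean(x), 1e-4), c

    def test_bit_reproducible(self, tiny_data, ri_spec):
        run = RunConfig(n_chains=2, n_iterations=300, burn_in=100, thinning=1, seed=7)
        a = run_metropolis_hastings(tiny_data, ri_spec, run=run)
        b = run_metropolis_hastings(tiny_data, ri_spec, run=run)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_acceptance_recorded_per_block(self, tiny_data, ri_spec):
        run = RunConfig(n_chains=1, n_iterations=300, burn_in=100, thinning=1, seed=3)
        fit = run_metropolis_hastings(tiny_data, ri_spec, run=run)
        st = fit.stats["chains"][0]
        assert st["blocks"] == ["beta_y1", "beta_y2", "variance", "u"]
        assert len(st["acceptance"]) == 4


# ---------------------------------------------------------------------------
# latent draws + Gibbs
# ---------------------------------------------------------------------------
class TestLatentDraws:
    def _setup(self, y2, eta):
        data = single_row_dataset(y2=y2)
        spec = ModelSpec(
            structure="full", fixed_y1=("intercept",), fixed_y2=("intercept",),
            random_covariates=(), prior=PriorConfig(),
        )
        state = ParameterState(np.array([0.0]), np.array([eta]), 1.0,
                               np.zeros((1, 0)), np.zeros((0, 0)))
        return data, spec, state

    def test_truncated_moment(self):
        data, spec, state = self._setup(1, 0.0)
        rng = np.random.default_rng(6)
        draws = np.array(
            [draw_latent_y2star(state, data, spec, rng)[0] for _ in range(100_000)]
        )
        expect = math.sqrt(2 / math.pi)
        sd = math.sqrt(1 - 2 / math.pi)
        assert abs(draws.mean() - expect) < 3 * sd / math.sqrt(len(draws))

    def test_sign_constraints(self):
        data, spec, state = self._setup(0, 1.0)
        rng = np.random.default_rng(7)
        draws = np.array(
            [draw_latent_y2star(state, data, spec, rng)[0] for _ in range(500)]
        )
        assert (draws <= 0).all()

    def test_extreme_eta_robust(self):
        data, spec, state = self._setup(1, -10.0)
        rng = np.random.default_rng(8)
        draws = np.array(
            [draw_latent_y2star(state, data, spec, rng)[0] for _ in range(200)]
        )
        assert np.isfinite(draws).all() and (draws > 0).all()


class TestGibbs:
    def test_prior_only_run_matches_prior(self):
        data = make_empty_dataset()
        spec = ModelSpec(
            structure="full", fixed_y1=("intercept",), fixed_y2=("intercept",),
            random_covariates=(), responses=("y1",),
            prior=PriorConfig(beta_scale=2.0, sigma2=InverseGammaSigma2(3.0, 2.0)),
        )
        run = RunConfig(n_chains=2, n_iterations=4000, burn_in=0, thinning=1, seed=9)
        fit = run_gibbs(data, spec, run=run)
        b = fit.get("beta_y1[intercept]").ravel()
        s2 = fit.get("sigma2_y1").ravel()
        n = len(b)
        assert abs(b.mean()) < 3 * 2.0 / math.sqrt(n)
        # IG(3,2): mean 1, var 1
        assert abs(s2.mean() - 1.0) < 3 * 1.0 / math.sqrt(n)

    def test_conjugate_toy_posterior(self):
        data = single_row_dataset(y1=2.0)
        spec = conjugate_gaussian_spec(beta_scale=1.0)
        run = RunConfig(n_chains=2, n_iterations=6000, burn_in=1000, thinning=1, seed=5)
        fit = run_gibbs(data, spec, run=run)
        b = fit.get("beta_y1[intercept]").ravel()
        # posterior N(1, 0.5)
        n_eff = len(b)  # independent draws under this conjugate Gibbs
        assert abs(b.mean() - 1.0) < 3 * math.sqrt(0.5 / n_eff)
        assert abs(b.var(ddof=1) - 0.5) < 3 * 0.5 * math.sqrt(2 / n_eff)

    def test_sigma_u_draws_spd(self, tiny_data, ri_spec):
        run = RunConfig(n_chains=1, n_iterations=300, burn_in=100, thinning=1, seed=2)
        fit = run_gibbs(tiny_data, ri_spec, run=run)
        frame = ModelFrame(tiny_data, ri_spec)
        for state in fit.states(frame):
            assert np.linalg.eigvalsh(state.Sigma_u).min() > 0

    def test_nonconjugate_prior_rejected(self, tiny_data):
        spec = ModelSpec.from_structure("random_intercept", prior=j.preset("brms_like"))
        with pytest.raises(UnsupportedPriorError, match="inverse-"):
            run_gibbs(tiny_data, spec)

    def test_flat_beta_rejected(self, tiny_data):
        spec = ModelSpec.from_structure("random_intercept", prior=j.preset("mlwin_like"))
        with pytest.raises(UnsupportedPriorError, match="beta"):
            run_gibbs(tiny_data, spec)

    def test_bit_reproducible(self, tiny_data, ri_spec):
        run = RunConfig(n_chains=2, n_iterations=200, burn_in=50, thinning=1, seed=4)
        a = run_gibbs(tiny_data, ri_spec, run=run)
        b = run_gibbs(tiny_data, ri_spec, run=run)
        np.testing.assert_array_equal(a.draws, b.draws)


# ---------------------------------------------------------------------------
# HMC
# ---------------------------------------------------------------------------
class TestHMC:
    def test_small_step_high_acceptance(self, tiny_data):
        spec = conjugate_gaussian_spec(covs=("intercept", "ultrasound"))
        hmc = j.HMCConfig(step_size=1e-4, n_leapfrog=1, adapt=False, adapt_mass=False)
        run = RunConfig(n_chains=1, n_iterations=1200, burn_in=200, thinning=1, seed=3)
        fit = run_hmc(tiny_data, spec, hmc=hmc, run=run)
        assert fit.stats["chains"][0]["acceptance"] > 0.999

    def test_conjugate_posterior_recovery(self, tiny_data):
        covs = ("intercept", "ultrasound", "rcp")
        spec = conjugate_gaussian_spec(covs=covs)
        run = RunConfig(n_chains=2, n_iterations=1500, burn_in=500, thinning=1, seed=6)
        fit = run_hmc(tiny_data, spec, run=run)
        mean, cov = conjugate_posterior(tiny_data, covs, 1.0, 1.0)
        for i, c in enumerate(covs):
            x = fit.get(f"beta_y1[{c}]")
            assert abs(x.mean() - mean[i]) < 3 * max(mcse_mean(x), 1e-4), c
            # marginal sd also matches closed form within a loose band
            assert abs(x.std(ddof=1) - math.sqrt(cov[i, i])) < 0.25 * math.sqrt(cov[i, i])

    def test_bit_reproducible(self, tiny_data, ri_spec):
        run = RunConfig(n_chains=2, n_iterations=200, burn_in=100, thinning=1, seed=8)
        a = run_hmc(tiny_data, ri_spec, run=run)
        b = run_hmc(tiny_data, ri_spec, run=run)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_divergences_reported(self, tiny_data, ri_spec):
        run = RunConfig(n_chains=1, n_iterations=150, burn_in=50, thinning=1, seed=9)
        fit = run_hmc(tiny_data, ri_spec, run=run)
        st = fit.stats["chains"][0]
        assert "divergences" in st and st["divergences"] >= 0
        assert "step_size" in st


# ---------------------------------------------------------------------------
# cross-sampler agreement on a shared joint dataset
# ---------------------------------------------------------------------------
@pytest.mark.slow
class TestSamplerAgreement:
    def test_three_samplers_agree(self, small_data, ri_spec):
        fits = {
            "mh": run_metropolis_hastings(
                small_data, ri_spec,
                run=RunConfig(n_chains=2, n_iterations=9000, burn_in=2000,
                              thinning=4, seed=11),
            ),
            "gibbs": run_gibbs(
                small_data, ri_spec,
                run=RunConfig(n_chains=2, n_iterations=5000, burn_in=1000,
                              thinning=2, seed=12),
            ),
            "hmc": run_hmc(
                small_data, ri_spec,
                run=RunConfig(n_chains=2, n_iterations=1800, burn_in=700,
                              thinning=1, seed=13),
            ),
        }
        names = [f"beta_y1[{c}]" for c in ri_spec.fixed_y1] + [
            f"beta_y2[{c}]" for c in ri_spec.fixed_y2
        ]
        for nm in names:
            ests = {k: (f.get(nm).mean(), mcse_mean(f.get(nm))) for k, f in fits.items()}
            pairs = [("mh", "gibbs"), ("mh", "hmc"), ("gibbs", "hmc")]
            for a, b in pairs:
                ma, sa = ests[a]
                mb, sb = ests[b]
                # short-chain MCSEs are optimistic for the slowest-mixing
                # coordinates; keep a small absolute floor
                tol = 3 * math.sqrt(sa**2 + sb**2)
                assert abs(ma - mb) < max(tol, 0.04), (nm, a, b, ests)


def test_run_sampler_dispatch(tiny_data, ri_spec):
    run = RunConfig(n_chains=1, n_iterations=60, burn_in=20, thinning=1, seed=1)
    assert run_sampler("gibbs", tiny_data, ri_spec, run=run).sampler == "gibbs"
    with pytest.raises(InvalidArgumentError):
        run_sampler("nuts", tiny_data, ri_spec)


def test_runconfig_validation():
    with pytest.raises(InvalidArgumentError):
        RunConfig(burn_in=10, n_iterations=10)
    with pytest.raises(InvalidArgumentError):
        RunConfig(thinning=0)
    assert RunConfig(n_iterations=110, burn_in=10, thinning=10).n_kept == 10
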