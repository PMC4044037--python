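"""Tests for the posterior assembly, samplers, and convergence diagnostics."""

import numpy as np
import pytest

from neacod.inference import (ConvergenceReport, FitConfig, Latents, PosteriorSamples,
                              PriorSpec, _VectorModel, _process_log_density,
                              audit_uniform_uppers, convergence_report, fit,
                              log_posterior, log_prior)
from neacod.observation import ObservationSet, log_likelihood
from neacod.structures import AgeStructure, Covariates, ObservationParams, ParameterSet
from neacod.synthetic import generate_dataset, small_test_scenario


@pytest.fixture(scope="module")
def tiny_problem():
    """A reduced problem with observations, plus its empty-mask twin."""
    cfg = small_test_scenario(seed=31, n_years=12)
    state, obs, truth = generate_dataset(cfg)
    st = obs.structure
    A, Y = st.max_age, st.n_years
    empty = ObservationSet(st, np.full((A, Y), np.nan), np.full((A, Y), np.nan),
                           np.full(Y, np.nan), np.full(Y, np.nan), np.full(Y, np.nan))
    return cfg, state, obs, empty, truth


class TestLogPosteriorAssembly:
    def test_sum_of_components(self, tiny_problem):
        cfg, state, obs, empty, truth = tiny_problem
        p = truth["params"]
        st = obs.structure
        rng = np.random.default_rng(0)
        lat = Latents(
            log_N_init=np.log(state.N[:, 0]),
            eps_E=truth["shocks"].eps_E,
            eps_O=truth["shocks"].eps_O[:-1],
            u_innov=truth["shocks"].u_innov[1:],
            delta=rng.normal(0, 0.1, st.n_years))
        pri = PriorSpec()
        cov = truth["covariates"]
        total = log_posterior(p, lat, obs, cov, pri)
        no_data = log_posterior(p, lat, empty, cov, pri)
        # the with-data total exceeds the prior-only total by the likelihood
        ll = total - no_data
        assert np.isfinite(total) and ll != 0.0
        assert ll == pytest.approx(
            log_likelihood(_rebuild(p, lat, cov, st), obs, p, lat.delta), rel=1e-9)
        # and the prior-only total is exactly priors + process densities
        assert no_data == pytest.approx(
            log_prior(p, lat, pri, st) + _process_log_density(p, lat), rel=1e-12)

    def test_out_of_support_is_minus_inf(self, tiny_problem):
        cfg, state, obs, empty, truth = tiny_problem
        cov = truth["covariates"]
        vm = _VectorModel(obs, cov, PriorSpec(), truth["params"])
        x = vm.initial_points(1, np.random.default_rng(1))[0]
        x_bad = x.copy()
        x_bad[vm._ix["s4"]] = 0.5          # selectivity must be negative
        assert vm.log_posterior(x_bad) == -np.inf
        x_bad = x.copy()
        x_bad[vm._ix["beta0"]] = 2 * PriorSpec().beta0_upper
        assert vm.log_posterior(x_bad) == -np.inf
        x_bad = x.copy()
        x_bad[vm._ix["sigma_O"]] = -0.1    # SDs strictly positive
        assert vm.log_posterior(x_bad) == -np.inf

    def test_process_terms_stationary_at_zero_shocks(self, tiny_problem):
        cfg, state, obs, empty, truth = tiny_problem
        p = truth["params"]
        st = obs.structure
        base = Latents.zeros(st, np.log(state.N[:, 0]))
        f0 = _process_log_density(p, base)
        h = 1e-5
        for field in ("eps_E", "eps_O", "u_innov", "delta"):
            arr = getattr(base, field)
            arr[0] += h
            fp = _process_log_density(p, base)
            arr[0] -= 2 * h
            fm = _process_log_density(p, base)
            arr[0] += h
            grad = (fp - fm) / (2 * h)
            assert abs(grad) < 1e-6          # zero gradient at the mode
            assert fp < f0 and fm < f0       # and a maximum

    def test_batch_path_matches_reference(self, tiny_problem):
        cfg, state, obs, empty, truth = tiny_problem
        cov = truth["covariates"]
        for observations in (obs, empty):
            vm = _VectorModel(observations, cov, PriorSpec(), truth["params"])
            X = vm.initial_points(20, np.random.default_rng(2))
            ref = np.array([vm.log_posterior(x) for x in X])
            assert np.allclose(vm.log_posterior_batch(X), ref, rtol=1e-10)


def _rebuild(params, latents, covariates, structure):
    from neacod.process import simulate_forward
    from neacod.structures import ProcessShocks
    shocks = ProcessShocks(latents.eps_E, np.concatenate([latents.eps_O, [0.0]]),
                           np.concatenate([[0.0], latents.u_innov]))
    return simulate_forward(params, covariates, np.exp(latents.log_N_init),
                            structure=structure, shocks=shocks)


def _fake_samples(draws: dict) -> PosteriorSamples:
    return PosteriorSamples({k: np.asarray(v, float) for k, v in draws.items()}, {}, {})


class TestConvergenceReport:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        s = _fake_samples({"x": rng.normal(0, 1, (3, 4000)),
                           "y": rng.normal(5, 2, (3, 4000))})
        rep = convergence_report(s)
        assert rep.table.loc["x", "rhat"] == pytest.approx(1.0, abs=0.01)
        assert rep.passed

    def test_offset_chains_fail(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 2000)
        s = _fake_samples({"x": np.stack([base, base + 5.0])})
        rep = convergence_report(s)
        assert rep.table.loc["x", "rhat"] > 1.5
        assert not rep.passed

    def test_thinned_ar1_autocorrelation(self):
        # AR(1) with phi=0.5 thinned by 10 has lag-1 autocorr 0.5^10 ~ 0.001
        rng = np.random.default_rng(2)
        n, phi = 200_000, 0.5
        x = np.empty(n)
        x[0] = rng.normal()
        innov = rng.normal(0, np.sqrt(1 - phi**2), n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t]
        thinned = x[::10].reshape(2, -1)
        rep = convergence_report(_fake_samples({"x": thinned}))
        assert abs(rep.table.loc["x", "lag1_autocorr"]) < 0.05
        assert rep.table.loc["x", "autocorr_ok"]

    def test_single_chain_flagged(self):
        rng = np.random.default_rng(3)
        s = _fake_samples({"x": rng.normal(0, 1, (1, 1000))})
        with pytest.warns(RuntimeWarning, match="single chain"):
            rep = convergence_report(s)
        assert not rep.table.loc["x", "rhat_ok"]

    def test_cross_correlation_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (2, 500))
        s = _fake_samples({"x": a, "y": 0.7 * a + rng.normal(0, 0.3, (2, 500))})
        rep = convergence_report(s)
        cc = rep.cross_correlation
        assert cc.loc["x", "y"] == pytest.approx(cc.loc["y", "x"])
        assert cc.loc["x", "y"] > 0.5


class TestUniformUpperAudit:
    def test_warns_when_bound_approached(self):
        pri = PriorSpec()
        s = _fake_samples({"beta0": np.full((2, 10), 0.99 * pri.beta0_upper),
                           "sigma_E": np.full((2, 10), 0.5)})
        with pytest.warns(RuntimeWarning, match="upper bound"):
            tab = audit_uniform_uppers(s, pri)
        assert not tab.loc["beta0", "ok"]
        assert tab.loc["sigma_E", "ok"]


class TestFit:
    def test_jags_same_seed_identical(self, tiny_problem):
        cfg, state, obs, empty, truth = tiny_problem
        cov = truth["covariates"]
        config = FitConfig(backend="jags", n_chains=2, n_adapt=100, burn_in=100,
                           n_iter=150, thin=1, seed=7, monitor_latent=False)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(obs, cov, PriorSpec(), config, constants=truth["params"])
            b = fit(obs, cov, PriorSpec(), config, constants=truth["params"])
        for name in ("M0", "beta0", "sigma_E", "log_q_age4"):
            assert np.array_equal(a.get(name), b.get(name))
        assert a.metadata["config_hash"] == b.metadata["config_hash"]

    def test_near_degenerate_recovery(self):
        # near-zero observation noise: the identifiable index scale q*N is
        # reproduced almost exactly and the catchabilities approach truth
        # (the pre-recruit scale rides the catchability/mortality ridge, so
        # the individual q's carry a residual scale uncertainty)
        cfg = small_test_scenario(seed=8, n_years=15)
        quiet = ObservationParams(sigma_C=0.01, sigma_I=(0.01,) * 9, sigma_year=0.005,
                                  sigma_egg=0.01, sigma_larv=0.01, sigma_0g=0.01)
        cfg = cfg.with_updates(params=cfg.params.with_updates(obs=quiet))
        state, obs, truth = generate_dataset(cfg)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit(obs, truth["covariates"], PriorSpec(),
                    FitConfig(backend="jags", n_chains=2, n_adapt=300, burn_in=1000,
                              n_iter=1000, thin=1, seed=2),
                    constants=truth["params"])
        p = truth["params"].obs
        for name, q_true in (("log_q_age3", p.q_age[0]), ("log_q_age4", p.q_age[1]),
                             ("log_q_pre1", p.q_pre[0]), ("log_q_post2", p.q_post[1])):
            assert abs(s.median(name) - np.log(q_true)) < np.log(1.15)
        # identifiable combination: predicted winter index vs observation
        st = obs.structure
        N_med = np.median(s.stacked("N"), axis=0)
        j = st.year_index(1990)
        a = 3
        q_med = np.exp(s.median(f"log_q_age{a + 1}"))
        assert q_med * N_med[a, j] == pytest.approx(obs.index_winter[a, j], rel=0.05)

    def test_emcee_same_seed_identical(self, tiny_problem):
        cfg, state, obs, empty, truth = tiny_problem
        cov = truth["covariates"]
        config = FitConfig(backend="emcee", n_chains=2, burn_in=50, n_iter=50,
                           thin=5, seed=3, n_walkers=220)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(empty, cov, PriorSpec(), config, constants=truth["params"])
            b = fit(empty, cov, PriorSpec(), config, constants=truth["params"])
        assert np.array_equal(a.get("M0"), b.get("M0"))

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            FitConfig(n_chains=1)
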