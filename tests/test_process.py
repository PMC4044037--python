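"""Unit and property tests for the life-cycle process model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neacod.process import (adult_transition, baranov_catch, compute_ssb, effort_step,
                            egg_production, egg_to_larva, fishing_mortality,
                            juvenile_transition, larva_to_zerogroup, simulate_forward,
                            zerogroup_to_age1, zerogroup_survival)
from neacod.structures import AgeStructure, ParameterSet, ProcessShocks


class TestSSB:
    def test_single_mature_age(self):
        N = np.zeros(9); w = np.ones(9); p = np.zeros(9)
        N[5], w[5], p[5] = 1e9, 2.0, 0.5
        assert compute_ssb(N, w, p) == pytest.approx(1e9)

    def test_no_mature_fish(self):
        assert compute_ssb(np.full(9, 1e8), np.ones(9), np.zeros(9)) == 0.0

    def test_three_age_toy(self):
        ssb = compute_ssb([1e8, 2e8, 3e8], [1, 2, 3], [0, 0.5, 1])
        assert ssb == pytest.approx(1.1e9)

    def test_mismatched_ages_raise(self):
        with pytest.raises(ValueError):
            compute_ssb([1.0, 2.0], [1.0], [1.0])


class TestEggProduction:
    def test_unit_conversion(self):
        # fecundity given per gram; 235 eggs/g on 1e9 kg of spawners
        assert egg_production(1e9, 235.0) == pytest.approx(2.35e14)

    def test_shock_scale(self):
        # a log-scale SD of 0.7 corresponds to about a 2-fold swing
        ratio = egg_production(1e9, 235.0, 0.7) / egg_production(1e9, 235.0, 0.0)
        assert ratio == pytest.approx(np.exp(0.7))
        assert round(ratio) == 2

    def test_zero_ssb(self):
        assert egg_production(0.0, 235.0) == 0.0

    def test_negative_ssb_raises(self):
        with pytest.raises(ValueError):
            egg_production(-1.0, 235.0)


class TestPlanktonicStages:
    def test_egg_survival(self):
        assert egg_to_larva(1.0, 0.169, 20.0) == pytest.approx(np.exp(-3.38))

    def test_zero_duration(self):
        assert egg_to_larva(5e13, 0.169, 0.0) == 5e13

    def test_chain(self):
        L = egg_to_larva(2.35e14, 0.169, 20.0)
        assert L == pytest.approx(2.35e14 * np.exp(-3.38), rel=1e-12)

    def test_baseline_larval_survival_in_observed_range(self, params):
        # 0.075/d x 60 d + 0.04/d x 60 d at zero anomaly: ~0.1007%
        p = params.with_updates(gamma=0.0)
        surv = larva_to_zerogroup(1.0, 0.0, p)
        assert surv == pytest.approx(np.exp(-6.9), rel=1e-12)
        assert 0.0008 <= surv <= 0.0012

    def test_zero_anomaly_is_gamma_independent(self, params):
        for g in (0.0, 3.38e-3, 0.01):
            assert larva_to_zerogroup(1e12, 0.0, params.with_updates(gamma=g)) == \
                larva_to_zerogroup(1e12, 0.0, params.with_updates(gamma=0.0))

    def test_gamma_for_1p5_fold_range(self, params):
        # survival(T=+1)/survival(T=-1) = 1.5 inverts to gamma = ln1.5/(2*60)
        g = np.log(1.5) / 120.0
        p = params.with_updates(gamma=g)
        ratio = larva_to_zerogroup(1.0, 1.0, p) / larva_to_zerogroup(1.0, -1.0, p)
        assert ratio == pytest.approx(1.5, rel=1e-10)

    def test_survival_capped_with_warning(self, params):
        p = params.with_updates(gamma=1.0)  # absurd warming effect
        with pytest.warns(RuntimeWarning):
            out = larva_to_zerogroup(1e6, 50.0, p)
        assert out == 1e6


class TestZerogroupToAge1:
    def test_density_independent_limit(self, params):
        p = params.with_updates(beta0=0.0, M0=0.35)
        assert zerogroup_survival(0.0, 0.0, p) == pytest.approx(np.exp(-0.35))

    def test_calibrated_mean_survival(self, params):
        # at the calibrated cannibal abundance the survival matches the
        # reported mean 0-group survival of 0.41
        s = zerogroup_survival(4.0e8, 0.0, params.with_updates(M0=0.35, beta0=1.82e-9))
        assert s == pytest.approx(0.41, abs=0.01)

    def test_cap_applies_after_shock(self, params):
        assert zerogroup_survival(0.0, 5.0, params) == 1.0
        assert zerogroup_to_age1(1e10, 0.0, 5.0, params) == 1e10


class TestJuvenileTransition:
    def test_density_independent_limit(self, params):
        p = params.with_updates(beta=(0.0, 0.0, 0.0), MJ=0.15)
        assert juvenile_transition(1e9, 1, p) / 1e9 == pytest.approx(np.exp(-0.15))

    def test_calibrated_age1_survival(self, params):
        # exp(-0.15)/(1 + 9.48e-11 * 1.25e9) ~ 0.77 (reported mean, age 1)
        out = juvenile_transition(1.25e9, 1, params)
        assert out / 1.25e9 == pytest.approx(0.77, abs=0.01)

    def test_saturation(self, params):
        cap = np.exp(-params.MJ) / params.beta_at(2)
        assert juvenile_transition(1e15, 2, params) == pytest.approx(cap, rel=1e-4)

    def test_invalid_age(self, params):
        with pytest.raises(ValueError):
            juvenile_transition(1e9, 5, params)

    @given(n1=st.floats(1e3, 1e12), n2=st.floats(1e3, 1e12))
    @settings(max_examples=50, deadline=None)
    def test_monotone_compensation(self, n1, n2):
        # strictly increasing in abundance, never overcompensating
        p = ParameterSet()
        lo, hi = sorted([n1, n2])
        if hi > lo:
            assert juvenile_transition(hi, 3, p) > juvenile_transition(lo, 3, p)
        assert juvenile_transition(hi, 3, p) <= np.exp(-p.MJ) / p.beta_at(3)


class TestAdultAndFishing:
    def test_natural_only(self):
        assert adult_transition(1.0, 0.0, 0.2) == pytest.approx(np.exp(-0.2))

    def test_combined_mortality(self):
        assert adult_transition(1.0, 0.5, 0.2) == pytest.approx(np.exp(-0.7))

    def test_zero_abundance(self):
        assert adult_transition(0.0, 0.5, 0.2) == 0.0

    def test_prior_mean_selectivity(self):
        assert fishing_mortality(-1.6, 0.0) == pytest.approx(np.exp(-1.6))

    def test_separability_in_effort(self):
        assert fishing_mortality(-1.2, np.log(2.0)) == pytest.approx(
            2.0 * fishing_mortality(-1.2, 0.0))

    def test_separability_across_ages(self):
        for U in (-0.5, 0.0, 1.3):
            ratio = fishing_mortality(-1.0, U) / fishing_mortality(-1.6, U)
            assert ratio == pytest.approx(np.exp(0.6))

    def test_effort_step_degenerate(self):
        rng = np.random.default_rng(0)
        assert effort_step(0.3, 0.0, rng) == 0.3

    def test_effort_random_walk_variance(self):
        # var(U[k] - U[0]) ~ k * sigma^2 over replicates
        rng = np.random.default_rng(12345)
        sigma, k, n = 0.2, 25, 4000
        finals = np.empty(n)
        for i in range(n):
            u = 0.0
            for _ in range(k):
                u = effort_step(u, sigma, rng)
            finals[i] = u
        assert np.var(finals) == pytest.approx(k * sigma**2, rel=0.1)


class TestBaranov:
    def test_no_fishing_no_catch(self):
        assert baranov_catch(1e9, 0.0, 0.2) == 0.0

    def test_closed_form(self):
        expected = 0.5 * (1 - np.exp(-0.4))
        assert baranov_catch(1.0, 0.2, 0.2) == pytest.approx(expected)

    def test_total_mortality_limit(self):
        assert baranov_catch(1e9, 1e6, 0.2) == pytest.approx(1e9, rel=1e-6)

    def test_zero_total_mortality(self):
        assert baranov_catch(1e9, 0.0, 0.0) == 0.0

    @given(F=st.floats(1e-6, 5.0), MA=st.floats(1e-6, 2.0), N=st.floats(1.0, 1e12))
    @settings(max_examples=100, deadline=None)
    def test_catch_is_fishing_share_of_deaths(self, F, MA, N):
        deaths = N * -np.expm1(-(F + MA))
        C = baranov_catch(N, F, MA)
        assert 0 <= C < N
        assert C / deaths == pytest.approx(F / (F + MA), abs=1e-12)


def _analytic_cohort(structure, params, covariates, initial_N):
    """Independent closed-form solution with all shocks and betas zero.

    Each cohort decays exponentially: juveniles at MJ, adults at MA+F with
    F = exp(s_a) (effort fixed at 0), and the egg chain multiplies the
    stage survivals; density dependence is off so every factor is explicit.
    """
    st, p = structure, params
    A, Y = st.max_age, st.n_years
    N = np.zeros((A, Y))
    N[:, 0] = initial_N
    eggs = np.zeros(Y)
    zerog = np.zeros(Y)
    s = np.asarray(p.s)
    for y in range(Y):
        ssb = np.sum(N[:, y] * covariates.weight[:, y] * covariates.maturity[:, y])
        eggs[y] = 1000.0 * p.f * ssb
        larv = eggs[y] * np.exp(-p.M_egg * p.t_EL)
        zerog[y] = larv * np.exp(-(p.M_larv_daily - p.gamma * covariates.temperature[y])
                                 * p.t_larv - p.M_juv_daily * p.t_ejuv)
        if y + 1 < Y:
            N[0, y + 1] = zerog[y] * np.exp(-p.M0)
            for a in (1, 2, 3):
                N[a, y + 1] = N[a - 1, y] * np.exp(-p.MJ)
            for a in range(st.recruit_age, A):
                F = np.exp(s[a - st.recruit_age])
                N[a, y + 1] = N[a - 1, y] * np.exp(-(p.MA + F))
    return N, eggs, zerog


class TestSimulateForward:
    def test_deterministic_oracle(self, flat_covariates):
        st_ = AgeStructure(n_years=20)
        cov = flat_covariates(st_, w=2.0, p=0.3, T=0.1)
        p = ParameterSet(beta0=0.0, beta=(0.0, 0.0, 0.0))
        init = 1e9 * np.exp(-0.3 * np.arange(9))
        state = simulate_forward(p, cov, init, structure=st_,
                                 shocks=ProcessShocks.zeros(20))
        N_ref, eggs_ref, zerog_ref = _analytic_cohort(st_, p, cov, init)
        assert np.allclose(state.N, N_ref, rtol=1e-10)
        assert np.allclose(state.eggs, eggs_ref, rtol=1e-10)
        assert np.allclose(state.zerogroup, zerog_ref, rtol=1e-10)

    def test_same_seed_reproducible(self, flat_covariates):
        st_ = AgeStructure(n_years=15)
        cov = flat_covariates(st_, w=1.5, p=0.4)
        init = np.full(9, 1e9)
        a = simulate_forward(ParameterSet(), cov, init, structure=st_, seed=99)
        b = simulate_forward(ParameterSet(), cov, init, structure=st_, seed=99)
        assert np.array_equal(a.N, b.N) and np.array_equal(a.catch, b.catch)

    def test_all_outputs_nonnegative_and_bounded(self, default_dataset):
        _, state, _, _ = default_dataset
        state.validate()  # non-negativity, F=0 below recruit age, catch <= N
        # realized stage survivals never exceed 1
        assert np.all(state.N[0, 1:] <= state.zerogroup[:-1] + 1e-9)
        for a in (1, 2, 3):
            assert np.all(state.N[a, 1:] <= state.N[a - 1, :-1] + 1e-9)

    def test_density_dependence_dampens_age4_variance(self, flat_covariates):
        st_ = AgeStructure(n_years=40)
        cov = flat_covariates(st_, w=1.5, p=0.35)
        init = 1.25e9 * np.exp(-0.35 * np.arange(9))
        rng = np.random.default_rng(5)
        shocks = ProcessShocks.draw(ParameterSet(), 40, rng)
        on = simulate_forward(ParameterSet(), cov, init, structure=st_, shocks=shocks)
        off = simulate_forward(ParameterSet(beta0=0.0, beta=(0.0, 0.0, 0.0)), cov, init,
                               structure=st_, shocks=shocks)
        drop = slice(10, None)  # discard transient
        v_on = np.var(np.log(on.N[3, drop]), ddof=1)
        v_off = np.var(np.log(off.N[3, drop]), ddof=1)
        assert v_on < v_off

    def test_missing_covariate_years_rejected(self, flat_covariates):
        st_ = AgeStructure(n_years=20)
        cov = flat_covariates(AgeStructure(n_years=10))
        with pytest.raises(ValueError):
            simulate_forward(ParameterSet(), cov, np.full(9, 1e9), structure=st_)

    def test_separability_of_F(self, default_dataset):
        _, state, _, _ = default_dataset
        ratios = state.F[5, :] / state.F[3, :]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)
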