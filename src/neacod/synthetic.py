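"""Synthetic datasets with the statistical structure of the real surveys.

The generator emulates the observational setting of the Northeast Arctic
cod stock: winter bottom-trawl indices for ages 1-9 from 1981, an autumn
0-group index from 1966, ichthyoplankton egg and larval indices 1959-1990,
and age-specific landings from 1959, together with weight-at-age, maturity
ogives and a June-August temperature anomaly.  Truth (every latent state
and parameter) is recorded so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .observation import ObservationSet, observe_landings, observe_stage_index
from .process import simulate_forward
from .structures import AgeStructure, Covariates, LatentState, ParameterSet, ProcessShocks

__all__ = ["ScenarioConfig", "generate_covariates", "generate_dataset", "small_test_scenario"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the fitted Northeast Arctic cod model: years 1959-2010,
    process SDs 0.7 on spawning and 0-group survival, the posterior-median
    density-dependence coefficients, and the historical survey windows.
    The fishing-effort history is a deterministic piecewise trend (gradual
    rise to the late 1980s, sharp drop, recovery in the late 1990s, decline
    thereafter) plus random-walk noise.
    """

    structure: AgeStructure = field(default_factory=AgeStructure)
    params: ParameterSet = field(default_factory=ParameterSet)
    # covariate generators
    temp_sd: float = 0.5           # stationary SD of the AR(1) anomaly, degC
    temp_ar1: float = 0.6          # lag-1 autocorrelation
    weight_cv: float = 0.05        # interannual CV of weight-at-age
    w_inf: float = 14.0            # asymptotic weight, kg
    growth_k: float = 0.15         # von Bertalanffy growth coefficient
    maturity_a50: float = 6.5      # age of 50% maturity
    maturity_slope: float = 0.8    # ogive steepness (years)
    # effort trend knots (year, log-effort level), linearly interpolated
    effort_knots: tuple[tuple[int, float], ...] = (
        (1959, 0.0), (1988, 0.6), (1992, 0.0), (1999, 0.5), (2010, -0.4))
    # observation windows (inclusive); None = end of series
    egg_years: tuple[int, int] = (1959, 1990)
    larv_years: tuple[int, int] = (1959, 1990)
    zerogroup_first_year: int = 1966
    winter_first_year: int = 1981
    landings_first_year: int = 1959
    # initial condition: ages 1..A in the burn-in start year, scaled by init_scale
    init_scale: float = 1.0
    burn_in_years: int = 15
    seed: int = 0

    def with_updates(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def _ar1_series(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``, then re-centred."""
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, innov_sd)
    return x - x.mean()


def generate_covariates(config: ScenarioConfig, rng: np.random.Generator,
                        n_years: int | None = None) -> Covariates:
    """Weight-at-age, maturity ogive and temperature anomaly series.

    Weight follows a cubed von Bertalanffy length curve with mild lognormal
    year-to-year variation; maturity is a logistic ogive in age (typical
    maturation at 6-8 years); temperature is a centred AR(1) anomaly.
    """
    st = config.structure
    Y = n_years if n_years is not None else st.n_years
    ages = np.arange(1, st.max_age + 1, dtype=float)
    w_mean = config.w_inf * (1.0 - np.exp(-config.growth_k * ages)) ** 3
    w_noise = np.exp(rng.normal(0.0, config.weight_cv, (st.max_age, Y)))
    weight = w_mean[:, None] * w_noise
    maturity = 1.0 / (1.0 + np.exp(-(ages - config.maturity_a50) / config.maturity_slope))
    maturity = np.repeat(maturity[:, None], Y, axis=1)
    temperature = _ar1_series(Y, config.temp_sd, config.temp_ar1, rng)
    return Covariates(weight=weight, maturity=maturity, temperature=temperature)


def _effort_trend(config: ScenarioConfig, years: np.ndarray) -> np.ndarray:
    ky = np.array([k[0] for k in config.effort_knots], float)
    kv = np.array([k[1] for k in config.effort_knots], float)
    U = np.interp(years.astype(float), ky, kv)
    return U - U[0]  # pinned to 0 in the first output year


def _initial_abundance(st: AgeStructure, scale: float) -> np.ndarray:
    """Rough pre-burn-in age structure; burn-in erases its details."""
    ages = np.arange(1, st.max_age + 1, dtype=float)
    return scale * 1.25e9 * np.exp(-0.35 * (ages - 1.0))


def generate_dataset(
    config: ScenarioConfig,
) -> tuple[LatentState, ObservationSet, dict[str, Any]]:
    """Simulate truth and observe it through the survey/landings models.

    The population is spun up for ``burn_in_years`` (at least one full age
    span) before the first output year so that early years are not
    initial-condition artifacts.  Returns the latent truth over the output
    years, the masked observations, and a truth record holding the
    parameters, shocks and covariates used.
    """
    st = config.structure
    p = config.params
    rng = np.random.default_rng(config.seed)
    burn = max(config.burn_in_years, st.max_age)
    total_years = st.n_years + burn
    full_st = AgeStructure(
        first_year=st.first_year - burn, n_years=total_years, max_age=st.max_age,
        recruit_age=st.recruit_age, cannibal_ages=st.cannibal_ages, dd_ages=st.dd_ages)

    cov_full = generate_covariates(config, rng, n_years=total_years)

    # process shocks: RW noise rides on the deterministic effort trend
    shocks = ProcessShocks.draw(p, total_years, rng)
    trend = _effort_trend(config, full_st.years)
    u_innov = np.diff(trend, prepend=trend[0]) + shocks.u_innov
    u_innov[0] = 0.0
    # hold effort at its first-output-year baseline during burn-in
    u_innov[:burn + 1] = 0.0
    shocks = ProcessShocks(shocks.eps_E, shocks.eps_O, u_innov)

    full_state = simulate_forward(p, cov_full, _initial_abundance(st, config.init_scale),
                                  structure=full_st, shocks=shocks)

    # slice off the burn-in
    sl = slice(burn, total_years)
    state = LatentState(
        st, full_state.eggs[sl], full_state.larvae[sl], full_state.zerogroup[sl],
        full_state.N[:, sl], full_state.SSB[sl], full_state.F[:, sl],
        full_state.U[sl] - full_state.U[burn], full_state.catch[:, sl])
    state.validate()
    covariates = Covariates(cov_full.weight[:, sl], cov_full.maturity[:, sl],
                            cov_full.temperature[sl] - cov_full.temperature[sl].mean())

    obs = _observe(state, p, config, rng)
    truth = {
        "params": p,
        "structure": st,
        "covariates": covariates,
        "shocks": ProcessShocks(shocks.eps_E[sl], shocks.eps_O[sl], shocks.u_innov[sl]),
        "latent": state,
        "seed": config.seed,
    }
    return state, obs, truth


def _observe(state: LatentState, p: ParameterSet, config: ScenarioConfig,
             rng: np.random.Generator) -> ObservationSet:
    st = state.structure
    op = p.obs
    Y, A = st.n_years, st.max_age
    years = st.years

    landings = np.full((A, Y), np.nan)
    winter = np.full((A, Y), np.nan)
    egg = np.full(Y, np.nan)
    larv = np.full(Y, np.nan)
    zg = np.full(Y, np.nan)

    sig_I = np.asarray(op.sigma_I[:A], float)
    for j, yr in enumerate(years):
        yr = int(yr)
        if yr >= config.landings_first_year:
            for a in range(st.recruit_age, A + 1):
                landings[a - 1, j] = observe_landings(state.catch[a - 1, j], op.sigma_C, rng)
        if yr >= config.winter_first_year:
            delta = rng.normal(0.0, op.sigma_year)
            for a in range(1, A + 1):
                q = op.q_winter(a, yr, A)
                eps = rng.normal(0.0, sig_I[a - 1])
                winter[a - 1, j] = q * state.N[a - 1, j] * np.exp(delta + eps)
        if config.egg_years[0] <= yr <= config.egg_years[1]:
            egg[j] = observe_stage_index(state.eggs[j], op.q_egg, op.sigma_egg, rng)
        if config.larv_years[0] <= yr <= config.larv_years[1]:
            larv[j] = observe_stage_index(state.larvae[j], op.q_larv, op.sigma_larv, rng)
        if yr >= config.zerogroup_first_year:
            zg[j] = observe_stage_index(state.zerogroup[j], op.q_0g, op.sigma_0g, rng)

    return ObservationSet(st, landings, winter, egg, larv, zg)


def small_test_scenario(seed: int = 0, n_years: int = 15) -> ScenarioConfig:
    """A reduced scenario (short series, age span 6) for fast unit tests."""
    st = AgeStructure(first_year=1981, n_years=n_years, max_age=6,
                      recruit_age=4, cannibal_ages=(3, 4), dd_ages=(1, 2, 3))
    p = ParameterSet(s=(-2.0, -1.7, -1.5))
    return ScenarioConfig(
        structure=st, params=p, seed=seed,
        egg_years=(1981, 1981 + n_years - 1), larv_years=(1981, 1981 + n_years - 1),
        zerogroup_first_year=1981, winter_first_year=1981, landings_first_year=1981,
        effort_knots=((1981, 0.0), (1981 + n_years, 0.1)), burn_in_years=8)
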