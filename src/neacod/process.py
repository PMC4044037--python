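"""Process model: one-year transitions for every life stage.

The life cycle is eggs -> larvae -> 0-group -> ages 1..A, with egg
production proportional to spawning stock biomass, exponential mortality
through the planktonic stages (temperature-dependent during the larval
phase), Beverton-Holt compensatory survival for the 0-group (cannibalism by
ages 3-4) and for juvenile ages 1-3 (intracohort), and natural plus
separable fishing mortality for the recruited ages.  Catch follows the
Baranov equation.  Process stochasticity enters as lognormal shocks on egg
production and 0-group survival and as a random walk on log fishing effort.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .structures import AgeStructure, Covariates, LatentState, ParameterSet, ProcessShocks

__all__ = [
    "compute_ssb",
    "egg_production",
    "egg_to_larva",
    "larva_to_zerogroup",
    "zerogroup_to_age1",
    "juvenile_transition",
    "adult_transition",
    "fishing_mortality",
    "effort_step",
    "baranov_catch",
    "simulate_forward",
]

logger = logging.getLogger(__name__)


def compute_ssb(N: np.ndarray, w: np.ndarray, p: np.ndarray) -> float:
    """Spawning stock biomass (kg): sum over ages of N * weight * maturity."""
    N, w, p = np.asarray(N, float), np.asarray(w, float), np.asarray(p, float)
    if not (N.shape == w.shape == p.shape):
        raise ValueError("abundance, weight and maturity must cover the same ages")
    return float(np.sum(N * w * p))


def egg_production(SSB: float, f: float, eps_E: float = 0.0) -> float:
    """Total egg production from SSB (kg) and fecundity f (eggs per gram).

    The lognormal shock exp(eps_E) absorbs stochasticity in the spawning
    process (mean fecundity, fertilisation, pre-survey egg survival).
    """
    if SSB < 0:
        raise ValueError("SSB must be >= 0")
    return 1000.0 * f * SSB * np.exp(eps_E)


def egg_to_larva(E: float, M_egg: float, t_EL: float) -> float:
    """Larval abundance after exponential egg mortality over t_EL days."""
    if E < 0:
        raise ValueError("egg abundance must be >= 0")
    if t_EL < 0:
        raise ValueError("duration must be >= 0")
    return E * np.exp(-M_egg * t_EL)


def larval_phase_survival(T: float, params: ParameterSet) -> float:
    """Survival fraction from larval to 0-group survey at anomaly T (degC).

    Daily larval mortality is reduced by gamma per degree of positive
    anomaly during the larval phase only; the early-juvenile phase is
    temperature-independent.  The fraction is capped at 1.
    """
    z = (params.M_larv_daily - params.gamma * T) * params.t_larv + params.M_juv_daily * params.t_ejuv
    surv = np.exp(-z)
    if surv > 1.0:
        warnings.warn("temperature anomaly drove stage survival above 1; capped", RuntimeWarning, stacklevel=2)
        return 1.0
    return float(surv)


def larva_to_zerogroup(L: float, T: float, params: ParameterSet) -> float:
    """0-group abundance from larvae after the larval + early-juvenile phases."""
    if L < 0:
        raise ValueError("larval abundance must be >= 0")
    return L * larval_phase_survival(T, params)


def zerogroup_survival(N_cannibals: float, eps_O: float, params: ParameterSet) -> float:
    """0-group -> age-1 survival: Beverton-Holt in cannibal abundance.

    S = min(1, exp(-M0) * exp(eps_O) / (1 + beta0 * N_cannibals)); the
    lognormal shock multiplies survival before the cap at 1.
    """
    if N_cannibals < 0:
        raise ValueError("cannibal abundance must be >= 0")
    S = np.exp(-params.M0 + eps_O) / (1.0 + params.beta0 * N_cannibals)
    return float(min(1.0, S))


def zerogroup_to_age1(O: float, N_cannibals: float, eps_O: float, params: ParameterSet) -> float:
    """Age-1 abundance next year from this year's 0-group."""
    if O < 0:
        raise ValueError("0-group abundance must be >= 0")
    return O * zerogroup_survival(N_cannibals, eps_O, params)


def juvenile_transition(N_a: float, a: int, params: ParameterSet) -> float:
    """Next-age abundance for a juvenile age with intracohort density dependence.

    N_{a+1} = N_a * exp(-MJ) / (1 + beta_a * N_a): compensatory
    (Beverton-Holt), saturating at exp(-MJ)/beta_a, never overcompensating.
    """
    if N_a < 0:
        raise ValueError("abundance must be >= 0")
    b = params.beta_at(a)
    return N_a * np.exp(-params.MJ) / (1.0 + b * N_a)


def adult_transition(N_a: float, F_a: float, MA: float) -> float:
    """Next-age abundance for a recruited age under natural + fishing mortality."""
    if N_a < 0 or F_a < 0 or MA < 0:
        raise ValueError("abundance and mortalities must be >= 0")
    return N_a * np.exp(-(MA + F_a))


def fishing_mortality(s_a: float, U_y: float) -> float:
    """Separable fishing mortality F = exp(s_a + U_y) for a recruited age."""
    return float(np.exp(s_a + U_y))


def effort_step(U_prev: float, sigma_U: float, rng: np.random.Generator) -> float:
    """One random-walk step of log fishing effort."""
    if sigma_U < 0:
        raise ValueError("sigma_U must be >= 0")
    return float(U_prev + rng.normal(0.0, sigma_U)) if sigma_U > 0 else float(U_prev)


def baranov_catch(N, F, MA):
    """Baranov catch: the fishing fraction of total annual removals.

    C = N * F/(F+MA) * (1 - exp(-(F+MA))); the F+MA -> 0 limit is 0.
    Accepts scalars or arrays.
    """
    N, F = np.asarray(N, float), np.asarray(F, float)
    if np.any(N < 0) or np.any(F < 0) or MA < 0:
        raise ValueError("abundance and mortalities must be >= 0")
    Z = F + MA
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(Z > 0, F / np.where(Z > 0, Z, 1.0), 0.0)
        out = N * frac * -np.expm1(-Z)
    return float(out) if out.ndim == 0 else out


def simulate_forward(
    params: ParameterSet,
    covariates: Covariates,
    initial_N: np.ndarray,
    structure: AgeStructure | None = None,
    shocks: ProcessShocks | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> LatentState:
    """Run the full life-cycle recursion over all years.

    ``initial_N`` gives abundances for ages 1..A in the first year.  Shocks
    may be supplied explicitly (e.g. all zeros for the deterministic
    skeleton) or drawn from ``rng``/``seed``.  Cohort bookkeeping maps age a
    in year y to age a+1 in year y+1; the cannibal abundance acting on the
    year-y 0-group is N[3, y] + N[4, y] of the same year.
    """
    st = structure or AgeStructure(n_years=covariates.n_years)
    Y, A = st.n_years, st.max_age
    if covariates.n_years != Y or covariates.weight.shape[0] != A:
        raise ValueError("covariates do not cover the modelled ages and years")
    initial_N = np.asarray(initial_N, float)
    if initial_N.shape != (A,):
        raise ValueError(f"initial abundances must cover ages 1..{A}")
    if np.any(initial_N < 0):
        raise ValueError("initial abundances must be >= 0")
    if shocks is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        shocks = ProcessShocks.draw(params, Y, rng)
    for name in ("eps_E", "eps_O", "u_innov"):
        if getattr(shocks, name).shape != (Y,):
            raise ValueError(f"shock array {name} must have length {Y}")

    N = np.zeros((A, Y))
    N[:, 0] = initial_N
    eggs = np.zeros(Y)
    larvae = np.zeros(Y)
    zerogroup = np.zeros(Y)
    SSB = np.zeros(Y)
    F = np.zeros((A, Y))
    U = np.zeros(Y)
    catch = np.zeros((A, Y))
    ra = st.recruit_age
    s = np.asarray(params.s, float)
    if s.shape != (A - ra + 1,):
        raise ValueError(f"selectivities must cover ages {ra}..{A}")
    can_idx = [a - 1 for a in st.cannibal_ages]

    for y in range(Y):
        if y > 0:
            U[y] = U[y - 1] + shocks.u_innov[y]
        SSB[y] = compute_ssb(N[:, y], covariates.weight[:, y], covariates.maturity[:, y])
        eggs[y] = egg_production(SSB[y], params.f, shocks.eps_E[y])
        larvae[y] = egg_to_larva(eggs[y], params.M_egg, params.t_EL)
        zerogroup[y] = larva_to_zerogroup(larvae[y], covariates.temperature[y], params)
        F[ra - 1:, y] = np.exp(s + U[y])
        catch[:, y] = baranov_catch(N[:, y], F[:, y], params.MA)
        if y + 1 < Y:
            N_can = float(N[can_idx, y].sum())
            N[0, y + 1] = zerogroup_to_age1(zerogroup[y], N_can, shocks.eps_O[y], params)
            for a in st.dd_ages:
                N[a, y + 1] = juvenile_transition(N[a - 1, y], a, params)
            for a in range(ra, A):
                N[a, y + 1] = adult_transition(N[a - 1, y], F[a - 1, y], params.MA)

    state = LatentState(st, eggs, larvae, zerogroup, N, SSB, F, U, catch)
    state.validate()
    return state
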