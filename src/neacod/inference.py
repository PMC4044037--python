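"""Bayesian estimation of the life-cycle model.

The joint posterior combines the observation likelihood, the process-error
densities (spawning and 0-group shocks, effort random-walk innovations,
winter-survey year effects) and the priors.  Two samplers are provided:

* ``backend="jags"`` (default): the model expressed in BUGS and sampled by
  JAGS through rjags — the standard tooling for state-space stock models.
* ``backend="emcee"``: an affine-invariant ensemble sampler over the
  package's own :func:`log_posterior`, useful for small problems and for
  validating the posterior assembly (e.g. prior-only sampling).

Both are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _jags
from .observation import ObservationSet, log_likelihood
from .process import simulate_forward
from .structures import AgeStructure, Covariates, ObservationParams, ParameterSet, ProcessShocks

__all__ = [
    "PriorSpec",
    "FitConfig",
    "Latents",
    "PosteriorSamples",
    "ConvergenceReport",
    "log_posterior",
    "fit",
    "convergence_report",
    "audit_uniform_uppers",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    Informative lognormals on the density-independent mortalities (medians
    0.425 and 0.2, log-scale variance 0.5), vague variance-1000 normals on
    log-catchabilities (means -25 for eggs/larvae, 0 otherwise) and on the
    selectivities (mean -1.6, truncated negative) and temperature effect,
    and Uniform(0, upper) on the density-dependence coefficients and all
    SDs.  The uniform uppers must not be approached by the posterior; see
    :func:`audit_uniform_uppers`.
    """

    m0_median: float = 0.425
    m0_logvar: float = 0.5
    mj_median: float = 0.2
    mj_logvar: float = 0.5
    beta0_upper: float = 1.0e-8
    beta_upper: tuple[float, float, float] = (2.0e-9, 2.0e-9, 2.0e-9)
    gamma_mean: float = 0.0
    gamma_var: float = 1000.0
    s_mean: float = -1.6
    s_var: float = 1000.0
    logq_var: float = 1000.0
    logq_stage_means: tuple[float, float, float] = (-25.0, -25.0, 0.0)  # egg, larv, 0g
    sigma_upper: dict = field(default_factory=lambda: {
        "sigma_E": 2.0, "sigma_O": 2.0, "sigma_U": 1.0, "sigma_C": 1.0,
        "sigma_year": 1.0, "sigma_I": 2.0, "sigma_stage": 2.5})
    logN_init_mean: float = 20.7   # log individuals, ~1e9
    logN_init_var: float = 1000.0


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    The desk profile (default) keeps runs tractable on one CPU; the
    published-scale profile reproduces the original settings (3 chains,
    250k burn-in, 250k iterations thinned by 1000, 750 retained draws).
    """

    backend: str = "jags"
    n_chains: int = 3
    n_adapt: int = 500
    burn_in: int = 2000
    n_iter: int = 2000
    thin: int = 1
    seed: int = 0
    monitor_latent: bool = True
    n_walkers: int | None = None   # emcee only; default 2*ndim rounded up

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for convergence diagnostics")
        if self.backend not in ("jags", "emcee"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "FitConfig":
        return cls(seed=seed, **kw)

    @classmethod
    def published_scale(cls, seed: int = 0) -> "FitConfig":
        return cls(n_chains=3, n_adapt=10000, burn_in=250000, n_iter=250000,
                   thin=1000, seed=seed)

    def config_hash(self, priors: PriorSpec) -> str:
        payload = repr((self, priors)).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class Latents:
    """Latent stochastic quantities conditioned on during posterior evaluation."""

    log_N_init: np.ndarray  # (A,), first-year log abundances
    eps_E: np.ndarray       # (Y,), spawning shocks
    eps_O: np.ndarray       # (Y-1,), 0-group survival shocks (transition years)
    u_innov: np.ndarray     # (Y-1,), effort innovations entering years 2..Y
    delta: np.ndarray       # (Y,), winter-survey year effects

    @classmethod
    def zeros(cls, structure: AgeStructure, log_N_init: np.ndarray | None = None) -> "Latents":
        A, Y = structure.max_age, structure.n_years
        if log_N_init is None:
            log_N_init = np.full(A, 20.7)
        return cls(np.asarray(log_N_init, float), np.zeros(Y), np.zeros(Y - 1),
                   np.zeros(Y - 1), np.zeros(Y))


def _norm_logpdf(x, sd):
    x = np.asarray(x, float)
    return float(np.sum(-0.5 * _LOG2PI - np.log(sd) - 0.5 * (x / sd) ** 2))


def _lognorm_prior_logpdf(x: float, median: float, logvar: float) -> float:
    if x <= 0:
        return -np.inf
    v = logvar
    return -np.log(x) - 0.5 * (_LOG2PI + np.log(v)) - (np.log(x) - np.log(median)) ** 2 / (2 * v)


def _uniform_logpdf(x: float, upper: float) -> float:
    return -np.log(upper) if 0.0 <= x <= upper else -np.inf


from functools import lru_cache


@lru_cache(maxsize=32)
def _neg_trunc_lognorm_const(mean: float, sd: float) -> float:
    from scipy.stats import norm
    return float(norm.logcdf(-mean / sd))


def _trunc_neg_normal_logpdf(x: float, mean: float, var: float) -> float:
    """Normal(mean, var) restricted to x < 0."""
    if x >= 0:
        return -np.inf
    sd = float(np.sqrt(var))
    lp = -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2
    return float(lp - _neg_trunc_lognorm_const(mean, sd))


def log_prior(params: ParameterSet, latents: Latents, priors: PriorSpec,
              structure: AgeStructure) -> float:
    """Sum of the prior log-densities of all estimated parameters and initials."""
    p, op = params, params.obs
    lp = _lognorm_prior_logpdf(p.M0, priors.m0_median, priors.m0_logvar)
    lp += _lognorm_prior_logpdf(p.MJ, priors.mj_median, priors.mj_logvar)
    lp += _uniform_logpdf(p.beta0, priors.beta0_upper)
    for b, up in zip(p.beta, priors.beta_upper):
        lp += _uniform_logpdf(b, up)
    lp += _norm_logpdf(p.gamma - priors.gamma_mean, np.sqrt(priors.gamma_var))
    su = priors.sigma_upper
    for name, val, key in (("sigma_E", p.sigma_E, "sigma_E"), ("sigma_O", p.sigma_O, "sigma_O"),
                           ("sigma_U", p.sigma_U, "sigma_U"), ("sigma_C", op.sigma_C, "sigma_C"),
                           ("sigma_year", op.sigma_year, "sigma_year"),
                           ("sigma_egg", op.sigma_egg, "sigma_stage"),
                           ("sigma_larv", op.sigma_larv, "sigma_stage"),
                           ("sigma_0g", op.sigma_0g, "sigma_stage")):
        if val <= 0:
            return -np.inf
        lp += _uniform_logpdf(val, su[key])
    for sig in op.sigma_I[: structure.max_age]:
        if sig <= 0:
            return -np.inf
        lp += _uniform_logpdf(sig, su["sigma_I"])
    for sa in p.s:
        lp += _trunc_neg_normal_logpdf(sa, priors.s_mean, priors.s_var)
    lq_sd = np.sqrt(priors.logq_var)
    me, ml, m0g = priors.logq_stage_means
    lp += _norm_logpdf(np.log(op.q_egg) - me, lq_sd)
    lp += _norm_logpdf(np.log(op.q_larv) - ml, lq_sd)
    lp += _norm_logpdf(np.log(op.q_0g) - m0g, lq_sd)
    for q in (*op.q_pre, *op.q_post, *op.q_age[: structure.max_age - 2]):
        lp += _norm_logpdf(np.log(q), lq_sd)
    lp += _norm_logpdf(latents.log_N_init - priors.logN_init_mean, np.sqrt(priors.logN_init_var))
    return float(lp)


def _process_log_density(params: ParameterSet, latents: Latents) -> float:
    """Log-density of the process shocks and year effects given the SDs."""
    p, op = params, params.obs
    if min(p.sigma_E, p.sigma_O, p.sigma_U, op.sigma_year) <= 0:
        return -np.inf
    return (_norm_logpdf(latents.eps_E, p.sigma_E)
            + _norm_logpdf(latents.eps_O, p.sigma_O)
            + _norm_logpdf(latents.u_innov, p.sigma_U)
            + _norm_logpdf(latents.delta, op.sigma_year))


def log_posterior(
    params: ParameterSet,
    latents: Latents,
    obs: ObservationSet,
    covariates: Covariates,
    priors: PriorSpec,
) -> float:
    """Unnormalised joint log-posterior: likelihood + process terms + priors.

    Out-of-support parameters return -inf.  The latent trajectory is the
    deterministic image of (initial abundances, shocks), so conditioning on
    ``latents`` fully determines the states entering the likelihood.
    """
    st = obs.structure
    try:
        lp = log_prior(params, latents, priors, st)
    except ValueError:
        return -np.inf
    if not np.isfinite(lp):
        return -np.inf
    lp += _process_log_density(params, latents)
    if not np.isfinite(lp):
        return -np.inf
    if obs.n_observed() > 0:
        Y = st.n_years
        shocks = ProcessShocks(
            eps_E=latents.eps_E,
            eps_O=np.concatenate([latents.eps_O, [0.0]]),
            u_innov=np.concatenate([[0.0], latents.u_innov]))
        with np.errstate(over="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                state = simulate_forward(params, covariates, np.exp(latents.log_N_init),
                                         structure=st, shocks=shocks)
            ll = log_likelihood(state, obs, params, delta_year=latents.delta)
        if not np.isfinite(ll):
            return -np.inf
        lp += ll
    return float(lp)


# ---------------------------------------------------------------------------
# posterior container and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """MCMC draws keyed by canonical parameter name, shape (chain, draw)."""

    params: dict
    latent: dict
    metadata: dict

    def names(self) -> list[str]:
        return list(self.params)

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated."""
        arr = self.params[name] if name in self.params else self.latent[name]
        return arr.reshape(-1, *arr.shape[2:])

    def median(self, name: str) -> float:
        return float(np.median(self.stacked(name)))

    def quantiles(self, name: str, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        return np.quantile(self.stacked(name), qs, axis=0)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.params:
            lo, med, hi = self.quantiles(name)
            rows.append({"parameter": name, "median": med, "q2.5": lo, "q97.5": hi,
                         "mean": float(self.stacked(name).mean())})
        return pd.DataFrame(rows).set_index("parameter")

    def to_dataframe(self) -> pd.DataFrame:
        """Long format with chain and iteration identifiers."""
        n_chain, n_draw = next(iter(self.params.values())).shape
        cols = {"chain": np.repeat(np.arange(n_chain), n_draw),
                "iteration": np.tile(np.arange(n_draw), n_chain)}
        for name, arr in self.params.items():
            cols[name] = arr.reshape(-1)
        return pd.DataFrame(cols)


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    cross_correlation: pd.DataFrame

    @property
    def passed(self) -> bool:
        return bool(self.table[["rhat_ok", "geweke_ok", "autocorr_ok"]].all().all())


def _spectral_se(x: np.ndarray) -> float:
    """Standard error of the mean allowing for autocorrelation (windowed)."""
    n = x.size
    x = x - x.mean()
    K = min(max(n // 10, 1), 50)
    g0 = float(np.dot(x, x)) / n
    acc = g0
    for k in range(1, K + 1):
        acc += 2.0 * float(np.dot(x[:-k], x[k:])) / n
    return float(np.sqrt(max(acc, g0 * 0.01) / n))


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    n = x.size
    a, b = x[: max(int(first * n), 2)], x[-max(int(last * n), 2):]
    se = np.hypot(_spectral_se(a), _spectral_se(b))
    return float((a.mean() - b.mean()) / se) if se > 0 else 0.0


def _lag1(x: np.ndarray) -> float:
    if np.allclose(x, x[0]):
        return 0.0
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def convergence_report(samples: PosteriorSamples, names: list[str] | None = None,
                       rhat_limit: float = 1.05, z_limit: float = 2.0,
                       autocorr_limit: float = 0.2) -> ConvergenceReport:
    """Split-chain R-hat, Geweke z, lag-1 autocorrelation, ESS, cross-correlations.

    Pass criteria: R-hat < 1.05, max |Geweke z| < 2 per chain, mean lag-1
    autocorrelation of the retained (thinned) draws < 0.2.
    """
    import arviz as az

    names = names or samples.names()
    rows = []
    single_chain_warned = False
    for name in names:
        arr = samples.params[name]
        if arr.shape[0] >= 2:
            rhat = float(az.rhat(arr))
            ess = float(az.ess(arr))
        else:
            rhat, ess = np.nan, float(az.ess(arr))
            single_chain_warned = True
        z = max((abs(_geweke_z(c)) for c in arr), default=np.nan)
        ac = float(np.mean([_lag1(c) for c in arr]))
        rows.append({"parameter": name, "rhat": rhat, "ess": ess, "geweke_z": z,
                     "lag1_autocorr": ac,
                     "rhat_ok": bool(rhat < rhat_limit) if np.isfinite(rhat) else False,
                     "geweke_ok": bool(z < z_limit),
                     "autocorr_ok": bool(ac < autocorr_limit)})
    if single_chain_warned:
        warnings.warn("R-hat unavailable with a single chain", RuntimeWarning)
    table = pd.DataFrame(rows).set_index("parameter")
    flat = np.column_stack([samples.stacked(n) for n in names])
    with np.errstate(invalid="ignore"):
        cc = np.corrcoef(flat, rowvar=False)
    cross = pd.DataFrame(cc, index=names, columns=names)
    return ConvergenceReport(table, cross)


def audit_uniform_uppers(samples: PosteriorSamples, priors: PriorSpec,
                         threshold: float = 0.95) -> pd.DataFrame:
    """Check that no Uniform-prior parameter crowds its upper bound.

    Issues a warning for any parameter whose maximum draw exceeds
    ``threshold`` times the bound (the bound would then be informative and
    must be raised).
    """
    su = priors.sigma_upper
    bounds = {"beta0": priors.beta0_upper,
              "beta1": priors.beta_upper[0], "beta2": priors.beta_upper[1],
              "beta3": priors.beta_upper[2],
              "sigma_E": su["sigma_E"], "sigma_O": su["sigma_O"], "sigma_U": su["sigma_U"],
              "sigma_C": su["sigma_C"], "sigma_year": su["sigma_year"],
              "sigma_egg": su["sigma_stage"], "sigma_larv": su["sigma_stage"],
              "sigma_0g": su["sigma_stage"]}
    for name in samples.names():
        if name.startswith("sigma_I"):
            bounds[name] = su["sigma_I"]
    rows = []
    for name, bound in bounds.items():
        if name not in samples.params:
            continue
        mx = float(samples.stacked(name).max())
        ok = mx < threshold * bound
        if not ok:
            warnings.warn(f"posterior for {name} approaches its uniform upper bound "
                          f"({mx:.3g} vs {bound:.3g}); raise the bound", RuntimeWarning)
        rows.append({"parameter": name, "upper": bound, "max_draw": mx, "ok": ok})
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(
    obs: ObservationSet,
    covariates: Covariates,
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
    constants: ParameterSet | None = None,
) -> PosteriorSamples:
    """Sample the joint posterior given observations and covariates.

    ``constants`` supplies the fixed quantities (fecundity, egg and larval
    mortalities and stage durations, adult natural mortality); its
    estimated entries are ignored.  Metadata records the seed, backend,
    config hash, and a convergence flag from a quick diagnostic pass.
    """
    priors = priors or PriorSpec()
    config = config or FitConfig()
    constants = constants or ParameterSet()
    logger.info("fit: backend=%s seed=%d config_hash=%s", config.backend, config.seed,
                config.config_hash(priors))
    if config.backend == "jags":
        samples = _fit_jags(obs, covariates, priors, config, constants)
    else:
        samples = _fit_emcee(obs, covariates, priors, config, constants)
    key = [n for n in ("M0", "MJ", "beta0", "beta1", "beta2", "beta3", "sigma_E", "sigma_O")
           if n in samples.params]
    try:
        report = convergence_report(samples, key)
        samples.metadata["converged"] = report.passed
        if not report.passed:
            warnings.warn("convergence diagnostics failed for some parameters; "
                          "inspect convergence_report()", RuntimeWarning)
    except Exception:  # diagnostics must never mask the fit itself
        samples.metadata["converged"] = None
    return samples


def _canonical_names(structure: AgeStructure) -> dict:
    """Map JAGS variable/index to canonical parameter names."""
    A, ra = structure.max_age, structure.recruit_age
    mapping = {}
    for k in range(A - ra + 1):
        mapping[("s", k)] = f"s{ra + k}"
    slot_names = ["log_q_pre1", "log_q_pre2", "log_q_post1", "log_q_post2"] + [
        f"log_q_age{a}" for a in range(3, A + 1)]
    for j, nm in enumerate(slot_names):
        mapping[("lq", j)] = nm
    return mapping


def _fit_jags(obs, covariates, priors, config, constants) -> PosteriorSamples:
    st = obs.structure
    regime_year = constants.obs.regime_year
    data = _jags.prepare_jags_data(obs, covariates, constants, priors, regime_year)
    code = _jags.build_jags_model(
        st, has_landings="nL" in data, has_winter="nW" in data,
        has_egg="nE" in data, has_larv="nLa" in data, has_0g="nO" in data)
    raw = _jags.run_jags(data, code, priors, config.n_chains, config.n_adapt,
                         config.burn_in, config.n_iter, config.thin, config.seed,
                         monitor_latent=config.monitor_latent)
    A, Y, ra = st.max_age, st.n_years, st.recruit_age
    params: dict = {}
    simple = {"M0": "M0", "MJ": "MJ", "beta0": "beta0", "gamma": "gamma",
              "sigE": "sigma_E", "sigO": "sigma_O", "sigU": "sigma_U", "sigC": "sigma_C",
              "sigYr": "sigma_year", "sigEo": "sigma_egg", "sigLo": "sigma_larv",
              "sigOo": "sigma_0g", "lq0": "log_q_0g", "lqE": "log_q_egg", "lqL": "log_q_larv"}
    for jn, cn in simple.items():
        params[cn] = raw[jn]
    for j in range(3):
        params[f"beta{j + 1}"] = raw["betaJ"][:, :, j]
    for a in range(A):
        params[f"sigma_I{a + 1}"] = raw["sigI"][:, :, a]
    names = _canonical_names(st)
    for k in range(A - ra + 1):
        params[names[("s", k)]] = raw["s"][:, :, k]
    for j in range(data["nq"]):
        params[names[("lq", j)]] = raw["lq"][:, :, j]
    latent: dict = {}
    if config.monitor_latent:
        nc, nd = raw["N"].shape[:2]
        F_full = np.zeros((nc, nd, A, Y))
        F_full[:, :, ra - 1:, :] = raw["Ff"]
        C_full = np.zeros((nc, nd, A, Y))
        C_full[:, :, ra - 1:, :] = raw["C"]
        latent = {"N": raw["N"], "SSB": raw["SSB"], "eggs": raw["E"], "larvae": raw["Lar"],
                  "zerogroup": raw["O"], "U": raw["U"], "F": F_full, "catch": C_full,
                  "S0": raw["S0"], "eps_E": raw["epsE"], "eps_O": raw["epsO"],
                  "delta": raw["delta"]}
    meta = {"backend": "jags", "seed": config.seed, "n_chains": config.n_chains,
            "burn_in": config.burn_in, "n_iter": config.n_iter, "thin": config.thin,
            "config_hash": config.config_hash(priors), "structure": st}
    return PosteriorSamples(params, latent, meta)


# --- emcee backend ---------------------------------------------------------

class _VectorModel:
    """Flat-vector view of (parameters, latents) for ensemble sampling."""

    def __init__(self, obs: ObservationSet, covariates: Covariates, priors: PriorSpec,
                 constants: ParameterSet):
        self.obs = obs
        self.cov = covariates
        self.priors = priors
        self.constants = constants
        st = obs.structure
        self.st = st
        A, Y, ra = st.max_age, st.n_years, st.recruit_age
        self.param_names = (
            ["M0", "MJ", "beta0", "beta1", "beta2", "beta3", "gamma",
             "sigma_E", "sigma_O", "sigma_U", "sigma_C", "sigma_year"]
            + [f"sigma_I{a}" for a in range(1, A + 1)]
            + ["sigma_egg", "sigma_larv", "sigma_0g"]
            + [f"s{a}" for a in range(ra, A + 1)]
            + ["log_q_pre1", "log_q_pre2", "log_q_post1", "log_q_post2"]
            + [f"log_q_age{a}" for a in range(3, A + 1)]
            + ["log_q_0g", "log_q_egg", "log_q_larv"])
        self.n_params = len(self.param_names)
        # shock blocks are stored standardised (non-centred): eps = sigma * z.
        # This removes the sigma-shock funnel that cripples ensemble moves.
        self.latent_blocks = [("log_N_init", A), ("z_eps_E", Y), ("z_eps_O", Y - 1),
                              ("z_u", Y - 1), ("z_delta", Y)]
        self.ndim = self.n_params + sum(n for _, n in self.latent_blocks)
        self.has_data = obs.n_observed() > 0
        self._ix = {n: i for i, n in enumerate(self.param_names)}

    # -- packing ------------------------------------------------------------
    def unpack(self, x: np.ndarray) -> tuple[ParameterSet, Latents]:
        st, ix = self.st, self._ix
        A, ra = st.max_age, st.recruit_age
        g = lambda n: float(x[ix[n]])
        n_q_age = A - 2
        obs_params = replace(
            self.constants.obs,
            sigma_C=g("sigma_C"), sigma_year=g("sigma_year"),
            sigma_I=tuple(x[ix["sigma_I1"]: ix["sigma_I1"] + A]) + tuple(self.constants.obs.sigma_I[A:]),
            sigma_egg=g("sigma_egg"), sigma_larv=g("sigma_larv"), sigma_0g=g("sigma_0g"),
            q_pre=(np.exp(g("log_q_pre1")), np.exp(g("log_q_pre2"))),
            q_post=(np.exp(g("log_q_post1")), np.exp(g("log_q_post2"))),
            q_age=tuple(np.exp(x[ix["log_q_age3"]: ix["log_q_age3"] + n_q_age])),
            q_0g=np.exp(g("log_q_0g")), q_egg=np.exp(g("log_q_egg")),
            q_larv=np.exp(g("log_q_larv")))
        params = replace(
            self.constants,
            M0=g("M0"), MJ=g("MJ"), beta0=g("beta0"),
            beta=(g("beta1"), g("beta2"), g("beta3")), gamma=g("gamma"),
            sigma_E=g("sigma_E"), sigma_O=g("sigma_O"), sigma_U=g("sigma_U"),
            s=tuple(x[ix[f"s{ra}"]: ix[f"s{ra}"] + (A - ra + 1)]),
            obs=obs_params)
        off = self.n_params
        z = {}
        for name, n in self.latent_blocks:
            z[name] = np.array(x[off: off + n])
            off += n
        latents = Latents(
            log_N_init=z["log_N_init"],
            eps_E=params.sigma_E * z["z_eps_E"],
            eps_O=params.sigma_O * z["z_eps_O"],
            u_innov=params.sigma_U * z["z_u"],
            delta=obs_params.sigma_year * z["z_delta"])
        return params, latents

    def _jacobian(self, params: ParameterSet) -> float:
        """log |d eps / d z| for the non-centred shock blocks."""
        Y = self.st.n_years
        op = params.obs
        if min(params.sigma_E, params.sigma_O, params.sigma_U, op.sigma_year) <= 0:
            return -np.inf
        return (Y * np.log(params.sigma_E) + (Y - 1) * np.log(params.sigma_O)
                + (Y - 1) * np.log(params.sigma_U) + Y * np.log(op.sigma_year))

    def log_posterior(self, x: np.ndarray) -> float:
        """Posterior density in the sampling (non-centred) coordinates."""
        try:
            params, latents = self.unpack(x)
        except ValueError:
            return -np.inf
        jac = self._jacobian(params)
        if not np.isfinite(jac):
            return -np.inf
        return log_posterior(params, latents, self.obs, self.cov, self.priors) + jac

    def log_posterior_batch(self, X: np.ndarray) -> np.ndarray:
        """Vectorised evaluation over walker rows.

        Without observations the posterior is the prior times the process
        densities, all of which vectorise; this path must agree with
        :meth:`log_posterior` exactly (covered by a consistency test).
        """
        X = np.atleast_2d(X)
        if self.has_data:
            return np.array([self.log_posterior(x) for x in X])
        return self._prior_only_batch(X)

    def _prior_only_batch(self, X: np.ndarray) -> np.ndarray:
        pr, st, ix = self.priors, self.st, self._ix
        A, ra = st.max_age, st.recruit_age
        n = X.shape[0]
        lp = np.zeros(n)

        def col(name):
            return X[:, ix[name]]

        def lognorm(x, median, logvar):
            out = np.full(n, -np.inf)
            ok = x > 0
            out[ok] = (-np.log(x[ok]) - 0.5 * (_LOG2PI + np.log(logvar))
                       - (np.log(x[ok]) - np.log(median)) ** 2 / (2 * logvar))
            return out

        def unif(x, upper):
            return np.where((x >= 0) & (x <= upper), -np.log(upper), -np.inf)

        def norm(x, mean, sd):
            return -0.5 * _LOG2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2

        lp += lognorm(col("M0"), pr.m0_median, pr.m0_logvar)
        lp += lognorm(col("MJ"), pr.mj_median, pr.mj_logvar)
        lp += unif(col("beta0"), pr.beta0_upper)
        for j in range(3):
            lp += unif(col(f"beta{j + 1}"), pr.beta_upper[j])
        lp += norm(col("gamma"), pr.gamma_mean, np.sqrt(pr.gamma_var))
        su = pr.sigma_upper
        sigma_cols = [("sigma_E", "sigma_E"), ("sigma_O", "sigma_O"), ("sigma_U", "sigma_U"),
                      ("sigma_C", "sigma_C"), ("sigma_year", "sigma_year"),
                      ("sigma_egg", "sigma_stage"), ("sigma_larv", "sigma_stage"),
                      ("sigma_0g", "sigma_stage")] + [
                      (f"sigma_I{a}", "sigma_I") for a in range(1, A + 1)]
        for name, key in sigma_cols:
            x = col(name)
            lp += np.where(x > 0, unif(x, su[key]), -np.inf)
        s_sd = np.sqrt(pr.s_var)
        for a in range(ra, A + 1):
            x = col(f"s{a}")
            lp += np.where(x < 0, norm(x, pr.s_mean, s_sd)
                           - _neg_trunc_lognorm_const(pr.s_mean, s_sd), -np.inf)
        lq_sd = np.sqrt(pr.logq_var)
        me, ml, m0g = pr.logq_stage_means
        for name, mean in ([("log_q_egg", me), ("log_q_larv", ml), ("log_q_0g", m0g),
                            ("log_q_pre1", 0.0), ("log_q_pre2", 0.0),
                            ("log_q_post1", 0.0), ("log_q_post2", 0.0)]
                           + [(f"log_q_age{a}", 0.0) for a in range(3, A + 1)]):
            lp += norm(col(name), mean, lq_sd)
        off = self.n_params
        for name, m in self.latent_blocks:
            block = X[:, off: off + m]
            off += m
            if name == "log_N_init":
                lp += norm(block, pr.logN_init_mean, np.sqrt(pr.logN_init_var)).sum(axis=1)
            else:
                # standardised shocks: the sigma scaling and its Jacobian
                # cancel into a unit normal
                lp += norm(block, 0.0, 1.0).sum(axis=1)
        return lp

    # -- initialisation ------------------------------------------------------
    def initial_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pr, st = self.priors, self.st
        A, Y, ra = st.max_age, st.n_years, st.recruit_age
        pts = np.empty((n, self.ndim))
        ix = self._ix
        pts[:, ix["M0"]] = pr.m0_median * np.exp(rng.normal(0, 0.3, n))
        pts[:, ix["MJ"]] = pr.mj_median * np.exp(rng.normal(0, 0.3, n))
        pts[:, ix["beta0"]] = rng.uniform(0.05, 0.5, n) * pr.beta0_upper
        for j in range(3):
            pts[:, ix[f"beta{j + 1}"]] = rng.uniform(0.05, 0.5, n) * pr.beta_upper[j]
        pts[:, ix["gamma"]] = rng.normal(pr.gamma_mean, 0.01, n)
        su = pr.sigma_upper
        for nm, key in (("sigma_E", "sigma_E"), ("sigma_O", "sigma_O"), ("sigma_U", "sigma_U"),
                        ("sigma_C", "sigma_C"), ("sigma_year", "sigma_year"),
                        ("sigma_egg", "sigma_stage"), ("sigma_larv", "sigma_stage"),
                        ("sigma_0g", "sigma_stage")):
            pts[:, ix[nm]] = rng.uniform(0.1, 0.6, n) * su[key]
        for a in range(1, A + 1):
            pts[:, ix[f"sigma_I{a}"]] = rng.uniform(0.1, 0.6, n) * su["sigma_I"]
        for a in range(ra, A + 1):
            pts[:, ix[f"s{a}"]] = np.minimum(-0.05, pr.s_mean + rng.normal(0, 0.5, n))
        for nm, mean in (("log_q_pre1", -17), ("log_q_pre2", -17), ("log_q_post1", -17),
                         ("log_q_post2", -17), ("log_q_0g", -21),
                         ("log_q_egg", -25), ("log_q_larv", -25)):
            pts[:, ix[nm]] = rng.normal(mean, 1.0, n)
        for a in range(3, A + 1):
            pts[:, ix[f"log_q_age{a}"]] = rng.normal(-17, 1.0, n)
        off = self.n_params
        for name, m in self.latent_blocks:
            scale = 0.5 if name == "log_N_init" else 0.8
            center = pr.logN_init_mean if name == "log_N_init" else 0.0
            pts[:, off: off + m] = rng.normal(center, scale, (n, m))
            off += m
        return pts


def _fit_emcee(obs, covariates, priors, config, constants) -> PosteriorSamples:
    import emcee

    vm = _VectorModel(obs, covariates, priors, constants)
    rng = np.random.default_rng(config.seed)
    n_walkers = config.n_walkers or max(2 * vm.ndim + 2, 4 * config.n_chains)
    n_walkers += n_walkers % 2
    p0 = vm.initial_points(n_walkers, rng)
    sampler = emcee.EnsembleSampler(
        n_walkers, vm.ndim, vm.log_posterior_batch, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)])
    sampler.random_state = np.random.RandomState(config.seed % (2**31)).get_state()
    state = sampler.run_mcmc(p0, config.burn_in, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, config.n_iter, thin_by=config.thin,
                     skip_initial_state_check=True)
    chain = sampler.get_chain()  # (step, walker, dim)
    # fold walkers into pseudo-chains for diagnostics
    n_steps = chain.shape[0]
    per = n_walkers // config.n_chains
    params: dict = {}
    for i, name in enumerate(vm.param_names):
        arr = chain[:, : per * config.n_chains, i]
        params[name] = arr.T.reshape(config.n_chains, per * n_steps)
    latent: dict = {}
    off = vm.n_params
    for name, m in vm.latent_blocks:
        arr = chain[:, : per * config.n_chains, off: off + m]
        latent[name] = np.transpose(arr, (1, 0, 2)).reshape(
            config.n_chains, per * n_steps, m)
        off += m
    meta = {"backend": "emcee", "seed": config.seed, "n_chains": config.n_chains,
            "n_walkers": n_walkers, "burn_in": config.burn_in, "n_iter": config.n_iter,
            "thin": config.thin, "config_hash": config.config_hash(priors),
            "structure": obs.structure,
            "acceptance_fraction": float(np.mean(sampler.acceptance_fraction))}
    return PosteriorSamples(params, latent, meta)
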