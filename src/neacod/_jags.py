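"""JAGS backend: model-code generation, data marshalling, and the Rscript bridge.

The hierarchical model is expressed in the BUGS language and sampled with
JAGS (via rjags).  Data and initial values travel as JSON; posterior draws
come back as one CSV matrix per chain.  Everything here is deterministic
given the seed: chain c uses RNG seed ``seed*1000 + c``.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .observation import ObservationSet
from .structures import AgeStructure, Covariates, ParameterSet

__all__ = ["build_jags_model", "prepare_jags_data", "run_jags"]

_RUNNER = Path(__file__).with_name("_jags_run.R")


def build_jags_model(structure: AgeStructure, has_landings: bool, has_winter: bool,
                     has_egg: bool, has_larv: bool, has_0g: bool) -> str:
    """Emit BUGS code for the life-cycle state-space model.

    Observation blocks are included only for data series that are present
    (a ``for (i in 1:0)`` loop would run in BUGS, so empty series must be
    dropped at code level).
    """
    if structure.dd_ages != (1, 2, 3):
        raise NotImplementedError("JAGS backend assumes intracohort density dependence at ages 1-3")
    if len(structure.cannibal_ages) != 2:
        raise NotImplementedError("JAGS backend assumes two cannibal ages")

    blocks = ["""model {
  # --- priors: mortalities and density dependence ---
  M0 ~ dlnorm(lm0_mu, lm0_tau)
  MJ ~ dlnorm(lmj_mu, lmj_tau)
  beta0 ~ dunif(0, beta0_up)
  for (j in 1:3) { betaJ[j] ~ dunif(0, betaJ_up[j]) }
  gamma ~ dnorm(g_mu, g_tau)
  # --- priors: process and observation SDs ---
  sigE ~ dunif(0, sE_up);    tauE <- pow(sigE, -2)
  sigO ~ dunif(0, sO_up);    tauO <- pow(sigO, -2)
  sigU ~ dunif(0, sU_up);    tauU <- pow(sigU, -2)
  sigC ~ dunif(0, sC_up);    tauC <- pow(sigC, -2)
  sigYr ~ dunif(0, sYr_up);  tauYr <- pow(sigYr, -2)
  for (a in 1:A) { sigI[a] ~ dunif(0, sI_up); tauI[a] <- pow(sigI[a], -2) }
  sigEo ~ dunif(0, sStage_up); tauEo <- pow(sigEo, -2)
  sigLo ~ dunif(0, sStage_up); tauLo <- pow(sigLo, -2)
  sigOo ~ dunif(0, sStage_up); tauOo <- pow(sigOo, -2)
  # --- priors: selectivity (negative) and log-catchabilities ---
  for (k in 1:m) { s[k] ~ dnorm(s_mu, s_tau) T(, 0) }
  for (j in 1:nq) { lq[j] ~ dnorm(0, lq_tau) }
  lq0 ~ dnorm(0, lq_tau)
  lqE ~ dnorm(-25, lq_tau)
  lqL ~ dnorm(-25, lq_tau)
  # --- initial abundances and effort random walk ---
  for (a in 1:A) { lnN1[a] ~ dnorm(n1_mu, n1_tau); N[a, 1] <- exp(lnN1[a]) }
  U[1] <- 0
  for (y in 2:Y) { U[y] ~ dnorm(U[y-1], tauU) }
  # --- within-year survey effect ---
  for (y in 1:Y) { delta[y] ~ dnorm(0, tauYr) }
  # --- process model ---
  for (y in 1:Y) {
    epsE[y] ~ dnorm(0, tauE)
    SSB[y] <- inprod(N[1:A, y], wp[1:A, y])
    E[y] <- fkg * SSB[y] * exp(epsE[y])
    Lar[y] <- E[y] * exp(-Megg * tEL)
    O[y] <- Lar[y] * exp(-(Mlarv - gamma * Tanom[y]) * tlarv - Mjuv * tjuv)
    for (k in 1:m) {
      Ff[k, y] <- exp(s[k] + U[y])
      C[k, y] <- N[RA - 1 + k, y] * Ff[k, y] / (Ff[k, y] + MA) * (1 - exp(-(Ff[k, y] + MA)))
    }
  }
  for (y in 1:(Y-1)) {
    epsO[y] ~ dnorm(0, tauO)
    S0[y] <- min(1, exp(-M0 + epsO[y]) / (1 + beta0 * (N[ci1, y] + N[ci2, y])))
    N[1, y+1] <- O[y] * S0[y]
    for (a in 1:3) { N[a+1, y+1] <- N[a, y] * exp(-MJ) / (1 + betaJ[a] * N[a, y]) }
    for (a in RA:(A-1)) { N[a+1, y+1] <- N[a, y] * exp(-(MA + Ff[a - RA + 1, y])) }
  }"""]
    if has_landings:
        blocks.append("""  # landings: mean-corrected lognormal around the Baranov catch
  for (i in 1:nL) {
    Lobs[i] ~ dlnorm(log(C[Lk[i], Lyy[i]]) - sigC * sigC / 2, tauC)
  }""")
    if has_winter:
        blocks.append("""  # winter bottom-trawl indices with shared year effect
  for (i in 1:nW) {
    Wobs[i] ~ dlnorm(lq[Wq[i]] + log(N[Wa[i], Wy[i]]) + delta[Wy[i]], tauI[Wa[i]])
  }""")
    if has_egg:
        blocks.append("""  for (i in 1:nE) { Eobs[i] ~ dlnorm(lqE + log(E[Ey[i]]), tauEo) }""")
    if has_larv:
        blocks.append("""  for (i in 1:nLa) { Laobs[i] ~ dlnorm(lqL + log(Lar[Lay[i]]), tauLo) }""")
    if has_0g:
        blocks.append("""  for (i in 1:nO) { Oobs[i] ~ dlnorm(lq0 + log(O[Oy[i]]), tauOo) }""")
    blocks.append("}")
    return "\n".join(blocks)


def winter_q_slot(age: int, year: int, regime_year: int) -> int:
    """1-based catchability slot: pre/post ages 1-2 first, then ages 3+."""
    if age == 1:
        return 1 if year < regime_year else 3
    if age == 2:
        return 2 if year < regime_year else 4
    return age + 2  # age 3 -> slot 5, ...


def prepare_jags_data(
    obs: ObservationSet,
    covariates: Covariates,
    constants: ParameterSet,
    priors,
    regime_year: int,
) -> dict:
    """Flatten observations into the index-vector form the BUGS code uses."""
    st = obs.structure
    Y, A = st.n_years, st.max_age
    ra = st.recruit_age
    years = st.years

    data: dict = {
        "Y": Y, "A": A, "RA": ra, "m": A - ra + 1,
        "ci1": int(st.cannibal_ages[0]), "ci2": int(st.cannibal_ages[1]),
        "nq": 4 + (A - 2),
        "wp": (covariates.weight * covariates.maturity).tolist(),
        "Tanom": covariates.temperature.tolist(),
        "fkg": constants.f_per_kg, "Megg": constants.M_egg, "tEL": constants.t_EL,
        "Mlarv": constants.M_larv_daily, "tlarv": constants.t_larv,
        "Mjuv": constants.M_juv_daily, "tjuv": constants.t_ejuv, "MA": constants.MA,
        # prior hyperparameters
        "lm0_mu": float(np.log(priors.m0_median)), "lm0_tau": 1.0 / priors.m0_logvar,
        "lmj_mu": float(np.log(priors.mj_median)), "lmj_tau": 1.0 / priors.mj_logvar,
        "beta0_up": priors.beta0_upper, "betaJ_up": list(priors.beta_upper),
        "g_mu": priors.gamma_mean, "g_tau": 1.0 / priors.gamma_var,
        "sE_up": priors.sigma_upper["sigma_E"], "sO_up": priors.sigma_upper["sigma_O"],
        "sU_up": priors.sigma_upper["sigma_U"], "sC_up": priors.sigma_upper["sigma_C"],
        "sYr_up": priors.sigma_upper["sigma_year"], "sI_up": priors.sigma_upper["sigma_I"],
        "sStage_up": priors.sigma_upper["sigma_stage"],
        "s_mu": priors.s_mean, "s_tau": 1.0 / priors.s_var,
        "lq_tau": 1.0 / priors.logq_var,
        "n1_mu": priors.logN_init_mean, "n1_tau": 1.0 / priors.logN_init_var,
    }

    m = obs.mask_landings
    ii, jj = np.nonzero(m)
    if ii.size:
        if np.any(ii + 1 < ra):
            raise ValueError("landings observed below the recruitment age")
        data.update(nL=int(ii.size), Lobs=obs.landings[m].tolist(),
                    Lk=(ii + 1 - ra + 1).tolist(), Lyy=(jj + 1).tolist())
    m = obs.mask_winter
    ii, jj = np.nonzero(m)
    if ii.size:
        slots = [winter_q_slot(int(a + 1), int(years[j]), regime_year) for a, j in zip(ii, jj)]
        data.update(nW=int(ii.size), Wobs=obs.index_winter[m].tolist(),
                    Wa=(ii + 1).tolist(), Wy=(jj + 1).tolist(), Wq=slots)
    for key, mask, vals, nname, vname, iname in (
        ("egg", obs.mask_egg, obs.index_egg, "nE", "Eobs", "Ey"),
        ("larv", obs.mask_larv, obs.index_larv, "nLa", "Laobs", "Lay"),
        ("0g", obs.mask_0g, obs.index_0g, "nO", "Oobs", "Oy"),
    ):
        jj = np.nonzero(mask)[0]
        if jj.size:
            data[nname] = int(jj.size)
            data[vname] = vals[mask].tolist()
            data[iname] = (jj + 1).tolist()
    return data


def _informed_inits(data: dict, priors, chain: int, seed: int) -> dict:
    """Starting values: prior centres plus data-informed catchability guesses."""
    rng = np.random.default_rng(seed * 1000 + 7919 + chain)
    A, Y, m, nq = data["A"], data["Y"], data["m"], data["nq"]
    n_guess = 1.25e9 * np.exp(-0.4 * np.arange(A))
    lq = np.full(nq, -17.0)
    if "nW" in data:
        wa = np.asarray(data["Wa"]) - 1
        wq = np.asarray(data["Wq"]) - 1
        wobs = np.log(np.asarray(data["Wobs"]))
        for slot in range(nq):
            sel = wq == slot
            if sel.any():
                lq[slot] = float(np.mean(wobs[sel] - np.log(n_guess[wa[sel]])))
    lq0 = 0.0
    if "nO" in data:
        lq0 = float(np.mean(np.log(data["Oobs"])) - np.log(5e9))
    lqE = -25.0 + (float(np.mean(np.log(data["Eobs"])) - np.log(2e14)) + 25.0 if "nE" in data else 0.0)
    lqL = -25.0 + (float(np.mean(np.log(data["Laobs"])) - np.log(2e12)) + 25.0 if "nLa" in data else 0.0)
    jit = lambda x, s: x * np.exp(rng.normal(0, s))
    inits = {
        "M0": jit(priors.m0_median, 0.2), "MJ": jit(priors.mj_median, 0.2),
        "beta0": priors.beta0_upper / 5 * np.exp(rng.normal(0, 0.3)),
        "betaJ": (np.array(priors.beta_upper) / 10 * np.exp(rng.normal(0, 0.3, 3))).tolist(),
        "gamma": float(rng.normal(0, 2e-3)),
        "sigE": 0.6, "sigO": 0.6, "sigU": 0.1, "sigC": 0.2, "sigYr": 0.2,
        "sigI": [0.4] * A, "sigEo": 0.5, "sigLo": 0.5, "sigOo": 0.6,
        "s": (np.minimum(-0.05, priors.s_mean + rng.normal(0, 0.2, m))).tolist(),
        "lq": lq.tolist(), "lq0": lq0, "lqE": lqE, "lqL": lqL,
        "lnN1": (np.log(n_guess) + rng.normal(0, 0.3, A)).tolist(),
        "epsE": [0.0] * Y, "epsO": [0.0] * (Y - 1),
        "delta": [0.0] * Y,
        "U": [None] + [0.0] * (Y - 1),
        ".RNG.name": "base::Mersenne-Twister",
        ".RNG.seed": int(seed * 1000 + chain),
    }
    return inits


_LATENT_MONITORS = ("N", "SSB", "E", "Lar", "O", "U", "Ff", "C", "S0", "epsE", "epsO", "delta")
PARAM_MONITORS = ("M0", "MJ", "beta0", "betaJ", "gamma", "sigE", "sigO", "sigU", "sigC",
                  "sigYr", "sigI", "sigEo", "sigLo", "sigOo", "s", "lq", "lq0", "lqE", "lqL")


def run_jags(
    data: dict,
    model_code: str,
    priors,
    n_chains: int,
    n_adapt: int,
    burn_in: int,
    n_iter: int,
    thin: int,
    seed: int,
    monitor_latent: bool = True,
    workdir: str | Path | None = None,
) -> dict[str, np.ndarray]:
    """Run JAGS through Rscript; return raw draws keyed by BUGS variable name.

    Each value has shape (chain, draw) for scalars or (chain, draw, *dims)
    for vector/matrix nodes.
    """
    monitors = list(PARAM_MONITORS) + (list(_LATENT_MONITORS) if monitor_latent else [])
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        td = Path(td)
        (td / "model.bug").write_text(model_code)
        (td / "data.json").write_text(json.dumps(data))
        inits = [_informed_inits(data, priors, c, seed) for c in range(1, n_chains + 1)]
        (td / "inits.json").write_text(json.dumps(inits))
        settings = {"n_chains": n_chains, "n_adapt": n_adapt, "burn_in": burn_in,
                    "n_iter": n_iter, "thin": thin, "monitors": monitors}
        (td / "settings.json").write_text(json.dumps(settings))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_RUNNER), str(td)],
            capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"JAGS run failed:\n{proc.stdout[-2000:]}\n{proc.stderr[-2000:]}")
        frames = [pd.read_csv(td / f"chain_{c}.csv") for c in range(1, n_chains + 1)]
    return _collect_draws(frames)


def _collect_draws(frames: list[pd.DataFrame]) -> dict[str, np.ndarray]:
    """Stack per-chain CODA matrices into (chain, draw, *dims) arrays."""
    cols = list(frames[0].columns)
    stacked = np.stack([f.to_numpy(float) for f in frames])  # (chain, draw, col)
    out: dict[str, np.ndarray] = {}
    groups: dict[str, list[tuple[tuple[int, ...], int]]] = {}
    for j, col in enumerate(cols):
        if "[" in col:
            base, idx = col.split("[", 1)
            indices = tuple(int(t) for t in idx.rstrip("]").split(","))
            groups.setdefault(base, []).append((indices, j))
        else:
            out[col] = stacked[:, :, j]
    for base, entries in groups.items():
        shape = tuple(max(e[0][d] for e in entries) for d in range(len(entries[0][0])))
        arr = np.full(stacked.shape[:2] + shape, np.nan)
        for indices, j in entries:
            arr[(slice(None), slice(None)) + tuple(i - 1 for i in indices)] = stacked[:, :, j]
        out[base] = arr
    return out
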