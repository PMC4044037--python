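"""Observation model: survey indices and reported landings.

True abundances and catches are latent; observations are lognormal around
catchability-scaled latents.  Landings carry a -sigma^2/2 bias correction so
their expectation equals the true catch; survey indices are left
uncorrected (the correction would only rescale the catchability estimates).
The winter bottom-trawl survey shares a random year effect across ages,
inducing within-year correlation of its residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import AgeStructure, LatentState, ObservationParams, ParameterSet

__all__ = [
    "ObservationSet",
    "observe_landings",
    "observe_winter_survey",
    "observe_stage_index",
    "log_likelihood",
]

_MISSING = np.nan


@dataclass
class ObservationSet:
    """Survey indices and landings with explicit missingness masks.

    Missing cells are encoded by masks (value arrays hold NaN there), never
    by zeros: all observed values must be strictly positive (lognormal
    support).  Landings cover the recruited ages only.
    """

    structure: AgeStructure
    landings: np.ndarray       # (A, Y); NaN where missing / below recruit age
    index_winter: np.ndarray   # (A, Y)
    index_egg: np.ndarray      # (Y,)
    index_larv: np.ndarray     # (Y,)
    index_0g: np.ndarray       # (Y,)
    mask_landings: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask_winter: np.ndarray = field(default=None)    # type: ignore[assignment]
    mask_egg: np.ndarray = field(default=None)       # type: ignore[assignment]
    mask_larv: np.ndarray = field(default=None)      # type: ignore[assignment]
    mask_0g: np.ndarray = field(default=None)        # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("landings", "index_winter", "index_egg", "index_larv", "index_0g"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            mname = "mask_" + {"landings": "landings", "index_winter": "winter",
                               "index_egg": "egg", "index_larv": "larv", "index_0g": "0g"}[name]
            mask = getattr(self, mname)
            mask = ~np.isnan(arr) if mask is None else np.asarray(mask, bool)
            if mask.shape != arr.shape:
                raise ValueError(f"mask shape mismatch for {name}")
            if np.any(mask & ~(arr > 0)):
                raise ValueError(f"non-positive or missing value in observed cells of {name}")
            setattr(self, mname, mask)

    def n_observed(self) -> int:
        return int(sum(m.sum() for m in (self.mask_landings, self.mask_winter,
                                         self.mask_egg, self.mask_larv, self.mask_0g)))


def observe_landings(C_true, sigma_C: float, rng: np.random.Generator):
    """Reported landings: lognormal error with mean corrected to the true catch.

    landings = C * exp(eps - sigma_C^2 / 2), eps ~ N(0, sigma_C^2), so
    E[landings] = C.  A zero true catch has no lognormal representation and
    yields a missing value (NaN).
    """
    C_true = np.asarray(C_true, float)
    if np.any(C_true < 0):
        raise ValueError("true catch must be >= 0")
    eps = rng.normal(0.0, sigma_C, C_true.shape)
    out = np.where(C_true > 0, C_true * np.exp(eps - 0.5 * sigma_C**2), _MISSING)
    return float(out) if out.ndim == 0 else out


def observe_winter_survey(
    N: np.ndarray,
    year: int,
    obs: ObservationParams,
    rng: np.random.Generator,
    delta: float | None = None,
) -> np.ndarray:
    """Winter bottom-trawl indices for ages 1..A in one survey year.

    I_a = q_eff(a, year) * N_a * exp(delta_y + eps_a): delta_y is the shared
    year effect (drawn here unless supplied), eps_a the age-specific error.
    Ages 1-2 switch catchability at the survey regime change.
    """
    N = np.asarray(N, float)
    A = N.shape[0]
    if delta is None:
        delta = rng.normal(0.0, obs.sigma_year)
    q = np.array([obs.q_winter(a, year, A) for a in range(1, A + 1)])
    sig = np.asarray(obs.sigma_I[:A], float)
    eps = rng.normal(0.0, 1.0, A) * sig
    return q * N * np.exp(delta + eps)


def observe_stage_index(stage_abundance, q_stage: float, sigma_stage: float,
                        rng: np.random.Generator):
    """Stage index (eggs, larvae or 0-group): I = q * abundance * exp(eps)."""
    x = np.asarray(stage_abundance, float)
    if np.any(x < 0):
        raise ValueError("stage abundance must be >= 0")
    eps = rng.normal(0.0, sigma_stage, x.shape)
    out = np.where(x > 0, q_stage * x * np.exp(eps), _MISSING)
    return float(out) if out.ndim == 0 else out


def _lognorm_logpdf(x, mu, sigma):
    """Log-density of LogNormal(mu, sigma^2) at x (> 0)."""
    x, mu = np.asarray(x, float), np.asarray(mu, float)
    return (-np.log(x) - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
            - 0.5 * ((np.log(x) - mu) / sigma) ** 2)


def log_likelihood(
    latent: LatentState,
    obs_set: ObservationSet,
    params: ParameterSet,
    delta_year: np.ndarray | None = None,
) -> float:
    """Total observation log-likelihood over observed cells only.

    The winter-survey year effects ``delta_year`` (one per model year) are
    conditioned on; they are latent variables integrated by the sampler
    during inference.  Omitting them evaluates at delta = 0.
    """
    st = latent.structure
    op = params.obs
    Y, A = st.n_years, st.max_age
    if obs_set.structure.n_years != Y or obs_set.index_winter.shape != (A, Y):
        raise ValueError("observation set does not match the latent dimensions")
    delta = np.zeros(Y) if delta_year is None else np.asarray(delta_year, float)

    total = 0.0
    # landings: mean-corrected lognormal around the true Baranov catch
    m = obs_set.mask_landings
    if m.any():
        mu = np.log(latent.catch[m]) - 0.5 * op.sigma_C**2
        total += float(np.sum(_lognorm_logpdf(obs_set.landings[m], mu, op.sigma_C)))
    # winter survey: q_eff * N with shared year effect
    years = st.years
    q_eff = np.empty((A, Y))
    for a in range(1, A + 1):
        for j, yr in enumerate(years):
            q_eff[a - 1, j] = op.q_winter(a, int(yr), A)
    m = obs_set.mask_winter
    if m.any():
        with np.errstate(divide="ignore"):
            mu = np.log(q_eff) + np.log(latent.N) + delta[None, :]
        sig = np.asarray(op.sigma_I[:A], float)[:, None] * np.ones((A, Y))
        total += float(np.sum(_lognorm_logpdf(obs_set.index_winter[m], mu[m], sig[m])))
    # stage indices
    for series, mask, q, sig, latent_arr in (
        ("egg", obs_set.mask_egg, op.q_egg, op.sigma_egg, latent.eggs),
        ("larv", obs_set.mask_larv, op.q_larv, op.sigma_larv, latent.larvae),
        ("0g", obs_set.mask_0g, op.q_0g, op.sigma_0g, latent.zerogroup),
    ):
        if mask.any():
            with np.errstate(divide="ignore"):
                mu = np.log(q) + np.log(latent_arr)
            total += float(np.sum(_lognorm_logpdf(getattr(obs_set, f"index_{series}")[mask], mu[mask], sig)))
    return total
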