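"""Downstream analyses of fitted or simulated trajectories.

Covers the compensation diagnostics: cohort survival from age 1 to 4 with
credible bands, recruits per 0-group, interannual variance of log abundance
by life stage (variance dampening), year-class strength ratios, bootstrap
correlations between abundance and a survival index built from observed
indices, and predicted age-class transition curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structures import LatentState, ParameterSet

__all__ = [
    "survival_1to4",
    "recruits_per_0group",
    "interannual_variance",
    "variance_by_stage",
    "yearclass_ratio",
    "bootstrap_survival_correlation",
    "predicted_ageclass_curve",
]


def _draws_from(params_or_samples) -> tuple[np.ndarray, np.ndarray]:
    """(MJ draws (n,), beta draws (n, 3)) from a ParameterSet or PosteriorSamples."""
    if isinstance(params_or_samples, ParameterSet):
        return np.array([params_or_samples.MJ]), np.array([params_or_samples.beta])
    s = params_or_samples
    MJ = s.stacked("MJ")
    beta = np.column_stack([s.stacked(f"beta{j}") for j in (1, 2, 3)])
    return MJ, beta


def survival_1to4(params_or_samples, N: np.ndarray,
                  first_year: int | None = None) -> pd.DataFrame:
    """Cohort survival from age 1 to age 4, per year, with credible band.

    For each draw the survival of the cohort aged 1 in year y is
    prod_{a=1..3} exp(-MJ) / (1 + beta_a * N[a, y+a-1]), following the
    cohort diagonally; evaluating per draw keeps the effect of parameter
    correlations in the band.  ``N`` is an (A, Y) abundance array (e.g. the
    posterior median trajectory or a simulated truth).  Years whose cohort
    runs off the series are omitted.
    """
    MJ, beta = _draws_from(params_or_samples)
    N = np.asarray(N, float)
    Y = N.shape[1]
    years = np.arange(Y - 2)
    # cohort abundances: ages 1..3 at years y, y+1, y+2
    Na = np.stack([N[a - 1, years + a - 1] for a in (1, 2, 3)])  # (3, n_years)
    if np.any(~np.isfinite(Na)):
        keep = np.all(np.isfinite(Na), axis=0)
        years, Na = years[keep], Na[:, keep]
    # (draws, 3, years)
    surv = np.exp(-3.0 * MJ)[:, None] / np.prod(1.0 + beta[:, :, None] * Na[None, :, :], axis=1)
    lo, med, hi = np.quantile(surv, [0.025, 0.5, 0.975], axis=0)
    out = pd.DataFrame({"year_age1": years + (first_year or 0), "median": med,
                        "q2.5": lo, "q97.5": hi})
    return out


def recruits_per_0group(state: LatentState) -> pd.DataFrame:
    """Recruits (age 4) per 0-group individual, by 0-group year."""
    st = state.structure
    ra = st.recruit_age
    Y = st.n_years
    rows = []
    for y in range(Y - ra):
        O = state.zerogroup[y]
        R = state.N[ra - 1, y + ra]
        rows.append({"year": int(st.years[y]), "zerogroup": O, "recruits": R,
                     "recruits_per_0group": R / O if O > 0 else np.nan})
    return pd.DataFrame(rows)


def interannual_variance(series: np.ndarray) -> float:
    """Sample variance (n-1 denominator) of the log of a positive series."""
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two values")
    if np.any(x <= 0):
        raise ValueError("series must be strictly positive")
    return float(np.var(np.log(x), ddof=1))


def variance_by_stage(state: LatentState, max_stage_age: int = 4) -> pd.DataFrame:
    """Interannual variance of log abundance for SSB, stages, and ages 1..4."""
    rows = [("ssb", interannual_variance(state.SSB)),
            ("eggs", interannual_variance(state.eggs)),
            ("larvae", interannual_variance(state.larvae)),
            ("zerogroup", interannual_variance(state.zerogroup))]
    for a in range(1, max_stage_age + 1):
        rows.append((f"age{a}", interannual_variance(state.N[a - 1])))
    return pd.DataFrame(rows, columns=["stage", "variance_log"])


def yearclass_ratio(series: np.ndarray) -> float:
    """Max/min ratio of a positive cohort-abundance series at one age."""
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty series")
    if np.any(x <= 0):
        raise ValueError("series must be strictly positive")
    return float(x.max() / x.min())


def bootstrap_survival_correlation(index: np.ndarray, age: int, n_boot: int = 10000,
                                   seed: int | None = None,
                                   prev_series: np.ndarray | None = None) -> dict:
    """Correlation between log abundance and a survival index, bootstrapped.

    The survival index of the focal age a in year y is the difference
    between the log indices of the *subsequent* and *previous* age-classes
    of the same cohort, log I[a+1, y+1] - log I[a-1, y-1].  Because the
    focal abundance index I[a, y] appears in neither term, its observation
    error is independent of the survival-index error and the correlation is
    not biased by shared noise.  Pearson correlation on logs; pairs are
    resampled with replacement.

    ``index`` is an (A, Y) matrix of survey indices with NaN for missing.
    For age 1 the previous age-class is the 0-group, whose index comes from
    a different survey: pass it as ``prev_series`` (length Y).  Returns the
    point estimate, bootstrap median and 2.5/97.5 percentiles.
    """
    I = np.asarray(index, float)
    A, Y = I.shape
    if not 1 <= age < A:
        raise ValueError(f"age must be in 1..{A - 1} (needs age+1 indices)")
    if age >= 2:
        prev = I[age - 2]
    elif prev_series is not None:
        prev = np.asarray(prev_series, float)
        if prev.shape != (Y,):
            raise ValueError("prev_series must cover the same years as the index matrix")
    else:
        raise ValueError("age 1 needs the 0-group index as prev_series")
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.log(I[age - 1, 1: Y - 1])
        s_prev = np.log(prev[: Y - 2])
        s_next = np.log(I[age, 2:])
    ok = np.isfinite(x) & np.isfinite(s_prev) & np.isfinite(s_next)
    x, surv = x[ok], s_next[ok] - s_prev[ok]
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 abundance-survival pairs, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], surv[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, (xc * yc).sum(axis=1) / denom, np.nan)
    lo, med, hi = np.nanpercentile(r, [2.5, 50, 97.5])
    point = float(np.corrcoef(x, surv)[0, 1])
    return {"age": age, "n_pairs": int(n), "r": point, "median": float(med),
            "q2.5": float(lo), "q97.5": float(hi), "n_boot": int(n_boot)}


def predicted_ageclass_curve(params_or_samples, age: int,
                             grid: np.ndarray) -> pd.DataFrame:
    """Predicted next-age abundance vs abundance at a juvenile age.

    Each MCMC draw contributes its own Beverton-Holt curve
    N_{a+1} = N_a exp(-MJ) / (1 + beta_a N_a), so the pointwise band
    reflects the joint (correlated) posterior of MJ and beta_a.  The curve
    saturates at exp(-MJ)/beta_a.
    """
    if age not in (1, 2, 3):
        raise ValueError("transition curves are defined for juvenile ages 1-3")
    MJ, beta = _draws_from(params_or_samples)
    grid = np.asarray(grid, float)
    b = beta[:, age - 1][:, None]
    curves = grid[None, :] * np.exp(-MJ)[:, None] / (1.0 + b * grid[None, :])
    lo, med, hi = np.quantile(curves, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame({"abundance": grid, "median": med, "q2.5": lo, "q97.5": hi})
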