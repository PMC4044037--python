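"""Domain containers for the life-cycle population model.

The model follows a cohort of Northeast Arctic cod from spawned eggs through
larvae, pelagic 0-group juveniles, demersal juveniles (ages 1-3) and adults
(ages 4-9, exploited by the fishery).  All abundances are in individuals,
spawning stock biomass (SSB) in kilograms, instantaneous mortalities in
day^-1 for the pre-settlement stages and year^-1 afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AgeStructure",
    "ObservationParams",
    "ParameterSet",
    "Covariates",
    "ProcessShocks",
    "LatentState",
]


@dataclass(frozen=True)
class AgeStructure:
    """Ages, years and the life-history role of each age class.

    Ages run 1..max_age with no plus group: fish surviving their year at
    ``max_age`` leave the model.  ``recruit_age`` is the age of recruitment
    to the fishery (fishing mortality is zero below it), ``cannibal_ages``
    are the ages preying on the 0-group, and ``dd_ages`` the ages whose
    outgoing survival is reduced by their own cohort's abundance.
    """

    first_year: int = 1959
    n_years: int = 52
    max_age: int = 9
    recruit_age: int = 4
    cannibal_ages: tuple[int, ...] = (3, 4)
    dd_ages: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if not (self.max_age >= self.recruit_age >= 1):
            raise ValueError("require max_age >= recruit_age >= 1")
        if self.n_years < 2:
            raise ValueError("need at least two years")
        if not all(1 <= a < self.max_age for a in self.dd_ages):
            raise ValueError("dd_ages must lie in [1, max_age)")
        if not all(1 <= a <= self.max_age for a in self.cannibal_ages):
            raise ValueError("cannibal_ages must lie in [1, max_age]")

    @property
    def years(self) -> np.ndarray:
        return self.first_year + np.arange(self.n_years)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(1, self.max_age + 1)

    @property
    def fished_ages(self) -> np.ndarray:
        return np.arange(self.recruit_age, self.max_age + 1)

    def year_index(self, year: int) -> int:
        idx = int(year) - self.first_year
        if not 0 <= idx < self.n_years:
            raise ValueError(f"year {year} outside {self.first_year}..{self.first_year + self.n_years - 1}")
        return idx

    def age_index(self, age: int) -> int:
        if not 1 <= age <= self.max_age:
            raise ValueError(f"age {age} outside 1..{self.max_age}")
        return int(age) - 1


@dataclass(frozen=True)
class ObservationParams:
    """Catchabilities and error SDs of the observation model.

    The winter bottom-trawl survey changed gear and coverage in 1993/1994;
    ages 1-2 therefore carry separate catchabilities before (``q_pre``) and
    from ``regime_year`` on (``q_post``).  ``sigma_year`` is the SD of the
    within-year random effect shared by all ages of the winter survey.
    """

    q_egg: float = float(np.exp(-25.0))
    q_larv: float = float(np.exp(-23.5))
    q_0g: float = 1.0e-9
    q_pre: tuple[float, float] = (4.0e-8, 6.0e-8)     # ages 1, 2 before regime change
    q_post: tuple[float, float] = (8.0e-8, 1.0e-7)    # ages 1, 2 from regime_year on
    q_age: tuple[float, ...] = (1.2e-7, 1.05e-7, 9.0e-8, 7.5e-8, 6.5e-8, 5.5e-8, 4.5e-8)  # ages 3..9
    regime_year: int = 1994
    sigma_C: float = 0.10
    sigma_I: tuple[float, ...] = (0.55, 0.45, 0.38, 0.32, 0.28, 0.25, 0.28, 0.32, 0.38)   # ages 1..9
    sigma_year: float = 0.20
    sigma_egg: float = 0.50
    sigma_larv: float = 0.50
    sigma_0g: float = 0.80

    def __post_init__(self) -> None:
        qs = (self.q_egg, self.q_larv, self.q_0g, *self.q_pre, *self.q_post, *self.q_age)
        if any(q <= 0 for q in qs):
            raise ValueError("catchabilities must be > 0")
        sigmas = (self.sigma_C, self.sigma_year, self.sigma_egg, self.sigma_larv,
                  self.sigma_0g, *self.sigma_I)
        if any(s < 0 for s in sigmas):
            raise ValueError("observation SDs must be >= 0")

    def q_winter(self, age: int, year: int, max_age: int = 9) -> float:
        """Effective winter-survey catchability for an age and survey year."""
        if age in (1, 2):
            return (self.q_post if year >= self.regime_year else self.q_pre)[age - 1]
        if not 3 <= age <= max_age:
            raise ValueError(f"winter survey covers ages 1..{max_age}")
        return self.q_age[age - 3]


@dataclass(frozen=True)
class ParameterSet:
    """Process parameters of the life-cycle model.

    Defaults are the fixed constants and posterior medians of the fitted
    model for Northeast Arctic cod: fecundity 235 eggs per gram of SSB, egg
    mortality 0.169 d^-1, a 60-day larval phase at 0.075 d^-1 followed by a
    60-day early-juvenile phase at 0.04 d^-1, 0-group annual mortality 0.35,
    juvenile annual mortality 0.15, fixed adult natural mortality 0.2, and
    the estimated density-dependence coefficients (beta0 intercohort
    cannibalism on the 0-group, beta[1..3] intracohort for ages 1-3).
    """

    f: float = 235.0                 # eggs per gram of SSB
    sigma_E: float = 0.7             # SD of spawning process error (log scale)
    M_egg: float = 0.169             # egg mortality, day^-1
    t_EL: float = 25.0               # egg-survey -> larval-survey duration, days
    M_larv_daily: float = 0.075      # larval mortality, day^-1
    t_larv: float = 60.0             # larval phase duration, days
    M_juv_daily: float = 0.04        # early-juvenile mortality, day^-1
    t_ejuv: float = 60.0             # early-juvenile phase duration, days
    gamma: float = 3.38e-3           # temperature effect on larval daily mortality, per degC
    M0: float = 0.35                 # 0-group density-independent mortality, year^-1
    beta0: float = 1.82e-9           # intercohort cannibalism coefficient, per individual
    sigma_O: float = 0.7             # SD of 0-group survival process error
    MJ: float = 0.15                 # juvenile mortality, year^-1
    beta: tuple[float, float, float] = (9.48e-11, 1.69e-10, 2.27e-10)  # ages 1..3
    MA: float = 0.2                  # adult natural mortality, year^-1 (fixed)
    s: tuple[float, ...] = (-1.7, -1.4, -1.2, -1.05, -0.95, -0.95)     # log selectivity, ages 4..9
    sigma_U: float = 0.05            # SD of log-effort random-walk innovations
    obs: ObservationParams = field(default_factory=ObservationParams)

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("fecundity must be > 0")
        nonneg = (self.sigma_E, self.M_egg, self.t_EL, self.M_larv_daily, self.t_larv,
                  self.M_juv_daily, self.t_ejuv, self.M0, self.beta0, self.sigma_O,
                  self.MJ, self.MA, self.sigma_U, *self.beta)
        if any(v < 0 for v in nonneg):
            raise ValueError("mortalities, durations, SDs and beta coefficients must be >= 0")
        if any(si >= 0 for si in self.s):
            raise ValueError("log selectivities must be < 0")

    @property
    def f_per_kg(self) -> float:
        """Fecundity in eggs per kilogram of SSB (input is per gram)."""
        return 1000.0 * self.f

    def beta_at(self, age: int) -> float:
        """Intracohort density-dependence coefficient for a juvenile age."""
        if age not in (1, 2, 3):
            raise ValueError("intracohort density dependence is defined for ages 1-3")
        return self.beta[age - 1]

    def with_updates(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Covariates:
    """Annual covariates: weight-at-age (kg), maturity-at-age, temperature.

    ``temperature`` is the June-August mean anomaly (degC, centred) of the
    thermal conditions experienced during the larval phase.
    """

    weight: np.ndarray      # (max_age, n_years), kg
    maturity: np.ndarray    # (max_age, n_years), probability
    temperature: np.ndarray  # (n_years,), degC anomaly

    def __post_init__(self) -> None:
        w, p, t = np.asarray(self.weight, float), np.asarray(self.maturity, float), np.asarray(self.temperature, float)
        if w.ndim != 2 or p.shape != w.shape or t.shape != (w.shape[1],):
            raise ValueError("covariate shapes inconsistent: weight/maturity (A, Y), temperature (Y,)")
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("maturities must lie in [0, 1]")
        object.__setattr__(self, "weight", w)
        object.__setattr__(self, "maturity", p)
        object.__setattr__(self, "temperature", t)

    @property
    def n_years(self) -> int:
        return self.weight.shape[1]


@dataclass(frozen=True)
class ProcessShocks:
    """Realised process errors driving one trajectory.

    ``eps_E[y]`` perturbs egg production in year y, ``eps_O[y]`` the survival
    of the year-y 0-group to age 1, and ``u_innov[y]`` is the log-effort
    random-walk innovation entering year y (``u_innov[0]`` is ignored;
    effort is pinned to 0 in the first year for identifiability).
    """

    eps_E: np.ndarray
    eps_O: np.ndarray
    u_innov: np.ndarray

    @classmethod
    def zeros(cls, n_years: int) -> "ProcessShocks":
        z = np.zeros(n_years)
        return cls(z.copy(), z.copy(), z.copy())

    @classmethod
    def draw(cls, params: ParameterSet, n_years: int, rng: np.random.Generator) -> "ProcessShocks":
        eps_E = rng.normal(0.0, params.sigma_E, n_years)
        eps_O = rng.normal(0.0, params.sigma_O, n_years)
        u = rng.normal(0.0, params.sigma_U, n_years)
        u[0] = 0.0
        return cls(eps_E, eps_O, u)


@dataclass
class LatentState:
    """Complete latent trajectory of the population over the model years."""

    structure: AgeStructure
    eggs: np.ndarray        # (Y,)
    larvae: np.ndarray      # (Y,)
    zerogroup: np.ndarray   # (Y,)
    N: np.ndarray           # (A, Y), ages 1..A
    SSB: np.ndarray         # (Y,), kg
    F: np.ndarray           # (A, Y), zero below recruit_age
    U: np.ndarray           # (Y,), log effort, U[0] = 0
    catch: np.ndarray       # (A, Y), individuals

    def validate(self) -> None:
        if self.U[0] != 0.0:
            raise ValueError("log effort must be 0 in the first year")
        for name in ("eggs", "larvae", "zerogroup", "N", "SSB", "F", "catch"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise ValueError(f"negative values in {name}")
        ra = self.structure.recruit_age
        if np.any(self.F[: ra - 1, :] != 0.0):
            raise ValueError("fishing mortality must be zero below the recruitment age")
        if np.any(self.catch > self.N):
            raise ValueError("catch cannot exceed abundance")

    def cannibal_abundance(self, year_idx: int) -> float:
        """Summed abundance of the cannibalistic ages in a given year."""
        idx = [a - 1 for a in self.structure.cannibal_ages]
        return float(self.N[idx, year_idx].sum())

    def as_frame(self) -> "object":
        """Long-format DataFrame of the latent trajectory (year, series, age, value)."""
        import pandas as pd

        st = self.structure
        rows: list[dict] = []
        for j, year in enumerate(st.years):
            rows.append({"year": year, "series": "eggs", "age": np.nan, "value": self.eggs[j]})
            rows.append({"year": year, "series": "larvae", "age": np.nan, "value": self.larvae[j]})
            rows.append({"year": year, "series": "zerogroup", "age": np.nan, "value": self.zerogroup[j]})
            rows.append({"year": year, "series": "ssb", "age": np.nan, "value": self.SSB[j]})
            rows.append({"year": year, "series": "effort", "age": np.nan, "value": self.U[j]})
            for a in st.ages:
                rows.append({"year": year, "series": "abundance", "age": a, "value": self.N[a - 1, j]})
                rows.append({"year": year, "series": "fishing_mortality", "age": a, "value": self.F[a - 1, j]})
                rows.append({"year": year, "series": "catch", "age": a, "value": self.catch[a - 1, j]})
        return pd.DataFrame(rows)
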