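# Methods

## Scope and structure

`neacod` implements a full life-cycle state-space model for an
age-structured marine fish population (eggs → larvae → 0-group → juveniles
→ adults → spawners), with Bayesian estimation of its parameters and latent
states from survey indices and landings. The model's structure, fixed
constants, priors and default parameter values follow the published
analysis of Northeast Arctic cod; the package replaces the proprietary
survey data with a synthetic generator that reproduces the surveys'
statistical structure, so every stage of the pipeline is testable
end-to-end.

## Process model and assumptions

One time step is one year, indexed by the survey year; a cohort at age `a`
in year `y` becomes age `a+1` in year `y+1`. Ages run 1–9 with no plus
group: survivors of age 9 leave the model. Within a year the order of
computation is SSB → eggs → larvae → 0-group, each within the same
calendar year; the 0-group of year `y` becomes age 1 in year `y+1`.

Assumptions worth making explicit:

- **Stochasticity enters at two points only**: egg production
  (`ε_E ~ N(0, σ_E²)`, absorbing fecundity variation, fertilisation and
  pre-survey egg survival) and 0-group→age-1 survival
  (`ε_O ~ N(0, σ_O²)`). Juvenile and adult transitions are deterministic
  given abundances and mortalities; interannual variability at those ages
  is inherited, which is precisely what makes the variance-dampening
  analysis interpretable.
- **Density dependence is compensatory everywhere** (Beverton–Holt form
  `e^{−M}/(1+βN)`): survival falls with abundance but recruitment never
  declines absolutely (no overcompensation). Intercohort predation
  (cannibalism by ages 3–4) acts on the 0-group; intracohort competition
  acts within ages 1–3.
- **Fishing is separable**: `F_{a,y} = exp(s_a + U_y)` with age
  selectivities constant through time and a log-effort random walk pinned
  to `U = 0` in the first year for identifiability. Fish recruit to the
  fishery at age 4; fishing on age 3 and below is taken as negligible.
- **Natural and fishing mortality operate simultaneously** through the
  year, so the Baranov equation gives the catch as the fishing share of
  total deaths.

### Choices the published description left open

- *Temperature.* Warm years improve larval survival; the functional form
  is not given. We use the simplest one: a linear offset to the larval
  *daily* mortality, `M_L − γT`, applied over the 60-day larval phase only
  (the early-juvenile phase is temperature-independent). With the default
  `γ = 3.38e-3 °C⁻¹ d⁻¹` and a ±1 °C anomaly range this yields the
  reported ~1.5-fold survival span around the 0.08–0.12% baseline.
- *Annual vs daily juvenile rates.* The transition text labels `M0`, `MJ`
  "day⁻¹" but the priors and all reported values are in year⁻¹ (medians
  0.425 and 0.2; posterior medians 0.35 and 0.15, consistent with the
  reported survivals 0.41 and 0.75–0.77). We treat both as annual rates
  over one-year transitions.
- *Cap and shock order.* The 0-group survival cap at 1 is applied after
  the lognormal shock multiplies survival: `min(1, e^{−M0+ε}/(1+β₀N_c))`.
  This keeps the density-independent limit exact and the cap a genuine
  bound on realised survival.
- *Cannibal timing.* The cannibal abundance acting on the year-`y`
  0-group is `N_{3,y} + N_{4,y}` of the same year (the transition's start).
- *Egg-to-larval-survey duration* `t_EL` is never printed; it is a config
  parameter, default 25 days, chosen (jointly with realistic covariate
  ogives and fishing levels) so the closed population loop equilibrates at
  realistic absolute abundances — see Calibration.
- *Survey regime split.* The winter survey changed gear/coverage in
  1993/94; survey years ≥ 1994 use the post-change catchabilities for ages
  1–2 (configurable).
- *Fig-2-style survival index.* The survival index of focal age `a` in
  year `y` is `log I_{a+1,y+1} − log I_{a−1,y−1}` — previous and subsequent
  age-classes of the same cohort — so the focal abundance index appears in
  neither term and its observation error cannot bias the correlation. For
  age 1 the previous class is the 0-group (a different survey, passed
  explicitly). The correlation is Pearson on logs; the coefficient type is
  not stated in the source and Pearson is the default for log-linear
  abundance indices.
- *Variance convention.* Interannual variances of log series are sample
  variances (n−1 denominator).

## Parameters

Fixed constants (independent external estimates): `f = 235 eggs g⁻¹`
(converted internally to kg⁻¹), `M_egg = 0.169 d⁻¹`, larval phase
`0.075 d⁻¹ × 60 d`, early-juvenile phase `0.04 d⁻¹ × 60 d`, adult natural
mortality `MA = 0.2 yr⁻¹`.

Estimated parameters and their defaults (the published posterior medians),
used as the synthetic generator's truth: `M0 = 0.35 yr⁻¹`,
`MJ = 0.15 yr⁻¹`, `β₀ = 1.82e-9`, `β₁ = 9.48e-11`, `β₂ = 1.69e-10`,
`β₃ = 2.27e-10` (all per individual), `σ_E = σ_O = 0.7`. Observation-side
defaults (not printed in the source; chosen to its qualitative
description): age-specific survey error SDs U-shaped in age with the
minimum (0.25) at age 6 and the maximum implied for the 0-group index
(0.8); year-effect SD 0.2; landings error SD 0.1; winter catchabilities
declining from age 3 to 9 and higher after the 1993/94 change for ages
1–2.

Priors reproduce the published ones: `M0 ~ LogNormal(median 0.425,
log-variance 0.5)`, `MJ ~ LogNormal(median 0.2, 0.5)`; log-catchabilities
`~ N(0, 1000)` (means −25 for eggs and larvae); selectivities
`~ N(−1.6, 1000)` truncated negative; `γ ~ N(0, 1000)` sign-unconstrained
(the reported credible interval includes zero); β's and all SDs
`~ Uniform(0, upper)` with uppers audited post-fit (a warning fires if any
posterior maximum exceeds 95% of its bound). Uniform uppers default to
`1e-8` for β₀, `2e-9` for β₁–β₃, 2.0 for the process SDs, 1.0 for
effort/landings/year-effect SDs, 2.0 for age-specific and 2.5 for
stage-specific observation SDs.

## Synthetic data: what it emulates, and what it does not

The generator reproduces: the historical observation windows (egg/larval
indices 1959–1990, 0-group from 1966, winter trawl ages 1–9 from 1981,
landings from 1959); lognormal observation errors including the shared
within-year survey effect and the 1993/94 catchability break; weight-at-age
(cubed von Bertalanffy, mild year-to-year jitter), a logistic maturity
ogive with 50% maturity at age 6.5 (typical maturation 6–8 years), and a
centred AR(1) June–August temperature anomaly (SD 0.5 °C, lag-1 0.6); an
effort history that rises to the late 1980s, drops sharply in the early
1990s, recovers by the late 1990s and declines thereafter, with random-walk
noise on top; and a burn-in of at least one full age span (default 15
years) so the output window carries no initial-condition artifacts.

It does **not** emulate: the actual Kola-transect temperature series or
ICES landings values; trends in weight/maturity (regime shifts in
condition); spatial structure; multispecies interactions; or
autocorrelated process errors. Passing tests therefore demonstrate that
the estimation machinery recovers the data-generating process *of this
model class* at realistic sizes and noise levels — not that the model is
correct for any real stock.

### Calibration

Absolute abundance scale is set by a closed loop (eggs depend on SSB,
which depends on survivors), so the generator's defaults were calibrated
once so that the loop equilibrates near the working points implied by the
published survival means: mean age-1 abundance ≈ 1.25e9 individuals (at
which `β₁` gives the reported 0.77 age-1 survival), juvenile survivals
0.75–0.78, SSB of order 0.5–1.5 Mt, and mean fishing mortality ≈ 0.4–0.5
(historically accurate for this fishery). The knobs were `t_EL = 25 d`
and selectivities `s = (−1.7, −1.4, −1.2, −1.05, −0.95, −0.95)` for ages
4–9 (rising to a plateau at ages 8–9, matching the described age pattern).
One published working point cannot be met simultaneously with the others:
a mean cannibal abundance of ~4e8 (at which `β₀` yields the reported 0.41
mean 0-group survival) is incompatible with mean age-1 abundance 1.25e9 in
any near-stationary age structure, where `N₃+N₄ ≈ N₁`. We calibrate to the
age-1 working point; realised cannibal abundance is ≈ 1e9 and realised
mean 0-group survival ≈ 0.3. The survival *functions* at the published
working points are verified exactly in the tests.

## Inference

The joint posterior is `likelihood × process densities × priors`, where
the latent trajectory is the deterministic image of the initial
abundances, the shock vectors (`ε_E`, `ε_O`), the effort innovations, and
the survey year effects — all sampled.

Two backends:

- **JAGS** (default; via `rjags` over `Rscript`): the model generated in
  BUGS, mirroring the equations above term for term. Missing cells are
  simply absent from the vectorised observation blocks. Chain `c` uses RNG
  seed `1000·seed + c`; runs are exactly reproducible.
- **emcee**: differential-evolution ensemble moves over the package's own
  `log_posterior`. The sampling coordinates are *non-centred* (shocks
  stored as standardised residuals, `ε = σz`), removing the funnel between
  the SDs and their shocks; the Jacobian of the rescaling is included.
  This backend doubles as an independent check of the posterior assembly:
  with no observations its marginals must (and do) reproduce the priors.

Sampler profiles: the *desk* profile (default) runs 3 chains × (500
adaptation + 2000 burn-in + 2000 retained draws, unthinned) — sized so a
50-year fit completes in minutes on one CPU; the *published* profile
reproduces the original published settings (3 chains, 250k burn-in, 250k iterations
thinned by 1000 → 750 retained draws). Diagnostics (split-chain R-hat <
1.05, |Geweke z| < 2, lag-1 autocorrelation of retained draws < 0.2, ESS,
cross-correlations) are computed after every fit and a failure is flagged
in the samples' metadata, not silently dropped; at desk scale some
slow-mixing nuisance parameters (notably initial abundances and the
selectivity/effort pair) routinely flag, while the density-dependence and
mortality parameters centre correctly.

Known identifiability limits, inherent to the model rather than the
sampler: the pre-recruit absolute scale trades against the β coefficients
(scaling juvenile abundances by `c` while dividing β's by `c` leaves all
transitions invariant, with the egg-chain shocks absorbing the rest), the
same catchability/mortality confounding that motivates the informative
mortality priors. Consequently individual catchabilities recover to
~10–15% at desk scale even on near-noise-free data, while identifiable
combinations (`q·N`) match to a few percent.

## Numerical notes

- Baranov catch uses `expm1` for the death fraction; the `F+MA → 0` limit
  returns zero catch without a division by zero.
- Realised stage survivals are capped at 1; a cap triggered by an extreme
  temperature anomaly logs a warning.
- Observed zeros are rejected at load time (lognormal support); missing
  cells are masks, never zeros.
- The Geweke diagnostic uses a windowed autocovariance (lag window
  `min(n/10, 50)`) for the spectral variance of the segment means.
- All percentile summaries are order-invariant in the draws; bootstrap
  and simulation utilities take explicit seeds.

## Problem sizes used by the test suite

Unit tests run on a reduced scenario (15 years, ages 1–6). The recovery
check fits one 50-year dataset at the default truth with the desk profile;
the variance-dampening check uses 100 replicate 50-year simulations; the
bootstrap check uses a 45-year survey-era scenario with 10,000 resamples;
prior reproduction uses an 8-year, 6-age empty dataset with 160 walkers.
These sizes are the package's desk-scale defaults — large enough for the
qualitative phenomena to be unambiguous, small enough to iterate on.

## Limitations

- No plus group: comparisons with assessments that accumulate ages 9+
  need an upstream adjustment.
- Single stock, single species; cannibalism is the only trophic link.
- The temperature effect is linear in daily mortality and confined to the
  larval phase; strong anomalies outside the calibrated range can hit the
  survival cap.
- Fixed adult natural mortality (0.2 yr⁻¹), as in the source analysis; a
  misspecified `MA` propagates into selectivity and effort estimates.
- Desk-scale MCMC is sized for parameter medians and intervals of the
  well-identified parameters, not for tail quantiles of nuisance latents.
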