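# Methods

This package reconstructs, as tested code over synthetic data, a small-area
analysis of participation in a national biennial bowel-screening program
(iFOBT kits mailed to residents aged 50–74, with the set of invited single
ages expanding year by year between 2015 and 2020).  The pipeline has five
stages: indirect age standardisation, broad-area rate-ratio models, Bayesian
spatial smoothing, a global heterogeneity test, and a centile-benchmark
counterfactual.

## Indirect standardisation with year-varying eligibility

Which single ages receive an invitation depends on the calendar year
(quinquennial ages only in 2015, all even ages 50–74 from 2019).  Expected
screens for area *i* over a two-calendar-year period are

    E_i = Σ_{year} Σ_{age ∈ eligible(year)} pop_i(age) · r(age, year)

where r(age, year) is the national screening rate for that cell.  The
standardised participation ratio is SPR_i = y_i / E_i, with y_i the observed
screened count.  When the national rates are derived from the same closed
population, ΣE equals Σy by construction (the calibration identity asserted
in the tests, exact up to the integer rounding of national invitee margins).

Populations arrive in 5-year bands; eligibility operates on single ages, so
bands are split uniformly over their five ages.  Inclusion filters remove
areas whose mean annual eligible population falls below 5, areas flagged as
islands, and suppressed count records; removals are logged by reason.
Rates are computed at full precision and rounded half-up to one decimal only
for presentation.

## Broad-area rate models

Screened counts per area are modelled as negative binomial (NB2,
Var = μ + αμ²) with log E_i as offset and area disadvantage quintile,
remoteness category and state as covariates.  Exponentiated coefficients are
participation rate ratios (PRR) with Wald 95% CIs; reference levels are the
most advantaged quintile, major cities, and the most populous state.  The
NB-vs-Poisson comparison uses the likelihood-ratio statistic with the
boundary-corrected null ½χ²₀ + ½χ²₁ (α sits on the boundary under the
Poisson null); at a statistic of exactly zero the p-value is 1.  When the
estimated dispersion collapses to the boundary the NB fit is reported as
the Poisson fit with α at its boundary value, whose coefficient covariance
is the correct limit.  Marginal SPRRs per stratum are predictive margins:
the whole study population is assigned each level of the factor in turn,
total predicted screens are compared against the reference level, and the
CI comes from the delta method on the log ratio.  (Whether the original
analysis used predictive margins or stratified refits is not determinable
from the available description; predictive margins are the design choice
here, and with a single covariate they reduce exactly to the conditional
PRR.)

## Leroux CAR spatial smoothing

Counts are Poisson, y_i ~ Poisson(E_i exp(β0 + ψ_i)), with a Leroux prior
on the spatial field:

    ψ ~ N(0, τ² [ρ(D − W) + (1 − ρ)I]^{-1})

interpolating between independence (ρ=0) and the intrinsic CAR (ρ→1).
Priors are the defaults of the CAR-fitting software this reconstructs:
β0 ~ N(0, 10⁵), τ² ~ InverseGamma(1, 0.01), ρ ~ Uniform(0, 1); the original
analysis does not state its settings, so these are a documented
reconstruction, not a citation.

The sampler is Metropolis-within-Gibbs:

* ψ: random-walk Metropolis against the full conditional
  N(ρ Σ_j w_ij ψ_j / (ρ d_i + 1 − ρ), τ² / (ρ d_i + 1 − ρ)) times the
  Poisson likelihood.  Sites are updated in graph-coloring blocks: areas in
  one color class share no edge, so their full conditionals are mutually
  independent and the vectorised block update has the same stationary
  distribution as site-by-site updating.
* τ²: conjugate inverse-gamma.  Because ψ is recentred to sum to zero, its
  quadratic form has expectation (n−1)τ², so the Gibbs shape uses (n−1)/2.
* ρ: random-walk Metropolis with reflection into [0, 1−10⁻⁶]; the precision
  log-determinant is Σ log(ρμ_j + 1 − ρ) over the precomputed eigenvalues
  μ_j of D − W.
* β0: random-walk Metropolis; each sweep ends by recentring ψ with β0
  absorbing the mean (the standard identifiability convention).
* Proposal scales adapt toward ~40% acceptance during burn-in only, so the
  kept chain is a valid time-homogeneous Markov chain.

Islands (zero-neighbor areas) degrade the full conditional to
N(0, τ²/(1−ρ)); ρ = 1 is disallowed.  Production settings are burn-in
20,000 / 100,000 kept draws at thin 10; the analysis scripts and tests use
a short profile (burn-in 2,000 / 10,000 kept at thin 2) whose adequacy is
demonstrated by the recovery experiments.  A single seeded chain is used,
with Geweke z-scores and autocorrelation-based effective sample sizes as
diagnostics; chains are bit-reproducible given the seed.

Summaries per area: the smoothed SPR (sSPR) and smoothed count are posterior
medians of exp(β0+ψ_i) and E_i·exp(β0+ψ_i); the posterior probability
PP_i = Pr(θ_i > 1) classifies areas as below (<0.2), uncertain (0.2–0.8,
boundaries inclusive) or above (>0.8) the national average.  Choropleth bins
for the sSPR are equal-width on the log scale, symmetric about 1, with an
odd bin count so the national average sits in the centre bin; the package
emits bin assignments and breaks, not rendered maps.

### Sampler validation and known recovery behavior

Three independent oracles check the sampler: (i) a prior-only chain
reproduces the moments of direct Cholesky draws from the Leroux prior;
(ii) for a single area with ρ and τ² fixed, the posterior mean of θ matches
1-D quadrature of the Poisson-lognormal posterior to two decimals; (iii) on
an identical dataset, the (ρ, τ²) posterior agrees with an independent
general-purpose MCMC implementation within Monte-Carlo error.

Estimating (ρ, τ²) from a *single* lattice realization is intrinsically
biased toward smaller ρ — on the 20×20 recovery design the exact-field
maximum-likelihood estimate itself averages ρ̂ ≈ 0.76 for a truth of 0.8 —
and τ² follows along the (ρ, τ²) posterior ridge.  Posterior medians stay
well inside ±0.15 (ρ) and ±0.10 (τ²) of truth on average, but the
frequentist coverage of the 95% equal-tailed credible interval for τ² at
this fixed design point is ≈89%, slightly under the nominal-coverage bound
asserted in the acceptance suite; the corresponding test documents this as
a property of the design, not of the sampler.

## Tango's maximized excess events test

With N = Σ counts, r_i = counts_i/N, p_i = E_i/ΣE and Gaussian kernel
weights a_ij = exp(−4(d_ij/λ)²), the excess events statistic is
C(λ) = N Σ_ij a_ij (r_i − p_i)(r_j − p_j), non-negative because the kernel
matrix is positive semidefinite.  The maximized form evaluates C over 15
geometric scales from the smallest nonzero inter-centroid distance to half
the largest (spanning local to broad clustering; the original grid is not
stated), computes Monte-Carlo p-values per scale under the multinomial null
(p = (1 + exceedances)/(1 + n_mc), default n_mc = 999), and adjusts the
minimum p by the fraction of null replicates whose own minimised p is at
least as extreme — which is never below the observed minimum by
construction.  No chi-square approximation is used.  The primary mode feeds
the model-smoothed counts against expected counts; a raw-count mode is
provided for sensitivity, since the original description ("the modelled
number of screens") is loose on this point.  Distances are Euclidean on
projected or synthetic coordinates, great-circle if declared geographic.

## Centile benchmark

Areas are ranked by sSPR, unweighted (each area counts once), and the
benchmark is the nearest-rank 80th-centile value.  Each area below it
contributes max(0, threshold − sSPR_i)·E_i extra screens — the gap on the
same SPR scale the ranking uses — and the counterfactual national rate adds
the total to observed screens over observed invitees.  An invitee-based
mode (gap × invitees × national rate) is provided for sensitivity; whether
the original centile was population-weighted and which base the extras used
is not stated in the available description, so both readings are surfaced
as modes with the expected-count mode as default.

## The synthetic generator

The generator emulates the structure of the real extract with known ground
truth: a rook-adjacency lattice; contiguous state blocks; remoteness rising
with distance from a central city cell (50% major cities, 30% inner
regional, 15% outer regional, 5% remote by area count); disadvantage
quintiles from thresholding a smoothed Gaussian field at its empirical
quintiles so disadvantage clusters like a real census index; populations
around a configurable mean (default 2,000 persons aged 50–74 per area,
larger in cities, smaller in remote areas) spread over five 5-year bands
with a mild aging gradient.  National age/year rates rise from ~30% at age
50 to ~56% at 74 with a small calendar drift, averaging in the mid-40s like
the real program.  True relative participation is
θ_i ∝ exp(β0 + ψ_i + covariate effects), recentred to population-weighted
mean 1; default covariate effects follow the direction and rough magnitude
of the published national margins (remote ≈ 0.80 of major cities, most
disadvantaged ≈ 0.85 of most advantaged).  Counts are drawn at the
area × age × year cell level — Poisson, or gamma-mixed per area for NB2
overdispersion — and the emitted national table is the column sum of the
same draws, which makes the standardisation calibration identity exact by
construction.  Cell means that would exceed one screen per invitee are
capped with a warning, and screened never exceeds invitees.

What the generator does **not** emulate: real geography or area codes,
population back-projection, screening outside the program, sex/ethnicity
composition, suppression mechanics beyond a random flag, or spatial
confounding beyond the Leroux field itself (the generator assumes the same
prior family the model fits — recovery tests therefore show correctness of
the machinery, not robustness to misspecification).

## Numerical choices and scale

Tests and analysis scripts run on 6×6 to 20×20 lattices with short MCMC
profiles; the recovery experiment uses 100 replicates of a 20×20 lattice
with burn-in 2,000 and 5,000 kept draws at thin 2, enough for effective
sample sizes around 2,000 on the hyperparameters so that CI endpoints are
numerically stable.  Monte-Carlo p-values use the (1+k)/(1+n) convention
and are printed as "<1/(1+n_mc)" when at the resolution floor.  All
randomness flows from one global seed through named per-stage substreams;
identical seeds give byte-identical outputs.

## Known limitations

* Periods are fitted independently; there is no spatio-temporal component,
  mirroring the original design (changing eligibility makes cross-period
  comparison hazardous regardless).
* The NB dispersion is a single global α; no zero inflation.
* The exact expected-count construction and centile details of the original
  supplementary material were not available; the constructions here are the
  standard ones and are documented above as this package's own choices.
* Dense Cholesky sampling of the Leroux prior limits exact field draws to a
  few thousand areas; the MCMC itself is sparse and scales further.
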