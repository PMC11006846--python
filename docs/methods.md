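# Methods

This note documents the statistical model, the numerical choices and
the synthetic-data design behind `hemobayes`, and what the test suite
does and does not establish.

## Data model

Measurements are long-format records `(animal_id, treatment, variable,
value)` with treatment `Bas` (basal) or `CO2` (after hypercapnic
cold-water immersion).  The registry holds the sixteen panel variables
plus a derived, display-only `log10pCO2`; the derived variable never
enters the modelling loop.  Units: pH unitless; partial pressures in
mmHg; electrolytes, bicarbonate and derived calcium quantities in
mmol/L.  The units of `A` (the analyzer's "Alkalosis" channel) and
`Osm` (osmolarity) are not resolved by the available instrument
documentation and are stored as explicit unknowns; the "(TC)" channels
are treated as four additional independent variables.  Hard bounds
(pH in (0, 14), concentrations and pressures positive) catch unit
mix-ups at read time; violations are flagged and recorded in
provenance, not fatal, since the analysis itself makes no support
assumption.

All empirical quantiles in the package — summary tables, outlier
fences, predictive-interval endpoints, credible intervals — use linear
interpolation between order statistics ("type 7"), the default of both
numpy and the mainstream statistical environments, so outputs are
directly comparable with conventionally produced summary tables.

## Outlier screening

Extreme outliers per (variable, treatment) stratum are values outside
`(Q1 - 3*IQR, Q3 + 3*IQR)`.  Screening is one-pass (re-screening the
kept values could remove more; that is deliberately not done), values
exactly on a fence are kept ("outside" read literally), and the same
fence is applied to paired differences as a deterministic, reproducible
substitute for removing aberrant pairs by eye from a QQ plot.

## Likelihoods and priors

Three candidate families: Normal(mu, sigma), location–scale
Student-t(mu, sigma, nu), and the Azzalini skew-normal(xi, omega,
alpha) in its standard form `2/omega * phi((y-xi)/omega) *
Phi(alpha*(y-xi)/omega)`.  The Student-t is restricted to nu > 1 so
every fitted distribution has a mean: the treatment-effect hypothesis
is a statement about E[D], and for the skew-normal the mean implied by
a draw is `xi + omega*delta*sqrt(2/pi)` (delta = alpha/sqrt(1+alpha^2)),
not the location parameter.

Priors are weakly informative and scale-adaptive (m0 = median(y),
s0 = sd(y)):

| parameter | prior | rationale |
|---|---|---|
| location / mean | Normal(m0, 10·s0) | proper but diffuse on the data scale |
| scale / sd | half-Student-t(3, 0, 5·s0) | heavy-tailed, keeps small-n posteriors proper |
| nu | 1 + Gamma(shape 2, rate 0.1) | mass on 2–50, mean ≈ 21; excludes mean-free regimes |
| alpha | Normal(0, 4) | admits strong skew, regularises the unidentified-skew case |

These mirror the default prior style of mainstream Bayesian regression
packages for these families.

## Posterior sampling

Sampling uses `emcee`'s ensemble sampler with differential-evolution
moves (DEMove 0.8 / DESnookerMove 0.2), 10 walkers treated as chains,
1000 warmup steps, then 5000 further steps thinned by 10 — 500 kept
iterations per walker, S = 5000 pooled draws (pooled draw-major so any
prefix of the pooled sample spans all walkers).  S = 5000 makes the
tail-probability resolution 1/S = 0.0002, which fixes the "< 0.0002" /
"> 0.9998" formatting of extreme reports.

Parameterisation matters more than the move set.  The normal and
Student-t are sampled as (mu, log sigma[, log(nu-1)]).  The
skew-normal is sampled *centered* — (mean, log sd, alpha), mapped to
(xi, omega, alpha) per draw — because on the raw scale xi and alpha
are strongly anticorrelated whenever the data carry little skew
information; with the raw parameterisation the default diagnostics
failed routinely, with the centered one split-R-hat is typically below
1.005.

Convergence is declared when all split-R-hat ≤ 1.01 and all bulk ESS ≥
400 (current community defaults), computed with `arviz` on the thinned
walker-chains.  Non-converged fits still return draws but are refused
by the reference-interval stage and excluded from model selection.  A
small-S profile (`FitConfig.fast`, S = 1000, thresholds R-hat ≤ 1.05 /
ESS ≥ 150) is used for the replicated simulation studies in the test
suite; split-R-hat on 100 draws per chain is noisy (values up to ~1.04
occur on demonstrably well-mixed chains), so the default thresholds
would mis-flag small runs.  Degenerate data (all values equal) raise a
fit error rather than sampling an unidentifiable scale.

Every stochastic step takes an explicit seed; per-family and
per-observation seeds are derived through `numpy.random.SeedSequence`
so runs are bit-reproducible and independent across components.

## Model selection

PSIS-LOO: pointwise elpd via Pareto-smoothed importance weights
(`arviz.psislw`, relative efficiency taken from the fit's ESS), exact
refit without the offending observation wherever the Pareto shape
diagnostic exceeds 0.7.  The family with the highest elpd_loo among
converged fits is selected outright (no one-standard-error rule);
differences to the winner are reported with their pointwise standard
errors; exact ties — which occur only in contrived inputs — break
toward the structurally simpler family (Normal < Student-t <
Skew-Normal).

A caveat established while validating against a brute-force exact-LOO
oracle (one full refit per left-out point, itself cross-checked
against dense 2-D grid integration of the normal-model posterior):
at n = 20 the PSIS estimate sits ~0.15 elpd units above exact LOO even
with S = 5000.  That optimistic finite-sample bias is a property of
the estimator, not of this implementation (which agrees with
`arviz.loo` to four decimals); tests therefore assert agreement within
the estimator's statistical uncertainty (2·SE, plus an absolute 0.25
sanity bound) rather than an arbitrarily tight constant.

## Reference intervals and predictive checks

One predictive value per posterior draw (no thinning, no multiple
draws per parameter vector); the interval is the empirical 1%/99%
quantile pair of those 5000 values, reported alongside the observed
min/max so that implausible extrapolations are visible.  The overlay
check draws 200 replicate samples of size n at randomly chosen
posterior draws and evaluates Gaussian kernel densities (Silverman
bandwidth) on a common 512-point grid spanning the pooled range ±5%.

## Treatment effect

Differences D = after − before per animal (≥ 5 complete pairs
required), screened, fitted, LOO-selected; `q01_diff`/`q99_diff` are
the 1%/99% quantiles of the S posterior draws of the mean of D — a 98%
credible interval for mu_D, which is the reading consistent with the
interval widths a posterior for a mean has at n ≈ 30.  H0: mu_D = 0 is
rejected iff P[mu_D > 0] > 0.99 or < 0.01 (strict).  The reported
tail-probability column is P[mu_D > 0].  No multiplicity correction is
applied across the sixteen variables.

## Synthetic cohort generator

The generator emulates the study design: 75 individually marked
animals; for each variable a random basal subsample (n 28–73, matching
the published per-variable counts) and a treated subsample (n 20–31)
drawn from the basal animals, so pairing integrity holds by
construction.  Basal marginals are calibrated to the published
per-stratum summaries: mean and sd are matched exactly in
distribution; a skew-normal is used when the published mean−median gap
exceeds 0.1 sd (slant solved numerically from the standardized gap),
a normal otherwise.  Post-treatment values are

    post = (mean_b + shift) + (sd_b * scale) * (rho * z_b + sqrt(1 - rho^2) * eps)

with z_b the standardized basal value, shift and scale the published
mean difference and sd ratio, and rho the within-animal correlation —
a free parameter (default 0.5) because true correlations are not
recoverable from published summaries; every correlation-sensitive
check therefore uses wide tolerances or generator truth.  Gross
outliers are injected at a configurable rate (default 2%) by
displacing values two fence-widths beyond the stratum's 3×IQR fence
(random side, respecting hard lower bounds), so screening recovery is
testable; calibration checks compare *screened* generated strata to
the published (outlier-removed) targets.  Draws below a hard lower
bound are folded to a thin margin above it, which affects only
far-tail draws of the most dispersed treated strata.  Missingness is
completely at random within each variable.

What passing tests on this generator do **not** show: real hemolymph
panels have cross-variable dependence (acid–base chemistry couples pH,
pCO₂ and bicarbonate), instrument rounding, and possibly informative
missingness; the generator models none of these, so pipeline
guarantees are per-variable marginal guarantees.

## Quantile reconstruction from printed summaries

`reconstruct_from_quantiles` inverts one printed summary row into an
n-point sample: the quantile function passes through the five printed
points, linear between the quartiles, and is evaluated at probabilities
j/(n−1) so the printed minimum, quartiles and maximum are attained
exactly.  The two outer segments are power-curved with exponents
solved (bounded least squares, exponent 1 = linear) so that the sample
also matches the printed mean and sd.  The curvature is necessary, not
cosmetic: a purely linear tail spreads 25% of the mass uniformly
between the extreme and its quartile, which for a row like basal pH
(quartiles 7.51–7.57 but minimum 7.37) inflates the sd from the
printed 0.05 to ~0.063 and drags the fitted predictive 1% endpoint
~0.04 low.  When the printed summary is consistent with linear tails
the solver returns the linear reconstruction unchanged.

## Problem sizes used in the test suite

Replicated simulation checks run at deliberately desk-scale sizes:
posterior-contraction coverage at 25 replicates per family (n = 1000),
reference-interval endpoint recovery at 20 replicates (n = 150), LOO
selection frequency at 20 seeds (n = 150), decision-rule false-
rejection at 100 replicates (n = 30) under the small-S profile, and
generator calibration over 10 seeds.  These sizes give the stochastic
assertions comfortable margins (binomial thresholds are set at or
below the corresponding large-sample rates) while keeping the default
suite a few minutes long.

## Known limitations

* All families have unbounded support; several analytes are physically
  bounded below.  A bounded-support family would be the natural next
  candidate in the comparison set.
* Walkers of one ensemble are not independent chains; split-R-hat and
  ESS on walkers are the pragmatic diagnostic here and behaved well
  empirically, but they are less conservative than multi-ensemble
  diagnostics.
* The decision rule is a fixed-threshold posterior tail probability;
  it controls nothing across the sixteen variables jointly.
* Reference intervals from n ≤ 73 observations are preliminary by
  nature; the 1%/99% predictive quantiles inherit full posterior
  uncertainty but still extrapolate beyond the observed range for
  heavy-tailed fits.
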