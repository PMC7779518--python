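# Methods

`lirype` implements a joint hierarchical Bayesian model for willow ptarmigan
(*Lagopus lagopus*) line-transect surveys: a distance-sampling observation
model, a Gompertz state-space model of population growth driven by climate and
rodent covariates, and a latent Bernoulli submodel for rodent occurrence.
This note records the model, its assumptions, the defaults and why, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## The model

**Observation layer.** Perpendicular distances of detected ptarmigan clusters
follow a half-normal detection function g(d) = exp(−d²/2σ²) with perfect
detection on the line, truncated at w = 200 m. The decay scale is modelled on
the log scale,

    log σ_it = b0_det + b_GS·z(group size) + L_i + SR_r(i),

with group size standardized over retained observations and Gaussian random
effects for transect line (L) and survey region (SR). The effective strip
width of the untruncated half-normal is ESW = σ·√(π/2); inside the distance
likelihood the density is normalized over [0, w] (σ√(π/2)·erf(w/σ√2)).
Cluster sizes follow a shifted Poisson (size − 1 ~ Poisson) with line and
region-year random effects on the log rate, so support starts at one bird;
the model-expected cluster size for a transect-year supplies the σ (and hence
ESW) used in the count layer.

Total counts N_obs on a surveyed transect-year are negative binomial with
mean N = D·TL·(ESW/1000)·2 (density D in birds/km², transect length TL in km,
both transect sides) and dispersion r (variance = N + N²/r). This dispersion
is a different quantity from the growth rate r_it; the code keeps them as
`nb_dispersion` and `growth_rate` throughout.

**State layer.** Year-1 log-density is mu1 + eps1_i with transect-level
random effects. Later years follow Gompertz growth on the log scale:

    ln D_it = ln D_i,t−1 + r_it
    r_it = b0 + bA·ln D_i,t−1 + L_i + SR_i + Year_t
         + bCS·CS_i + bCT·CT_it + bR·R_it + bRL·R_i,t−1 + bH·H_i,t−1
         + bint_CT·CS_i·CT_it + bint_R·CS_i·R_it

with bA ∈ (−2, 0). Besides the year random effect there is no extra process
noise, so the latent surface is a deterministic function of the parameters;
all stochasticity lives in the random effects and the observation layers.
Missing survey years still carry a latent density (the recursion runs over
every year) but contribute no count likelihood.

**Rodent layer.** Rodent occurrence is a latent region-year probability with
a saturated logit decomposition, logit R_rt = c0 + Y_t + SR_r + (Y·SR)_rt,
fitted jointly; transect-level binary records are Bernoulli draws from their
region's probability, and missing records contribute nothing (they are
imputed through the latent probability). Occurrence is modelled at region
level because the shared predators thought to mediate the rodent–ptarmigan
link forage over scales larger than a single transect.

**Rodent covariate scale.** A jointly estimated latent cannot be
pre-standardized like the climate covariates, so R enters the growth model as
the centred probability (R − 0.5); fitted rodent coefficients are therefore
slopes per unit occurrence probability, and the generator's truth values for
bR, bRL and bint_R are on that same scale. For reporting alongside the
standardized covariate effects, slopes can be multiplied by the SD of the
centred rodent surface (the generator records it as `truth.rodent_sigma`,
typically ≈ 0.2 under the default cycles, so a slope of 0.3 per unit
probability is ≈ 0.06 per SD). A config switch (`rodent_scale`: "centred" |
"raw") controls how the probability enters the growth model. A cautionary
note from the package's own calibration experiments: scaling the rodent
slopes up to make the standardized rodent effect dominate the climate
effects (slopes ≈ 1.5 per unit probability) makes the cyclically forced
Gompertz posterior multimodal at the 150-transect design — density
dependence and the same-year and lagged rodent effects alias on a period-4
cycle — so effect sizes of that magnitude need either longer chains with
mode-jumping moves or more data to resolve.

**Priors.** Fixed effects ~ Normal(0, 10); random-effect SDs ~
half-Normal(0, 2); NB dispersion ~ Uniform(0.01, 50); bA ~ Uniform(−2, 0),
the narrower support helping convergence of the density-dependence term.
These are declared defaults in `PriorConfig`, configurable, in the weakly
informative JAGS idiom.

## Sampling

The posterior is sampled with a blocked adaptive Metropolis-within-Gibbs
scheme written for this model (no probabilistic-programming backend is used):

- Families whose members are conditionally independent given the rest —
  transect effects, region effects, region-year effects — are proposed
  jointly in one vectorized pass and accepted element-wise, with
  per-coordinate scales adapted toward 44% acceptance.
- Correlated fixed-effect blocks (the ten growth-model coefficients including
  mu1; the detection pair; the rodent year effects) use adaptive multivariate
  random walks with Haario-style covariance learning, tuned toward 23.4%.
- Two extra move types repair the posterior's known pathologies: a *ridge
  move* that perturbs bA while holding the equilibrium −b0/bA fixed (b0 and
  bA are near-collinear because the data pin the equilibrium density), and
  *recentring/rescaling moves* for each random-effect family — shifting mass
  between an intercept and its family mean (likelihood-invariant, judged on
  priors alone) and scaling a family jointly with its SD (the standard fix
  for hierarchical funnels).
- The growth-side recursion + count likelihood and the per-observation
  distance likelihood are evaluated in fused numba kernels; a pure-numpy
  implementation of the same functions is the in-repo reference, and a
  second, readable record-keyed implementation of the entire posterior
  (`lirype.population.joint_log_posterior`) is cross-checked against the
  vectorized one to ~1e-13 in the tests.

Determinism: all chains derive their generators from `numpy.random.
SeedSequence(seed)`; identical seed and settings give bitwise-identical
draws. Convergence is assessed with the classic Gelman–Rubin potential scale
reduction factor on the monitored scalars (the growth coefficients, mu1,
dispersion, detection and group-size intercepts, c0, and key SDs), gated at
R-hat < 1.1. Effective sample sizes are computed but not gated on.

Default desk-scale settings are 3 chains × 4000 iterations with half
discarded as burn-in; the survey-scale protocol (3 × 50 000, 25 000 burn-in)
is available through the same `McmcSettings`. The acceptance suite fits 20
replicate studies at 3 × 2200 and one convergence-gate fit at 3 × 3000 —
problem sizes chosen so the whole suite runs comfortably on one CPU.

Posterior summaries are pooled-chain means with 95% equal-tailed percentile
intervals (matching common JAGS summaries; HPD intervals are not used), and
an effect is "inferred" when its interval excludes zero. Effect-along-
gradient curves evaluate bR + bint_R·CS and bCT + bint_CT·CS per draw over a
CS grid.

## Climate covariates

Four seasonal variables are derived from daily series: spring onset (first
day with a trailing 7-day mean snow depth of zero), winter onset (first day
with a trailing mean above zero), and mean spring (MAM) / winter (DJF)
temperatures. Conventions the source data do not fix, chosen here once:

- DJF for analysis year t uses December of calendar year t−1, so the winter
  precedes the August survey.
- Winter onset is scanned over a July(t−1)–June(t) window and indexed as
  days since July 1 internally, so autumn onsets sort monotonically across
  the calendar boundary.
- Rolling means are trailing (window ending on the index day); the zero-depth
  tolerance is 1e-9 cm. A centred window would shift onsets by three days
  but leave all decompositions unchanged.
- Missing daily values raise by default; linear interpolation of gaps up to
  a configurable few days can be enabled (interpolated national climate
  grids rarely have gaps).

Each variable splits into CS (per-transect mean over the analysis years; the
spatial harshness gradient) and CT (yearly deviations from CS, which sum to
zero per transect by construction); both are centred and scaled to SD 1
(ddof = 1) before entering the model, with scaling constants retained for
back-transformation. For displays, spring-onset effects are sign-flipped so
that larger always means more benign; model-time covariates are never
flipped.

## The synthetic-data generator

The generator emulates the survey's statistical structure with known ground
truth (defaults in `lirype.simulate.DEFAULT_TRUTH`, declared in one place):

- Landscape: regions on a 0–1 harshness gradient, log-normal transect
  lengths around 3.7 km, per-transect surveyed-year masks with occasional
  gaps and at least 6 surveyed years (the survey's inclusion rule).
- Climate: either full daily series (regional mean + seasonal sinusoid +
  region-year anomaly + daily noise, with a temperature-driven snow
  accumulation/melt rule, so onsets are well defined and track the
  gradient), or a direct mode that draws standardized CS/CT with the same
  correlation structure and no daily series. The direct mode's CS is a
  harshness score (larger = colder), so a positive rodent × CS interaction
  means stronger rodent effects in harsher regions.
- Rodents: clipped-cosine cycles of period ~4 years, phase per region,
  peak occurrence rising from 0.38 in the most benign to 0.64 in the
  harshest regions with troughs near 0.05, transect-level Bernoulli records
  and a 10% missing fraction.
- Ptarmigan: the growth recursion under the truth; the total count on a
  surveyed transect-year is Poisson(N·ω) with ω ~ Gamma(r, r) — exactly the
  negative binomial the count likelihood assumes — and is then partitioned
  into clusters with shifted-Poisson sizes, the last cluster trimmed so
  sizes sum to the count. Detected distances are uniform candidates thinned
  by exp(−d²/2σ²), i.e. truncated half-normal with each cluster's own σ. A
  small fraction of decoy "surveyor-flush" records beyond the 10 m surveyor
  limit is appended; the standard filters remove them and they are never
  counted in n_obs.
- Harvest is standardized white noise with a zero true effect (the covariate
  is carried by the model but not expected to matter).

Known deviations from real data, hence limits of what passing tests show:
no spatial autocorrelation beyond the regional gradient; rodent cycles are
cyclo-stationary with region-constant phase rather than travelling waves;
the trimmed partition slightly distorts the cluster-size law relative to the
shifted Poisson (small clusters are mildly over-represented), which the
size model absorbs with a slightly lower rate; detection truly is
half-normal, so the tests validate internal consistency, not the detection
key itself; and the direct covariate mode has no measurement analogue of
interpolated climate products.

A further limitation worth stating: with the default truth (rodent × climate
interaction of 0.2 per unit occurrence probability) and negative-binomial
count noise at the survey's scale, the interaction's posterior standard
error is ≈ 0.12, so single replicates of the 10-region × 15-transect ×
10-year design identify its sign with posterior probability only around
0.9 — some data realizations genuinely favour the wrong sign. Detecting
gradient-dependent interactions of this size reliably needs either more
regions or a stronger effect; the recovery tests report this property
honestly rather than tuning the simulation toward certainty.

## Numerical choices and degenerate inputs

- Likelihood guards: σ below 1 µm, overflowing means or probabilities pinned
  at 0/1 return −1e300 rather than raising, so bad proposals are rejected
  rather than crashing a chain.
- NB likelihood caches its Γ-function constants per dispersion value; means
  below 1e-300 are clamped before logs (exact in the n = 0 limit).
- Ties in the scaled residuals are randomized (residual = Pr(sim < obs) +
  U·Pr(sim = obs)), the correct treatment for discrete counts; the residual
  seed is independent of the replicate seed.
- The Gelman–Rubin statistic is the classic (non-split) between/within
  formula; identical chains give √((n−1)/n), not exactly 1.
- Equal-tailed intervals use numpy's default (linear-interpolation)
  percentile rule.
- `aggregate_counts` emits 0 (not missing) for a surveyed transect-year with
  no detections: zero counts are informative in distance sampling.

## Sensitivity scenario

The residual-diagnostics sensitivity check uses a deliberately strong and
identifiable misspecification: same-year rodent slope 1.5 per unit
occurrence probability, no lagged effect, and regionally asynchronous cycle
phases (0, 1, 2, 3), so
that the omitted rodent signal cannot be absorbed by the shared year random
effects — with synchronized phases a no-rodent model can soak most of the
cycle into year effects, which is a property of the model structure, not a
failure of the diagnostic.
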