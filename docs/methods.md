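# Methods

## Data model

Immersion loggers sample wet/dry every 3 s and sum to 10-min blocks, so a
block is an integer 0–200. Night is the 12-h window 18:00–06:00 local time
(equatorial study area, no DST; timestamps carry a fixed UTC offset).
A block belongs to the night containing its *start* time: blocks starting in
[18:00, 24:00) to that evening's date, [00:00, 06:00) to the previous
evening's. A complete night has 72 blocks and a maximum aggregate count of
14,400 = 72 × 200.

Nights with missing blocks are kept with a shrunken binomial trial count
n = 200 × observed blocks rather than dropped; a `min_blocks` filter
(default 1) is available for stricter handling. Duplicate (bird, timestamp)
rows are a hard error — silent last-wins would hide logger faults.

A *wet bout* is a maximal run of consecutive blocks with wet_count ≥ 1
(at least 3 s of contact); a block of a flying bout is completely dry. The
`proportion_bout_regression` diagnostic fits nightly aggregate count on bout
count by ordinary least squares; a strong linear relation is expected when
both processing steps are sound.

## Hierarchical model

y_it ~ Binomial(n_it, p_it) with logit(p_it) = x_it' β_i,
x = (1, sst, moon_fraction); β_i ~ MVN(μ_β, Σ); μ_β ~ MVN(μ_0, Σ_0);
Σ⁻¹ ~ Wishart(ν_0, S_0) (parameterised so E[Σ⁻¹] = ν_0 S_0). The binomial
likelihood treats the full nightly count with its (possibly reduced) trial
count; there is no overdispersion term beyond the bird-level random
coefficients — a known limitation if nights within a bird are correlated
beyond what β_i captures.

SST enters in °C, uncentred, so coefficients are directly interpretable
(an optional standardisation flag exists for conditioning). The moon
covariate is one nightly illumination fraction in [0, 1]; moonrise/moonset
timing within the night is not modelled.

Default hyperparameters — μ_0 = 0, Σ_0 = 100 I, ν_0 = 4 (dimension + 1),
S_0 = I — are proper and weakly informative. With few birds the Wishart
prior noticeably inflates small random-effect variances (e.g. an SST-slope
variance of 4 × 10⁻⁴ against a prior scale of 1), which widens the
population-mean intervals for those components; point recovery is
unaffected, and coverage errs conservative. All hyperparameters are
overridable.

## Sampler

Metropolis-within-Gibbs, single chain, one seeded `numpy` Generator:

1. μ_β | β, Σ — exact MVN conjugate draw:
   V = (Σ_0⁻¹ + m Σ⁻¹)⁻¹, mean V(Σ_0⁻¹ μ_0 + Σ⁻¹ Σᵢ β_i).
2. Σ⁻¹ | β, μ_β — exact Wishart draw with df ν_0 + m and scale
   (S_0⁻¹ + Σᵢ (β_i − μ_β)(β_i − μ_β)')⁻¹.
3. β_i | data, μ_β, Σ — random-walk Metropolis on the 3-vector, all birds
   updated in one vectorised pass. The proposal covariance is a per-bird
   scalar step² times a fixed shape: the inverse of (Fisher information at
   the empirical-logit initialisation + I). The identity ridge keeps the
   shape well defined for flat covariates or no-data birds; the Fisher part
   absorbs the strong intercept–SST correlation that uncentred SST induces.
   The scalar adapts in windows of 50 iterations during burn-in only
   (multiplicative update toward ~30% acceptance, the usual 20–40% band for
   a 3-dimensional random walk), then freezes so detailed balance holds for
   every retained draw.

Initialisation: β_i at the empirical logit of the bird's pooled proportion
(clipped to [10⁻⁶, 1 − 10⁻⁶]), other components zero; μ_β at the β mean;
Σ at identity. Defaults: 10,000 iterations, 1,000 burn-in, no thinning.
A `thin` option keeps every k-th post-burn-in draw; the degenerate
single-bird validation uses 91,000 iterations thinned by 10 so its 9,000
retained draws are nearly independent, which the total-variation comparison
against quadrature needs (with an unthinned chain the TV estimate is
dominated by Metropolis autocorrelation, ~0.03–0.06, regardless of sampler
correctness). `fix_mu` / `fix_sigma` clamp the population parameters for
such degenerate runs; with Σ clamped tiny *and* μ_β sampled, the β↔μ pair
mixes pathologically (each pins the other), so the validation clamps both.

Likelihood evaluations drop the binomial coefficient (constant in β); the
exported `binomial_loglik` includes it.

## Inference outputs

Summaries are empirical means, SDs and equal-tailed 2.5/97.5 percentile
intervals of the retained μ_β draws (percentile, not HPD). The posterior
predictive band for a night's wet probability defaults to *population*
mode: per retained draw, sample a new bird β* ~ MVN(μ_β, Σ) and map the
night's design row through the inverse logit; *bird* mode substitutes the
stored β_i draws. The actogram export averages wet fraction per
(night, block-of-night) cell across birds.

## Synthetic data

The generator is the generative twin of the model. Moon fraction is a
deterministic raised cosine, (1 − cos 2πt/29.53)/2, new moon at the start
date — the model consumes only the fraction, so no ephemeris is needed. SST
is an annual sinusoid plus linear trend plus Gaussian noise; defaults
(mean 24.5 °C, amplitude 2.5 °C, trend −0.02 °C/day, noise SD 0.3 °C) give
the slow cool-season decline of an equatorial Pacific study area. Defaults
for the study design are 20 birds × 180 nights with true
μ_β = (−5.8, 0.04, −0.74) and Σ = diag(0.25, 4 × 10⁻⁴, 0.04) — coefficient
scales typical of a strongly nocturnal, moon-avoiding forager.

Nightly counts y ~ Binomial(14,400, p) are laid out over the 72 blocks as
contiguous wet runs: the ⌈y/200⌉ wet blocks (all 200 except one remainder
block) are split into a geometric number of bouts (mean 3, capped by
feasibility) and placed uniformly with at least one dry block between runs.
Allocation conserves y exactly, so aggregation inverts generation. Blocks
can be dropped at a configurable `missing_block_rate` (default 0 — the
emulated deployments record continuously). Daytime blocks are emitted fully
dry except on rare rest-on-water days (rate 0.0025/bird-day, matching the
handful of such days seen per multi-bird season).

What the generator does *not* emulate: within-night autocorrelation beyond
bout contiguity, moonrise/moonset geometry, weather, individual temporal
trends, or device failure modes other than uniform block dropout. Passing
recovery tests therefore shows the estimator is correct under the model's
own assumptions, not that real deployments satisfy them.

## Validation choices and problem sizes

* Bout detection is checked against a brute-force run-length scan on 10,000
  random nights.
* The degenerate single-bird run is compared with deterministic grid
  quadrature (2,001-point grid over ±6 posterior SDs) by total variation on
  10 equal-probability bins; the observed distance is ~0.012 against a 0.02
  bound.
* The recovery study uses 12 seeded replicates in the test suite and 8 in
  the acceptance script, each a full generate → aggregate → join → fit run
  at the default study size, fit with default MCMC settings; pass rules
  allow at most one failing replicate and require 95% CrI coverage of each
  μ_β component in [85%, 100%].
* Repeat runs with identical seed and configuration produce byte-identical
  posterior CSVs.

## Known limitations

Single chain by default (no R̂ across chains); plain binomial likelihood
(no extra-binomial dispersion); one moon value per night; the Wishart
default inflates very small variance components as noted above; bout
statistics of the generator are a convenience model, not a mechanistic one.
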