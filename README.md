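# lunarsea

Tools for analysing nocturnal at-sea activity of seabirds carrying leg-mounted
immersion (wet/dry) loggers, and for asking how that activity tracks the lunar
cycle and sea-surface temperature (SST). The motivating system is a tropical,
nocturnally foraging seabird whose prey rides the diel vertical migration:
on bright (full-moon) nights the prey stays deep and the birds sit on the
water less; on dark (new-moon) nights surface prey is available and wet time
goes up.

The package covers the full path from decoded logger output to
population-level inference:

* **`logger_processing`** — parse 10-min immersion blocks (each an integer
  0–200 counting wet 3-s sub-periods), assign blocks to 12-h nights
  (18:00–06:00 local time), aggregate to nightly binomial counts
  (*y* of *n* = 200 × observed blocks, at most 14,400 = 72 × 200), and detect
  wet bouts (maximal runs of blocks with ≥ 3 s of water contact).
* **`covariates`** — nightly covariate tables (SST °C, moon-illumination
  fraction 0–1) and design-matrix joining.
* **`model`** — the hierarchical Bayesian binomial-logit GLMM with a custom
  Metropolis-within-Gibbs sampler (below).
* **`report`** — posterior summary tables, posterior predictive bands for the
  nightly wet probability, actogram matrices, study bookkeeping.
* **`simulate`** — a synthetic-data generator with known truth, so the whole
  pipeline (including parameter recovery) runs with no field data.

## The model

For bird *i* on night *t*, the aggregated wet count is

```
y_it ~ Binomial(n_it, p_it),        logit(p_it) = x_it' beta_i,
x_it = (1, sst_t, moon_t),          beta_i ~ MVN(mu_beta, Sigma),
mu_beta ~ MVN(mu_0, Sigma_0),       Sigma^-1 ~ Wishart(nu_0, S_0).
```

Each bird gets its own reaction to the environment through `beta_i`
(intercept, SST effect per °C, moon-phase effect per unit illuminated
fraction); the inferential target is the population mean `mu_beta`. The
sampler alternates exact conjugate draws of `mu_beta` and `Sigma^-1` with an
adaptive random-walk Metropolis step on each `beta_i` (Fisher-shaped
proposal, scalar step adapted during burn-in only). Defaults: 10,000
iterations with the first 1,000 discarded as burn-in; weakly informative
proper priors (`mu_0 = 0`, `Sigma_0 = 100 I`, `nu_0 = 4`, `S_0 = I`). An
effect is called significant when its equal-tailed 95% credible interval
excludes zero.

## Worked example

Simulate a deployment of 8 birds followed for 60 nights (true population
coefficients −5.8, 0.04, −0.74), then refit them from the raw block stream:

```sh
$ lunarsea simulate --out demo --seed 42 --birds 8 --nights 60
wrote 69120 block records for 8 birds x 60 nights to demo

$ lunarsea fit --blocks demo/blocks.csv --covariates demo/covariates.csv \
               --out demo_fit --seed 7
fitted 8 birds, 480 bird-nights; posterior in demo_fit/posterior.csv

$ cat demo_fit/summary.csv
parameter,mean,sd,ci_low,ci_high,excludes_zero
intercept,-5.8475823621603045,0.36346770213677193,-6.569619148350929,-5.144691732760363,True
sst,0.04056014123683868,0.13418583801051398,-0.22115569922536393,0.30654789969197305,False
phase,-0.7843298897221372,0.1430855160093149,-1.0644446250552253,-0.5033526938278928,True
```

Reading the table: the intercept (≈ −5.85) says a bird spends a small
fraction of a dark, average-SST night on the water once the covariates are
at zero; the phase coefficient (≈ −0.78, CrI entirely negative) says wet
time drops as the moon fills, and the generating value −0.74 is well inside
the interval. With only 8 birds the SST effect (truth 0.04 per °C) is not
separable from the intercept — its interval straddles zero; the recovery
study below uses 20 birds × 180 nights, where all components are recovered.

The same steps are available as library calls
(`simulate_deployment` → `aggregate_nights` → `join_design` →
`sample_posterior` → `summarize_population`).

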