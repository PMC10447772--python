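# Methods

## Model and likelihood

The outcome model for state-year death counts is a Gamma-Poisson
(negative binomial) regression with a log link and a log-population
offset. We fix the parameterization once, since negative-binomial
conventions vary across software: the distribution has **mean λ** and
**shape φ**, i.e. the latent Poisson rate is `λ·u` with
`u ~ Gamma(shape=φ, rate=φ)`, giving `Var(D) = λ + λ²/φ` and the
Poisson limit as `φ → ∞`. The log pmf is evaluated with log-gamma
functions and is stable far beyond the count range of any state-year
panel (tested to `y = 10⁶`).

Three intercept structures share this likelihood:

* **mundlak** — partially pooled state intercepts
  `α_s ~ Normal(ᾱ, τ)` plus the state mean of the standardized
  exposure as a covariate (coefficient `β₅`);
* **fixed_effects** — independent `α_s ~ Normal(−10, 1)`, no
  group-mean term;
* **naive** — partially pooled intercepts *without* the group-mean
  term. This variant is deliberately misspecified under state-level
  confounding and exists to demonstrate, by simulation, why the
  group-mean covariate matters.

Priors are weakly informative: `ᾱ ~ Normal(−10, 1)` (a baseline rate of
`exp(−10) ≈ 4.5` per 100,000 person-years), `τ ~ Exponential(1)`,
`β_k ~ Normal(0, 1)` on standardized covariates, and
`φ ~ Exponential(1)`. No prior for the dispersion is dictated by the
modeling tradition this package follows, so the Exponential(1) choice
is a convention consistent with the other weakly informative priors;
it is overridable through `PriorConfig`, as are all hyperparameters.

Design construction: the exposure and the two crime rates are
standardized by the pooled sample mean and n−1 SD across all
state-years (one transform per variable, invertible via the stored
parameters); the crime interaction is the product of the two
standardized rates, keeping its coefficient on the same per-SD scale;
the group mean `Ḡ_s` is computed on the standardized scale so `β₅`
shares units with `β₁`. The offset is the natural log of the raw
person-count population — rates per 100,000 appear only in reports,
never in the likelihood. Unbalanced panels are accepted with a warning.

## Identification

Unobserved state-level factors (culture, legislation, enforcement) can
raise both long-run gun ownership and baseline homicide rates. In a
random-effects model this correlation between the exposure and the
intercepts biases the exposure coefficient. The Mundlak device inserts
the group mean of the exposure as a covariate: since the state-mean
exposure is a descendant of the unobserved state factors, it soaks up
the between-state (confounded) variation and leaves `β₁` identified by
within-state changes, as in a fixed-effects model, while retaining
partial pooling. The synthetic-data generator reproduces exactly this
causal structure so the claim is testable.

## Sampler

The `built_in` backend is an adaptive random-walk Metropolis sampler
applied coordinate-wise (Metropolis-within-Gibbs). Design choices:

* **Unconstrained scale.** `τ` and `φ` are sampled as logs with the
  Jacobian adjustment; draws are reported on the natural scale.
* **Shear reparameterization.** With only a couple of percentage
  points of within-state exposure variation, covariate columns are
  nearly collinear with the state intercepts, and plain coordinate
  updates crawl along the resulting ridge (effective sample sizes of
  ~5 in early experiments). Every likelihood column therefore enters
  the sampler as its within-state deviation, with its state-mean
  component folded into sheared intercepts
  `a_s = α_s + Σ_j c_j x̄_{js}`; for the Mundlak model the exposure's
  total between coefficient (`β₁ + β₅`) becomes a separate coordinate
  whose full-conditional involves only priors. This is an exact linear
  reparameterization (unit Jacobian) — the posterior is unchanged, only
  the proposal geometry improves (ESS for `β₁` ≈ 950 out of 4,000
  draws at the default configuration).
* **Block intercept updates.** All state intercepts are proposed at
  once with independent per-state accept/reject decisions, valid
  because likelihood and intercept prior factorize over states given
  the global parameters; per-state likelihood deltas are accumulated
  with a bincount. One sweep costs a handful of vectorized
  likelihood evaluations regardless of the number of states.
* **Adaptation.** Per-coordinate proposal scales adapt toward a 0.44
  acceptance rate in windows of 50 iterations, during warmup only, so
  the post-warmup chain is a valid fixed-kernel Markov chain.
* **Initialization.** Chains start from jittered, data-informed points
  (log crude rates per state); initialization retries until the
  posterior is finite and fails loudly after 50 attempts.
* **Determinism.** All randomness flows from `SamplerConfig.seed`
  through per-chain `SeedSequence` spawns; identical seed, config and
  data give bit-identical draws.
* **Anomaly counter.** Proposals with non-finite posterior evaluations
  after warmup increment `sampler_warnings` (the analogue, for this
  sampler family, of divergence warnings in gradient-based samplers).
* `fix_phi` pins the dispersion, which turns the model into a Poisson
  regression in the `φ → ∞` limit — used by the conjugate
  Poisson-Gamma oracle test.

An `external` backend delegates to emcee's affine-invariant ensemble
sampler on the same unconstrained posterior and serves as an
independent cross-check in the test suite; the two backends agree on
posterior means within Monte-Carlo error.

Defaults are 4 chains × 1,000 warmup × 1,000 sampling iterations.
The replicate study uses 2 chains × (500 + 500), which keeps each fit
under ~1 s at the 900-observation scale.

## Diagnostics and summaries

* **Split-R̂** follows the half-chain formulation:
  `R̂ = sqrt(((N−1)/N·W + B/N)/W)` over the 2m half-chains; a
  rank-normalized variant is available. Zero within-chain variance
  yields a NaN sentinel rather than a silent 1.0.
* **ESS** is the autocorrelation-based estimate with Geyer
  initial-monotone truncation (delegated to arviz), with the same
  degenerate-input sentinel.
* **HPDI**: draws are sorted and the narrowest contiguous window
  containing `ceil(mass·n)` draws is returned; ties break toward the
  lowest lower bound; the default mass is 0.89. A count-symmetric
  equal-tailed interval on the same `ceil` rule is provided for
  comparison and is never narrower than the HPDI.
* **Reporting triple**: posterior mean, posterior SD (reported as
  "SE"), and the HPDI.
* **IRR**: `exp(β)` per one exposure SD; percent changes keep full
  precision internally and round to integer percent only for display.

## Synthetic panel generator

The generator emulates the structure of a 50-state × 18-year firearm
mortality panel with restricted-access real counterparts, so the whole
pipeline is testable offline:

* Per state: a standard-normal confound `U_s`; baseline intercept
  `α_s = ᾱ + γ·U_s`; mean ownership
  `m_s = 40 + s_b·(δ·U_s + V_s)/√(1+δ²)` with independent `V_s`, so
  `δ` is a unitless confound loading (`corr(m_s, U_s) = δ/√(1+δ²)`)
  and `s_b` fixes the between-state ownership spread independently of
  the confound strength; log-normal populations, constant over years
  (an optional drift knob exists).
* Per year: ownership `G_st = m_s + Normal(0, within SD)`; violent and
  property crime rates follow stationary AR(1) series around
  state-specific means, generated independently of the exposure (an
  optional loading exists for sensitivity experiments, default 0).
* Counts: Gamma-Poisson at
  `log λ = log π + α_s + β·(standardized covariates)`, where the true
  coefficients apply to the covariates exactly as a fitted model sees
  them (standardized pooled over the realized sample), making recovery
  comparisons exact rather than approximate.

Default calibration (all configurable): ownership mean 40%, between-SD
13.45 and within-SD 2 percentage points (total SD ≈ 13.6), ownership
clipped to [2, 70] (clip events are counted in the truth record);
`ᾱ = −10`, `β₁ = 0.06`, `φ = 5`; populations log-normal around 4
million with log-SD 0.9; crime levels around 380 (violent) and 3,000
(property) per 100,000 with AR(1) autocorrelation 0.85; confound
loadings `γ = δ = 0.5`; crime effects 0.2 and 0.1 per SD with no
interaction, chosen as plausible crime–homicide gradients. With these
settings a generated panel has median death rates, ownership and crime
levels in the ranges of the emulated panel (see
`calibration_report`), though its year-to-year count noise is heavier
than real mortality series (pure overdispersion, no smooth time
trends).

What the generator does **not** emulate: spatial correlation between
neighboring states, interstate firearm flows, national time trends,
population drift (off by default), and exposure measurement error.
Passing recovery tests therefore show that the estimators do what they
claim under the assumed causal structure — not that the real-data
estimates are correct.

## Recovery study and findings

`recovery_study` simulates replicate panels and fits any subset of the
three model variants at reduced draws (2 × 500 after 500 warmup),
recording posterior mean/SD, the 89% HPDI, truth coverage and the
z-distance from truth; seeds derive deterministically from one base
seed. The acceptance suite runs 60 replicates — enough that the
binomial spread of a nominal 0.89 coverage rate is well inside a
[0.70, 0.99] band.

Findings computed by the suite and `scripts/acceptance.py`:

* The **Mundlak** model is well calibrated: coverage ≈ 0.88–0.92,
  mean bias within one Monte-Carlo SE of zero, posterior SD matching
  the frequentist spread of the estimates.
* The **naive** random-intercept model (no group-mean term) is pulled
  more than 2 posterior SDs from the truth in roughly three quarters
  of replicates — the simulated demonstration of why the Mundlak
  device is needed.
* The **fixed-effects** variant is *not* bias-free under these
  conditions: its informative `Normal(−10, 1)` intercept prior shrinks
  the free intercepts toward a common constant, which re-admits a
  fraction of the confounded between-state slope. With per-state
  intercept likelihood variance ≈ 0.012 against prior variance 1, that
  weight is ≈ 0.4, giving a systematic bias of ≈ +0.07 on `β₁`
  (coverage ≈ 0.82, still inside the band, because the bias is about
  one posterior SD). The effect was verified against a
  negative-binomial GLM with state dummies, so it is a property of the
  model, not of the sampler. It shrinks as within-state exposure
  variation grows or the intercept prior widens; per-replicate Mundlak
  and fixed-effects means nonetheless agree within 2 posterior SDs in
  every replicate.

## Numerical choices and degenerate inputs

* Linear predictors above 700 on the log scale would overflow `exp`;
  the log likelihood returns −∞ with a warning and samplers treat the
  point as rejected. The generator refuses configurations whose true
  log rate exceeds 30.
* Standardizing a constant vector, an empty group in group-mean
  computation, fewer than 10 draws for an HPDI, fewer than 2 chains,
  and non-integer or negative counts all raise typed errors rather
  than propagating NaNs; constant chains yield NaN diagnostics
  sentinels by design.
* Kernel density summaries use a Gaussian KDE with Silverman
  bandwidth on a regular grid over the draw range (flagged, not
  estimated, for point-mass draws); bandwidth affects plots only.
* CSV is the canonical exchange format; every CLI output directory
  carries a manifest (command, config hash, data hashes, seed,
  timestamp, version) sufficient to reproduce it bit-for-bit.

## Known limitations

* The built-in sampler is random-walk based: robust and dependency
  free, but it needs the shear reparameterization to mix on this
  model family and would scale poorly to models with many more global
  parameters.
* "SE" follows the reporting convention of the source literature
  (posterior SD), which differs from a frequentist standard error.
* The FE prior-leak bias above means the fixed-effects variant should
  not be treated as an assumption-free benchmark when between-state
  signal is strong and within-state exposure variation is weak.
* Real state-year mortality panels have features (secular trends,
  spatial dependence, varying populations) that the generator omits;
  conclusions about real data must rest on the real analyses, not on
  these simulations.
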