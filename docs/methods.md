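# Methods

`smfm` implements a stochastic mechanism-fitting model (SMFM): candidate
social and asocial learning mechanisms are written as components of a
continuous-time rate model for bouts of interaction with a two-box,
two-option foraging task, and fitted to time-structured event logs from
group diffusion experiments.  This note records the model, its
assumptions, the numerical choices, and what the synthetic-data studies
do and do not demonstrate.

## The rate model

Each individual *i* of group *j*, while attending a session and not
already mid-bout, initiates bouts at option-type *k* ∈ {flap, tube} on
box *l* ∈ {left, right} with rate

```
rate_ikl(t) = r_k · exp(β·x_i + u_i + v_j) · (1 + γ·A_ik(t) + T_ikl(t))
```

* `r_k` — baseline rate (events/s) per option-type.
* `β·x_i` — time-constant covariates (age class, sex, dominance;
  treatment contrasts against adult/F/subordinate); `u_i ~ N(0, σ_ind²)`
  and `v_j ~ N(0, σ_group²)` are log-scale random effects.
* `A_ik(t)` — the learned association of option-type *k* with reward,
  using the count-based closed form of the Rescorla–Wagner rule
  extended with observation counts:

  ```
  A = 1 − (1 − λ_a)^R · Π_c (1 − s_c)^{O_c}
  ```

  `R` counts past rewarded bouts at *k* (all sessions), `O_c` counts
  past observations of others manipulating *k*, split into nested
  increment classes *c* ∈ {manipulation seen, entry seen, feeding
  seen}: an observation that includes seeing the actor feed increments
  all three counters, so `s_entry` is the *additional* effect of seeing
  entry beyond seeing a manipulation.  `λ_a` is indexed by dominance
  class because asocial learning differs sharply between dominants and
  subordinates in this system.
* `γ` — relative influence of learning on the initiation rate.
* `T_ikl(t)` — transient social effects, decomposed hierarchically into
  a general kernel (any observed manipulation, any option), a box-level
  local-enhancement kernel (same box), a specific local-enhancement
  kernel (same option and box), and an optional same-option-type
  (stimulus-enhancement) kernel.  Each kernel is
  `g · exp(−ρ·(t − τ))` where τ is the time of the *most recent*
  qualifying observation in the current session (not a sum over
  history), and all kernels share one decay rate ρ; `ln 2 / ρ` is the
  half-life of the transient effects.  The raw same/different-option ×
  same/different-box contrasts (SOSB, SODB, DOSB, DODB) are an exact
  linear map of the hierarchical strengths
  (`kernel_contrasts`/`strengths_from_contrasts`), and stimulus
  enhancement corresponds to SODB > DODB, i.e. `g_sametype > 0`.

**Composition caveat.**  The additive composition
`(1 + γA + T)` — transient effects add to the learning multiplier,
both scaled by the baseline — is a reconstruction: it matches the
convention of reporting transient effect sizes as multiples of the
baseline rate, but a fully multiplicative composition is defensible
too.  The composition is isolated in one place
(`RateDecomposition` and the two likelihood kernels in
`smfm_core`) so the alternative can be swapped in without touching
anything else.

**Timing semantics.**  Experience counters step at bout/observation
*end* times and a query at exactly the end time does not include the
event, so no covariate ever reflects the bout it describes.  The
transient clocks are set at observation end times, *do* count an
observation ending exactly at the query time (the effect is at full
strength immediately after observation), and reset at every session
start; counters carry across sessions.  Bouts recorded at "other"
contact points are kept in the log but excluded from the four-option
model and from experience counts.

**Condition variants.**  Which events set the transient clocks is an
event-class filter: `any` recorded observation (default), only
observations including `entry`, only `feeding`, or `all_present`
(every bout end sets the clocks of every other attendee, observed or
not).  These variants, plus removal of the transient kernels entirely,
are the model set compared by DIC.

## Likelihood

Bout initiations form a competing-risks inhomogeneous point process
over the four options.  For each individual × session the log-likelihood
is Σ log rate at each initiation (left-limit state) minus the integrated
hazard over all at-risk time (attending, not mid-own-bout), summed over
options.  Between consecutive state-change times (own bout boundaries,
own observation ends, clock updates) the rate is a constant plus a sum
of decaying exponentials, so the integral is closed-form per segment.
`SMFMLikelihood` compiles a log once into flat segment/event arrays and
evaluates the exact log-likelihood as a vectorized function of the
parameters (~1–3 ms at the problem sizes used in the tests).
Demonstrators' bouts feed other individuals' experience but
demonstrators are excluded from the fitted process.

The test suite checks this path against a dense-grid numerical
integration of the pointwise rate (0.01 s grid) on batches of randomly
parameterized small experiments, at 1e−4 absolute agreement.

## Inference

Sampling is single-block adaptive random-walk Metropolis on transformed
parameters (log for rates/strengths/γ/ρ, logit for λ and s, identity
for contrasts and random-effect values).  Chains start at a MAP
estimate (L-BFGS); the initial proposal covariance is a Laplace
approximation (central-difference Hessian at the MAP,
eigenvalue-floored at 1e−4 to keep ridge directions finite); during
burn-in the global scale adapts by Robbins–Monro toward 0.234
acceptance and the covariance is re-estimated twice from the
accumulated history, resetting the scale-adaptation clock each time.
Runs are exactly reproducible from the seed.

Priors (the original analysis printed none; all overridable via
`PriorSpec`): half-normal(0, 0.05) on baseline rates, uniform(0, 1) on
λ and s, half-normal(0, 20) on γ, half-normal(0, 50) on transient
strengths, half-normal(0, 0.5) on ρ, normal(0, 2²) on covariate
contrasts, half-normal(0, 1) on random-effect SDs with centred
individual/group effects.  Random effects are implemented but off in
the default fitted variant; at the reduced problem sizes of the test
studies they are not identifiable and the simulated groups are
exchangeable by construction.

Summaries: posterior medians, 95% highest-posterior-density intervals
(shortest sorted window, checked exactly against a brute-force scan),
inequality probabilities as posterior fractions, split-R-hat and ESS
via ArviZ with warning gates at R-hat > 1.05 and ESS < 200.
DIC = Dbar + pD with pD = Dbar − D(posterior mean of the transformed
parameters); a negative pD warns but does not fail.

## Bout outcomes (Cox analyses)

Within a bout, solving and abandonment are competing terminal events;
each gets its own Cox proportional-hazards analysis with the other
outcome censored.  Covariates are frozen at bout start: prior
successes/failures at the same and other option-type, ever-solved flag,
observed feeding successes, and a recency term `exp(−ρ̂·Δt)` for the
time since another individual last manipulated the same option at the
same box (0 if never this session; ρ̂ normally the fitted posterior
median, so the covariate is bounded and needs no arbitrary cap).
Counts enter untransformed so coefficients are per-event multipliers.

The partial likelihood uses the Efron tie approximation (Breslow by
flag) and is maximized by Newton–Raphson with analytic gradient and
Hessian (gradient tolerance 1e−8, step-halving on decrease).  Evidence
per covariate comes from all-subsets AIC averaging: Akaike weights over
all 2^k subsets (non-convergent or rank-deficient fits are dropped with
a warning), model-averaged coefficients with absent models contributing
zero, unconditional standard errors per Burnham–Anderson
(Σ w_m √(var_m + (b_m − b̄)²)), and back-transformed multipliers with
95% unconditional CIs.  The fits are fixed-effects only: the original
mixed-effects (nested group/individual frailty) Cox formulation is
*not* reproduced, so clustering by individual is unmodelled; at the
simulated scales used here bouts per individual are few and the
averaging targets are generated marginally, but on real data the
unconditional intervals will be somewhat anti-conservative.

## Option-bias test

The traditions test statistic is Σ_g n_g·|p_g − p̄| over groups (p_g =
group's flap proportion among units — individuals or manipulations —
and p̄ the pooled proportion).  The null distribution reallocates every
unit's option i.i.d. Bernoulli(p̄) preserving group sizes, with the
add-one Monte-Carlo p-value (1 + #{T* ≥ T}) / (1 + n_perm).  The exact
modification used in the original analysis is not recoverable from the
main text, so this standard randomization form with an explicit,
configurable statistic and unit is a documented reconstruction.  A
type-I-error simulation (coin-flip null tables) keeps the rejection
rate near nominal, and a two-group exact enumeration oracle checks the
Monte-Carlo p-value.

## Simulator

`simulate_experiment` generates complete experiments by Ogata thinning:
between state changes every rate only decays, so the total rate just
after the latest state change bounds the future rate and candidate
events are accepted with probability rate(t)/bound.  Bout durations and
outcomes come from competing exponential solving/abandonment hazards
with log-linear covariate effects frozen at bout start (solved bouts
set entered-box and obtained-food; bouts truncated by session end are
abandoned).  Observers are sampled i.i.d. with probability `p_obs`
among attendees not mid-bout during the observed bout, and observation
rows span the full target bout.  Demonstrators are scripted — a fixed
number of successful demonstrations of their trained option per session
at random non-overlapping times — and never appear as observers.

Default design: 9 groups of 12–24, 8 sessions of 3–35 min (mean
19 min), demonstrators (subordinate adult males) in 6 of 9 groups
(three per option-type), `p_obs = 0.4`.  Default parameters: baseline
1.6e−4 events/s/option (the observed pre-observation initiation rate),
λ = 0.051 (subordinates) / ~0 (dominants), s_entry = 0.0035, half-life
20 s, specific-enhancement-dominated transient strengths that are
larger in younger animals.  γ and the g magnitudes have no published
point estimates; γ = 5 and g_specific ≈ 3–8 (by age) were chosen once
as values that make learning and enhancement clearly visible at field
scale, and are recorded in every ground-truth file.

What the simulator does *not* emulate: spatial movement and proximity
(observation is a Bernoulli abstraction of the 1 m/orientation
criterion), attendance variation within sessions, satiation beyond the
covariate effects, inter-observer transcription error, and any
dependence of observation probability on rank or kinship.  Passing
recovery tests therefore shows the estimator is correct *under the
model*, not that the model is correct for field data.

## Problem sizes used by the test studies

The statistical studies run at reduced, study-shaped sizes chosen as
the package's own test scale: the likelihood-oracle batch uses 4–6
animals and 1–3 sessions of 40–60 s with inflated baselines
(0.005–0.03 events/s); the recovery and DIC studies keep the 9-group ×
8-session, 6-seeded design shape and the generating values λ = 0.05,
s_entry = 0.004, half-life 20 s, g_specific = 5 (specific-dominated),
but use 4-animal groups, 600 s sessions, baseline 3e−3, and two chains
of 3000 iterations (1200 burn-in) started at the MAP.  Fewer animals
with longer sessions was chosen over the reverse because per-individual
reward counts must reach the saturating region of the Rescorla–Wagner
curve for λ, γ and s to separate from the baseline rate; at equal total
event counts, spreading events thinly across many animals leaves the
posterior on a prior-dominated ridge where baseline and learning
multiplier trade off.  Paper-scale designs are available through the
same API (`make_design()` defaults) and the CLI.

## Known limitations

* The algebraic composition of learning and transient effects is a
  documented reconstruction (see above).
* γ is only weakly separated from λ and s at small data sizes; the
  posterior is ridge-shaped and prior-sensitive there.
* Fixed-effects Cox (no frailty); see the bout-outcomes section.
* One shared ρ across kernels and age classes; per-kernel decay rates
  would need a different parameter space.
* The sum-over-history alternative to the most-recent-observation
  kernel is not implemented; the kernel structure makes the swap local
  to `_kernel_terms` and the likelihood compiler.
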