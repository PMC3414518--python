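# smfm — stochastic mechanism-fitting models for social learning

Field studies of animal social learning face a dilemma: controlled
demonstrator/observer experiments identify learning *mechanisms* but
destroy the natural social setting, while group diffusion experiments
preserve the setting but classically yield only coarse evidence that
"something social" happened.  `smfm` implements the stochastic
mechanism-fitting approach for the second kind of data: hypothesized
mechanisms are written as components of a continuous-time hazard model
of task interaction, fitted directly to the timed event log of a
diffusion experiment, so that each mechanism's presence, strength and
duration is estimated rather than inferred from group-level contrasts.
It is written for behavioural ecologists analysing seeded or unseeded
diffusion experiments (the motivating system is wild meerkat groups
confronted with a two-option foraging box), and for methodologists who
want a fully simulable test bed for such models.

## The model

Individual *i* of group *j* initiates bouts at option-type
*k* ∈ {flap, tube} on box *l* ∈ {left, right} at rate

```
rate_ikl(t) = r_k · exp(β·x_i + u_i + v_j) · (1 + γ·A_ik(t) + T_ikl(t))
```

with `A = 1 − (1−λ_a)^R · Π_c (1−s_c)^{O_c}` the Rescorla–Wagner
association built from `R` past rewards and `O_c` past observations of
class *c* (manipulation/entry/feeding seen), and
`T = Σ_kernels g · exp(−ρ·(t − τ))` transient social effects decaying
from the most recent observed manipulation this session (general,
same-box, same-option-and-box, and optional same-option-type kernels;
half-life `ln 2 / ρ`).  The exact likelihood treats initiations as a
four-option competing-risks point process.  Companion analyses:

* Bayesian fitting by adaptive Metropolis with medians, 95% HPD
  intervals, inequality probabilities and DIC comparison of
  observation-condition variants (`smfm.inference`);
* AIC-averaged Cox models of within-bout solving and abandonment with
  unconditional confidence intervals (`smfm.bout_outcomes`);
* the option-bias randomization test for group traditions
  (`smfm.traditions`);
* a forward simulator producing valid event logs from known ground
  truth by Ogata thinning (`smfm.simulator`).

See `docs/methods.md` for assumptions, priors, and numerical choices.

## Worked example

Simulate a small seeded experiment and refit it:

```sh
smfm init-config --out cfg --scale small --seed 0
smfm simulate --design cfg/design.yaml --params cfg/params.yaml \
              --seed 7 --out demo_log
smfm validate demo_log
smfm fit --log demo_log --iters 2000 --burn 800 --seed 1 --out demo_fit
```

`validate` prints

```
OK: 17 individuals, 12 sessions, 396 bouts, 302 observations
```

and `fit` ends with the posterior table (medians and 95% HPDs on the
natural scale; the desk-scale config generates from baseline 3e−3,
λ = 0.051, s_entry = 0.0035, γ = 3, g_specific = 5, half-life 20 s):

```
              median    hpd_lo     hpd_hi        ess      rhat
r:flap      0.002544  0.001610   0.003513  36.141654  1.051060
r:tube      0.003093  0.001920   0.004281  30.770385  1.051103
lambda      0.095845  0.003043   0.355924  36.913937  1.094183
s:entry     0.034738  0.000411   0.188549   8.837694  1.172962
gamma       2.342811  0.655734  11.871623  24.556464  1.162069
g:general   1.674892  0.421719   3.301455  50.647176  1.014109
g:box       0.700285  0.000487   2.862029   4.009382  1.457115
g:specific  6.698385  3.188053   9.520467  38.843105  1.049455
rho         0.051824  0.029190   0.078014  85.090458  1.011446
```

Read: the baseline rates bracket the generating 3e−3 initiations/s per
option; the transient effects are dominated by the specific (same
option, same box) kernel — ~6.7× baseline immediately after an
observation, HPD [3.2, 9.5] around the generating 5 — decaying with
half-life `ln 2 / 0.052 ≈ 13 s`; the asocial and social learning rates
are small with wide HPDs.  A 12-session desk log cannot pin λ, s or γ
sharply (note the low ESS / high R-hat warnings the command prints for
exactly those parameters); the full-scale `--scale study` config and
longer chains are the serious setting.

The Cox and traditions analyses run the same way:

```sh
smfm cox --log demo_log --outcome abandonment --rho 0.0347
smfm option-bias --counts counts.csv --n-perm 9999 --seed 2
```

(`counts.csv` has columns `group,n_flap,n_tube[,seeded_option]`, one row
per group.)

The library mirrors the CLI one-to-one (`simulate_experiment`,
`SMFMLikelihood`, `run_mcmc`, `summarize`, `compare_variants`,
`build_bout_table`, `all_subsets_average`, `option_bias_test`,
`recovery_harness`).

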