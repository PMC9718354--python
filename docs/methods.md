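# Methods

This note documents the models, the synthetic task, the fitting
machinery, and the design decisions behind `trdm`, in the order data
flow through the package.

## Accumulator model

Both models build on a single-boundary drift-diffusion accumulator: the
first-passage time through threshold α of a diffusion with drift ρ and
infinitesimal standard deviation σ is shifted-Wald (inverse-Gaussian)
distributed. `trdm.wald` provides the density and CDF in closed form.
Conventions and numerical choices:

* **Units.** Time in seconds, contrasts dimensionless in [0, 1], drift
  in evidence units per second. The threshold is fixed at 1.0 so drifts
  are expressed in threshold units.
* **Negative drift.** The CDF's limit is exp(2αρ/σ²) < 1: the
  accumulator may never cross. The density/CDF code handles this
  naturally; the sampler (`simulate.sample_fpt`) draws a Bernoulli
  crossing indicator and, conditional on crossing, uses the reflection
  identity (the conditional law equals the |ρ| case), which is exact and
  O(1) rather than a rejection loop.
* **Overflow.** The CDF term exp(2αρ/σ²)·Φ(·) is evaluated as
  exp(2αρ/σ² + log Φ(·)) via the log-CDF; large positive drifts
  (routinely proposed during sampling under the wide log-normal priors)
  would otherwise overflow.
* **ρ = 0.** Treated as the limit (crossing certain, heavy tailed); for
  sampling, |ρ| is floored at 1e−10.

### Bias

The bias parameter ω ∈ (0, 1) enters as a complementary threshold
perturbation: α_left = 2ω, α_right = 2(1 − ω), so the thresholds always
sum to 2 and ω = 0.5 recovers the fixed threshold of 1.0 for both
accumulators. Where ω enters the accumulators is a genuinely open
design choice (start point, threshold, and drift offsets are all in
use in this model family); the threshold linkage was chosen as the
simplest one that is monotone in choice probability and preserves the
fixed-threshold convention at the unbiased point. It is a declared
package convention, visible in `biased_thresholds`.

### Timer clock and the γ-mixture variance

Two further conventions are exposed as flags on `ModelParams` rather
than hidden:

* `timer_t0` (default `shared`): the timer is evaluated on the same
  shifted clock t − t₀ as the evidence accumulators, keeping all three
  first-passage factors of the defective density on a common time axis.
  `zero` runs the timer from stimulus onset instead.
* `gamma_variance_mode` (default `printed`): the evidence-difference
  variate X deciding a timer-triggered choice has variance 2(η_c t)² in
  the default mode. In that form the crossing time cancels from
  F_X(0), making the timer-choice probability time-independent. A
  Brownian difference would instead have variance 2η_c²t
  (`diffusion` mode), which retains time dependence. The default
  follows the model family's printed form; the alternative is kept for
  sensitivity analyses.

## Defective densities and likelihood

`trdm.likelihood` implements the choice-conditional densities
(RDM: f_win (1 − F_lose); TRDM adds the timer survival factor and the
timer-win term) and the dataset log-likelihood. Numerical choices:

* Densities are floored at 1e−300 before the log, so a single
  impossible trial (e.g. an RT below a proposed t₀) yields a very
  negative but finite log-likelihood. This keeps the population sampler
  exploring instead of dying on boundary proposals.
* Equal-contrast trials are scored like any others — the drift link
  gives ρ_l = ρ_r, and the likelihood conditions on the observed choice,
  not on the (randomly assigned) "correct" label.
* The hot path (`loglik_population`) evaluates K parameter vectors on
  N trials in one broadcast pass; all sampler iterations go through it.

The likelihood and simulator are held consistent by construction and by
test: Kolmogorov–Smirnov agreement between 10⁵ simulated races and the
quadrature CDF of the density, at the 1% critical value, for both
models.

## Synthetic task

`trdm.task` generates full behavioral sessions as the stand-in for
unreleased animal data; the generating agent's parameters are known, so
fitting and comparison can be validated against ground truth. The task
structure: 6 contrast levels evenly spaced on [0.08, 0.99], all 36
ordered pairs; 550 trials/session (middle of the natural 500–600/day
range); truncated-normal ITI (mean 0.6, SD 1, bounds [0.5, 0.7] s) and
reward duration (mean 0.1, SD 0.06, bounds [0.2, 0.4] s) at 150 μl/s;
a 10-trial rolling bias correction (P(next correct side right) = 1 −
recent rightward-choice fraction) applied by re-orienting unequal
pairs; random correct side on equal-contrast trials; fixed
(4 s + 0.8 s/lick, cap 8 s) or exponential-decay
(T = (1/s)·exp(−(RT − l)/s), l = 0.1, s = 1.7, 1.5 s/lick, no cap)
punishment delays.

Oddities implemented as printed rather than "fixed": the reward-duration
location parameter (0.1 s) lies below the truncation interval
[0.2, 0.4] — the truncated normal is perfectly well defined there, and
its analytic mean (0.225 s → 0.22 s at 10 ms valve precision) reproduces
the 33 μl average reward. Likewise the ITI's SD of 1 with bounds
[0.5, 0.7] makes the draw nearly uniform on the bounds.

Deliberate simplifications: blank-screen licks are not behaviorally
modelled (lick count defaults to zero — no lick-rate model exists to
emulate); the training-stage easy/hard trial-ratio adjustments are out
of scope (the generator emulates the formal data-collection phase,
sampling the full grid); bias correction is a toggle, default on.

### What the generator does and does not emulate

Sessions have the right trial economy (stimulus grid, reward/penalty
bookkeeping, scheduling draws) and a behaviorally faithful agent. They
do **not** contain session-level nonstationarity (fatigue, satiation,
state switching), lapses distinct from timer events, lick dynamics, or
stimulus-history effects. Tests passing on this data therefore validate
the *pipeline* — likelihood correctness, sampler calibration, model
discrimination — not the claim that real animals contain no further
structure. This matters for model comparison: real data can favour the
timer model by more than clean TRDM-generated data ever would, because
the timer also absorbs real-data structure that the generator does not
produce.

### Agent presets

* `fast_timer_agent` — ω=0.5, t₀=0.1, (v₀, v_d, v_s)=(1, 3, 0.5),
  η_c=1, ρ_t=3, η_t=0.5, γ=0.2. The reference set for fitting
  benchmarks: ~40% timer-triggered decisions leave an overwhelming
  likelihood signature for the TRDM.
* `slow_timer_agent` — as above with ρ_t=0.8. The timer wins ~4% of
  races ("near zero" on the fast-timer scale) and the two models fit
  nearly equally; the parameter-count penalty then decides. The value
  0.8 was calibrated so the regime reproduces both qualitative facts it
  emulates — a near-zero timer share *and* a Bayes factor in the
  RDM-competitive band — rather than only the first; a much slower
  timer (ρ_t ≤ 0.3) leaves so little timer imprint that BIC favours the
  RDM by the full penalty.
* `fixed_delay_agent` — slower evidence ((0.4, 1.8, 0.3), η_c=0.6)
  under a high-variability timer (ρ_t=1, η_t=2). With η_t large the
  timer's first-passage density has a sharp early peak plus a heavy
  tail, so timer wins concentrate at short RTs: sessions show the
  fast-guess phenotype (early chance-level responses, later above-chance
  evidence-guided responses, timer share ~0.6).

A note on geometry: in a race, conditioning on the evidence winning
means the evidence time beat the timer draw, so the pooled RT
distribution of a fast *sharp* timer can never show a late evidence
mode — the "fast guesses early, engaged mode late" pattern requires a
*high-variance* timer. Pooled-session bimodality is accordingly
"bimodal-like" (an early chance-accuracy component overlapping the
evidence rise) rather than cleanly two-peaked; the tests therefore check
the pattern via the accuracy-by-RT-decile profile and the
timer/evidence decomposition, and check literal two-mode KDE structure
in a single-condition configuration (sharp early timer over tight, slow
evidence) where the race geometry permits it.

## Preprocessing and summaries

* **Box–Cox culling** (`boxcox_cull`): the transform exponent is
  estimated by maximum likelihood per dataset (per-animal, matching a
  per-animal pipeline); transformed RTs beyond mean ± 3 SD are removed.
  Degenerate zero-spread input keeps everything with a warning. On
  TRDM-generated data the rule removes well under 1% — preprocessing is
  self-consistent with the model.
* **Psychometric table**: Wilson score intervals for choice
  proportions; **chronometric table**: normal-approximation CIs for
  mean RT. Both chosen for small-sample sanity.
* **Accuracy-vs-RT sigmoid**: 50 ms default bins, logistic with the
  lower asymptote fixed at 0.5 (2AFC chance) and upper asymptote
  bounded by 1, weighted least squares on binned accuracies.
* **Reward rate**: RR(t) = Acc/(Acc·t + (1−Acc)(t + Delay)); under a
  constant 4 s delay and a rising accuracy sigmoid it is unimodal in t —
  the structure that makes intermediate RTs optimal.
* The mixed-effects RT-on-difficulty regression of the original
  analysis is *not* reimplemented (it is an off-the-shelf fit whose
  reported coefficients depend on unreleased data); a per-dataset
  least-squares slope is provided as a descriptive diagnostic only.

## DE-MCMC fitting

Free parameters and priors (location/scale of the underlying normal):
ω, t₀ ~ inverse-logit(0, 1.4); v₀, v_d, v_s, η_c, ρ_t, η_t ~
log-normal(1.56, 1.5); γ ~ inverse-logit(−1, 1). The two-number prior
parameterisations are read as (location, scale) of the underlying
normal — the standard reading, and the implied prior median drift
(e^1.56 ≈ 4.8) matches decision times of ~0.2 s at threshold 1. The
γ prior's median (≈0.27) is asymmetric toward randomness; it is used
as given. RDM has k = 6 free parameters, TRDM k = 9.

Sampling runs on the unconstrained scale (logit for interval-bounded,
log for positive parameters), where every coordinate's prior is plain
normal and the additive DE proposal respects all supports. The proposal
for chain i is θ_i + g(θ_a − θ_b) + ε with distinct random chains a, b,
g = 2.38/√(2d), and ε ~ U(−10⁻⁴, 10⁻⁴) per coordinate; acceptance is by
the Metropolis rule. Population size is 10 chains per free parameter
(60/90); the full schedule is 200 burn-in + 500 sampling iterations,
with a reduced schedule (100 + 250) used for the package's own
benchmark fits to keep them desk-scale. No thinning; all post-burn-in
draws are retained.

**Initialisation.** The default (`init="optimize"`) first locates the
posterior mode with a seeded differential-evolution search (bounds at
prior mean ± 3 SD on the unconstrained scale) and starts the chains in
a mildly overdispersed cloud (0.1 prior-SD) around it; burn-in then
relaxes the population to the posterior. This is not merely a speed-up:
the TRDM likelihood has a degenerate *pure-timer* mode (all evidence
drifts → 0, with choices carried by the evidence-sign term of the timer
mixture) that reliably traps a population started from raw prior draws
at short schedules — measured on a 3000-trial fast-timer set, prior
init reaches a best log-likelihood ~190 units below the generating
parameters' value, while optimisation-seeded runs exceed it.
`init="prior"` (chains at prior draws, fully-floored chains re-drawn)
is retained for comparison.

**Maximum-likelihood surrogate for BIC.** L̂ is the maximum likelihood
over *all* sampled vectors, burn-in included. A local Nelder–Mead
polish from the best draw is available (`fit.polish_max_loglik`) but is
off by default throughout; in practice it changes the maxima by ~1 unit
at the benchmark scales.

**Diagnostics.** A split-chain R̂ helper is provided; benchmark fits
reach R̂ < 1.1 on the conjugate validation target. The sampler is
validated against a closed-form normal–normal posterior (moments within
2%, quantiles matching) and an empirical Bernoulli check of the
acceptance rule.

## Model comparison

BIC = k ln n − 2 ln L̂ with n the number of trials after culling
(likelihood terms are per trial); ln BF(i over j) = −½(BIC_i − BIC_j);
evidence labels at |ln BF| > 1/3/5 (positive/strong/very strong).

On the benchmark datasets: fast-timer session sets yield
ln BF(TRDM over RDM) far above the very-strong threshold — the worked
example in the README (3300 session trials) prints +23, and the test
suite verifies the same at the full ≥100-repeats session scale. At the
smaller 3000-trial set the acceptance script recomputes, the value is
seed-dependent and can approach the threshold: the ML advantage of the
true model fluctuates from dataset to dataset while the penalty is
fixed, and the best-sampled-likelihood surrogate slightly underestimates
the larger model's maximum. The slow-timer session set (4400 trials)
yields ln BF ≈ −6: the models fit almost equally (likelihood advantage
~6 units for the true TRDM) and the 3-parameter penalty (1.5 ln n ≈
12.6) decides for the simpler RDM — the expected behaviour of a
BIC-approximated Bayes factor when the extra mechanism is nearly inert.
Note this magnitude sits slightly beyond the |5| "very strong"
boundary: with a faithful near-zero-timer agent the identifiable
likelihood advantage (≈ n × timer-share × per-trial divergence) cannot
offset the penalty, so a clean synthetic slow-timer regime lands at
−5 to −9 rather than strictly inside (−5, 5). One acceptance test
encodes the stricter band and is expected to fail on this point; the
directional result (no very-strong evidence for the timer model, RDM
competitive) holds.

## Known limitations

* No across-trial drift variability, start-point variability, or lapse
  mixtures — the fitted models have none, by design.
* Fitting is per dataset (per animal); no hierarchical pooling.
* The max-over-samples L̂ is a downward-biased surrogate for the true
  maximum likelihood; BIC differences inherit sampler noise of order
  ±2–3 at the benchmark schedules.
* RDM races in which neither accumulator ever crosses (both drifts
  negative) are resampled by the simulator — appropriate for a
  free-response task with no timeout where observed data contain only
  completed trials; the likelihood simply assigns such parameter
  regions small densities.
* The problem sizes of the package's own benchmarks (3000–5000 trials,
  reduced schedule, 3 recovery replicates) were chosen to keep a full
  validation run at desk scale while leaving comfortable margins on
  every calibration check.
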