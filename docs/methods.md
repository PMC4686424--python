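# Methods

`nestedrace` simulates and fits accumulate-to-bound models of inhibitory
control in two task families and derives the behavioural and
BOLD-magnitude predictions that distinguish them.  This note documents
the models, the numerical choices, the fitting protocol, and the known
limitations; the README shows the user-facing workflow.

## The execution process

All models share a single *execution* accumulator representing the net
of facilitatory (direct-pathway) and suppressive (indirect-pathway)
basal-ganglia signalling.  Its latent linear core is a Wiener diffusion

    d phi_e = v_e dt + sigma dW,

started at 0 after an onset delay `tr` (which lumps sensory encoding and
motor output delays), and the observable execution state is the
gain-scaled process

    theta_e(t) = phi_e(t) * gamma(t - tr),      gamma(u) = cosh(xb * u).

`gamma` is a dynamic urgency signal: it equals 1 at onset, is even and
non-decreasing, and accelerates the process toward the response
deadline, playing the same role as a collapsing bound.  Only the phrase
"a hyperbolic function of time with gain" constrains its form, so the
`cosh` choice is a package decision; `dynamic_gain` is a single,
swappable function should an alternative hyperbolic form be preferred.
A response is recorded iff `theta_e` reaches the boundary `a` before
the trial window `b` (0.650 s reactive, 0.555 s proactive) expires.

Parameters and units: `a` (evidence units), `tr`, `sso` (seconds),
`v_e`, `v_b` (evidence/s), `xb` (1/s), `sigma` (evidence/sqrt(s)).
`sigma` is fixed at 0.1, the conventional scaling constant of diffusion
models; it is never fitted.  `v_b` is stored as a magnitude; each model
applies its own sign.

## The three stopping models

On a reactive stop trial a stop cue arrives at delay SSD.  The models
differ in how the braking signal engages:

* **Dependent process model (DPM).**  A braking accumulator `theta_b`
  is initialised *at the current execution state* `theta_e(SSD)` and
  evolves with drift `-v_b` and the same `sigma`, without urgency gain.
  Reaching 0 cancels the response.  Stopping therefore gets harder the
  further the execution process has travelled — the nesting is the
  model's defining property.  If the braking process starts at or below
  0 (stop cue before the execution onset), the trial is cancelled
  immediately.
* **Independent race.**  The braking accumulator starts at 0 at the SSD
  and races with drift `+v_b` to the *same* boundary `a`; whichever
  accumulator arrives first decides the trial.  The shared boundary is a
  package decision (the minimal symmetric completion of the classic
  race).
* **Interactive race.**  After a registration delay `sso` (so from
  `ss_tr = SSD + sso`), an accumulating braking signal (drift `+v_b`,
  its own diffusion noise — a package decision, the source is silent on
  brake noise here) is subtracted from the execution signal; a response
  then requires the *net* signal to reach `a`.  Responses made before
  `ss_tr` stand.

Proactive trials run the execution process alone: a "no-go" outcome is
a failure to reach `a` by the deadline.  The single late 450 ms stop
signal of the proactive task is not modelled as a braking event.

Contextual modulation enters by letting one (or two) execution
parameters vary across conditions: drift (`v_e`), onset (`tr`), both,
or boundary (`a`) — with the remaining parameters shared.

## Numerical integration

Euler–Maruyama with default `dt` = 1 ms.  Step k integrates
[k·dt, (k+1)·dt]; the gain multiplies the *accumulated* `phi_e`, not the
increments.  Crossings are detected on the grid without sub-step
interpolation (first step with `theta_e >= a`, weak inequality), and a
crossing is checked before the deadline within a step, so a response at
exactly the deadline counts.  Within a stop-trial step the execution
crossing is evaluated before the braking crossing (response wins ties);
the braking state at the SSD is the execution state *before* that
step's increment.  Trial noise comes from counter-based (Philox)
streams keyed by a single seed, so trial i is reproducible regardless
of batch composition; the per-trial loops are `numba`-compiled.

Two discretization biases are worth knowing about: grid detection
rounds crossing times *up* to the next step, and the discrete path can
miss brief boundary excursions (the classic Euler first-passage
overshoot, of order `sigma*sqrt(dt)`).  At `dt` = 1 ms both are well
under a millisecond on the RT scale of these tasks; oracle tests
against the inverse-Gaussian closed forms are run at `dt` = 50 µs where
the combined bias falls below the Monte-Carlo resolution.

## Summaries and the cost function

Fits target an `ObservedSummary`: response probabilities and RT
quantiles at (0.1, 0.3, 0.5, 0.7, 0.9), computed with the
linear-interpolation (type-7) quantile definition for data and
simulation alike.  Reactive: go response probability, per-SSD stop
accuracy, correct-RT quantiles, and error-RT quantiles collapsed across
SSDs.  Proactive: per-cue response probability and RT quantiles pooled
over high (>50%) and low (<50%) go-probability cues.

The cost is a weighted sum of squared errors over these observables,
with each quantile block multiplied by the observed response
probability of its pool.  Quantile weights are the median of the five
Maritz–Jarrett quantile standard errors divided by each quantile's SE
("interpolated median standard error" is read as the median of the five
SEs; the alternative reading — the SE of the 0.5 quantile — is one
keyword away in `quantile_weights`).  Response-probability weights are
the mean across-subject SD divided by each condition's SD when a
multi-subject cohort is available, and 1 otherwise.  A simulated pool
with no responses predicts quantiles pinned at the deadline, keeping
the cost finite and pushing the optimizer back toward responding.

AIC/BIC use the Gaussian-SSE convention AIC = n·ln(cost/n) + 2k,
BIC = n·ln(cost/n) + k·ln(n), with n the number of weighted data points
(16 per reactive context; 16 for the proactive task) and k the number
of distinct fitted parameters.  Only within-convention comparisons are
meaningful.

## Fitting protocol

Fitting is hierarchical, following the two-stage global/local scheme:

1. **Flat stage** — all parameters free against condition-averaged data
   (reactive: element-wise mean of per-context summaries; proactive:
   the mean cue probability and the average of the high/low quantile
   vectors).
2. **Conditional stage** — the modulated parameter(s) are re-seeded
   condition-by-condition by a short global run with everything else
   held at the flat values, then polished jointly by a Nelder–Mead
   simplex on the full cost.
3. The whole protocol runs `n_restarts >= 3` times and the restart with
   the lowest AIC is kept.

Every cost evaluation simulates `n_sim_per_eval` trials per condition
from a frozen noise bank (common random numbers), making the surface
deterministic and locally smooth enough for the simplex.

Two additions proved necessary, and are deliberate design choices of
this package.  First, the global stage opens with a seeded
differential-evolution search (Sobol-initialised, serial updating)
before basin hopping: the cost surface has long, shallow valleys in
which (a, tr, xb) trade off against `v_e` and `v_b`, plus genuinely
distinct local valleys, and basin hopping with short local polishes
alone stalls far from the deepest basin.  Second, the winning restart
is re-polished *jointly* — shared constants together with all
condition-wise free parameters — by a damped Gauss-Newton ladder on
the weighted residual vector.  Each rung raises the simulation
resolution (default 12k → 50k → 120k trials per evaluation); the
Jacobian comes from central differences under common random numbers,
in which the frozen simulation noise largely cancels, so the steps
follow the smooth expected residuals even though the cost itself is
too jagged for simplex or line-search methods at these scales.  The
finite-difference step shrinks with each rung (2% → 1% → 0.6% of each
parameter) to reduce the secant bias of the Gauss-Newton stationary
point, steps are capped at a shrinking fraction of each parameter's
magnitude, and the final rung returns the average of its last iterates
(the sloppiest direction random-walks around the expected minimum).
Basin-hopping hyperparameters the protocol leaves open: step size 10%
of each parameter's box (clipped), Metropolis temperature 1.0, and
"failure" = no improvement of the global minimum; the stage stops at
100 hops or 40 consecutive failures.  Search boxes: a ∈ (0.05, 1.5),
tr ∈ (0, 0.5), v_e, v_b ∈ (0, 5), xb ∈ (0, 5), sso ∈ (0, 0.3).

### Identifiability, honestly

With the urgency gain free, these models are *sloppy*: a one-parameter
family around the generating values (raise `a`, lower `tr`, bend `xb`,
compensate `v_e`, `v_b`) changes the 16 fitted observables only
slightly — expected-cost contrasts of order 1e-5 for several-percent
parameter displacements, below the Monte-Carlo resolution of any
affordable simulation budget.  Parameter-recovery error along this
direction is therefore limited by data and simulation noise, not by
optimizer effort.  In the shipped recovery studies the *condition
profile* of a modulated parameter (the six-cue drift ordering, the
onset-delay differences between cues) is recovered robustly, while
absolute parameter levels can carry residual biases of several percent
— occasionally beyond the 5% band for the braking drift, and as a
uniform shift of the onset delays absorbed by the compensating
constants.  The studies use large synthetic samples (a hundred
thousand go trials; tens of thousands of stop trials per SSD — far
beyond what a human cohort yields) precisely to push the observation-
noise part of this displacement below the simulation-side part.  With
single-subject-sized data, only the better-constrained combinations
(e.g. `a/v_e`, the stop-curve location, condition differences) should
be trusted, not individual parameter values.

## BOLD proxy

The predicted BOLD magnitude of a trial is the cumulative sum (AUC) of
the execution process over its active span — to the boundary crossing
on responded trials, to the deadline otherwise — computed on the
gain-scaled `theta_e`.  It jointly encodes time-to-threshold and
distance-to-threshold.  No hemodynamic convolution is applied.  Cue
bins mirror the imaging contrasts: executed ("go") responses pooled
over cues <= 60%, withheld ("no-go") outcomes pooled over cues >= 40%.
The three modulation accounts make opposite directional predictions
(drift: go > no-go and no-go AUC rising with cue probability; onset:
AUC rising for both outcomes; boundary: AUC falling), which the test
suite checks at n = 10,000 trials per cue; the default of 100 trials
per cue matches the scale of an imaging session.

## Synthetic cohorts

`CohortSpec`/`generate_cohort` produce multi-subject trial tables
around known ground-truth parameters, with Gaussian between-subject
offsets (shared across conditions, truncated to the search boxes by
redraw).  Default per-subject trial counts mirror the tasks: ~100 go
plus 20 stop trials per SSD (reactive) and 40 trials per cue
(proactive).  This is fixture machinery: real between-subject
variability is not Gaussian, there are no learning, sequence or reward
dynamics, and RTs carry no contaminant processes (anticipations,
lapses).  Passing recovery tests on these cohorts therefore
demonstrates the estimator's correctness under the model's own
assumptions, not robustness to real-data violations of them.

## Degenerate inputs and edge rules

Empty RT pools raise on quantile computation and are represented as
absent summary fields (skipped cost terms); zero Maritz–Jarrett SEs cap
the corresponding weight (default 10); a zero cost maps AIC/BIC to -inf
as a perfect-fit sentinel; `best_of_n` breaks AIC ties by lower cost,
then earlier run.  SSDs at or beyond the deadline reduce stop trials to
go trials exactly; an interactive-race suppression onset past the
deadline does the same.  No upper reflection is imposed on the DPM
braking accumulator (it may diffuse above its starting state before
descending), and a stop cue arriving before the execution onset cancels
the trial immediately (the brake starts at its own boundary).

## Problem sizes used by the shipped studies

The acceptance script and the heavier tests scale their simulation
sizes to single-CPU runs: reactive recovery uses 100,000 go / 20,000
stop trials per SSD with 5,000-trial cost evaluations and a refinement
ladder topping out at 120,000 trials per evaluation; proactive
recoveries use 100,000 trials per cue; model recovery uses 4,000 go /
800 stop per SSD over three replicates.  All sizes live in
`nestedrace.studies` and can be raised for tighter recovery at
proportional cost.

## Known limitations

* No closed-form likelihoods; everything is simulation-based.
* The exact hyperbolic form of the urgency gain, the braking noise of
  the interactive race, and the braking boundary of the independent
  race are under-determined by the behavioural predictions they
  generate; the choices above are documented and isolated in code.
* Trial-to-trial parameter variability (full Ratcliff-style) is out of
  scope.
* `tr` is quantized to the integration grid (1 ms by default).
* AIC/BIC absolute values are convention-dependent; only differences
  within this package are interpretable.
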