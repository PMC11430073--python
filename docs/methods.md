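# Methods

## The model

The package models the four phenotypes of chimeric-antigen-receptor (CAR) T
cells after infusion, together with the tumor population they target, as a
five-compartment ODE system (all states in cells, time in days, t = 0 the
infusion):

    dCD/dt = -(beta + eta) CD
    dCT/dt = eta CD + k(t) F(T) CT - (xi + epsilon + lambda) CT + theta T CM - alpha T CT
    dCM/dt = epsilon CT - theta T CM - mu CM
    dCE/dt = lambda CT - delta CE
    dT/dt  = r T (1 - b T) - gamma f(CF, T) T

`CD` are freshly infused ("distributed") cells that either die (`beta`) or
engraft as effectors (`eta`); effectors `CT` expand on antigen contact,
die (`xi`), convert to memory (`epsilon`) or exhaust (`lambda`); memory
cells `CM` die slowly (`mu`) and re-activate on tumor contact (`theta T`);
exhausted cells `CE` die at `delta`.  The tumor grows logistically
(rate `r`, carrying capacity `1/b`) and is killed by the functional pool
`CF = CD + CT` at rate `gamma` through the saturating contact function
`f(CF,T) = CF*T/(vartheta + a + CF*T)`.  Effector expansion is
`k(t) F(T)` with antigen saturation `F(T) = T/(A+T)` and a time-decaying
rate `k(t) = r_min + p1/(1 + (p2 t)^p3)`.

Only the total CAR-T count `C = CD + CT + CM + CE` is clinically
measurable; that sum is what every fit below compares to data.

Initial condition: `(CD, CT, CM, CE, T)(0) = (dose, 0, 0, 0, T0)` with
`T0 = 1e7` cells by default.  The bundled patient's infusion dose is not
recorded separately from the measurements; since `C(0) = CD(0) = dose`
under this initial condition, the day-0 measured count (9.230e7 cells) is
used as the dose.

Six constants are shared across patients (`alpha`, `r`, `b`, `vartheta`,
`theta`, `a`; literature values bundled as defaults); the 13 remaining
rates are patient-specific and are what the package estimates.

### Structural identifiability caveats (they matter everywhere below)

* Whenever `p2 * t_max << 1` — true for the bundled patient, where
  `p2 ~ 1e-10` and the window is 26 days — `(p2 t)^p3` underflows to zero,
  `k(t)` is constant, and `r_min` and `p1` enter the dynamics only through
  their sum.  The split between them, and `p2`/`p3` themselves, are pure
  ridge coordinates.
* `A` is flat once the tumor burden is far above it (`F(T) ~ 1` for any
  `A << T ~ 1e7`).
* The effector loss rates (`xi`, `lambda` with downstream `delta`) trade
  off against one another: cells leaving via `xi` vanish from `C`
  immediately, cells leaving via `lambda` linger in `CE` and decay at
  `delta`, and with 11 noisy observations of the sum these routes are only
  weakly distinguishable.

With 11 observations and 13 free rates the least-squares problem is
formally underdetermined; all downstream conclusions are about the
identifiable combinations, not about every rate individually.

## Numerics

The system is integrated with `scipy.integrate.solve_ivp` using LSODA
(automatic stiff/non-stiff switching; states span 1 to ~1e12 cells and
rates differ by orders of magnitude).  Defaults: `rtol = 1e-8`,
`atol = 1e-2` cells — the absolute tolerance is expressed in cells because
counts are huge and fractions of a cell carry no meaning.  Tests compare
trajectories with `rtol = 1e-6` plus an absolute floor of 0.1 cell,
because the solver's global error can slightly exceed its per-step `atol`
once a compartment has decayed to a handful of cells.

Saturating rate functions (`F`, `f`) are evaluated on states clipped to
zero so a small solver undershoot cannot flip their sign; the linear terms
use the raw state, which is what pulls an undershoot back.  Solver failure
is raised as `IntegrationError` and mapped to a log-posterior of `-inf`
inside inference (the proposal is rejected; chains never die).

`p3` is constrained strictly positive so `(p2 t)^p3` is defined at t = 0.

## Least-squares stage

`scipy.optimize.least_squares` (trust-region reflective) on the raw
residuals `observed - C_model`, bounds `[0, inf)` on all 13 rates,
tolerances 1e-10, and `x_scale` set to the initial-guess magnitudes (the
parameters span ~25 orders of magnitude; an unscaled trust region stalls).
The noise scale is not a least-squares parameter.

Two reproducible artifacts of this setup are worth knowing:

* A start exactly on a bound is nudged strictly feasible by the solver
  (`x -> x + 1e-10 * max(1, |x|)`), which maps the literature
  `p2 = 7.539e-25` to exactly `1e-10`; the coordinate is inert there
  (underflow gradient) and never moves again.
* From the literature initialization the optimizer descends into a basin
  with `xi -> 0` (all effector loss routed through exhaustion).  This
  basin has a lower sum of squares than the historically reported
  parameter set for this patient; restarting the optimizer from that
  reported set also descends into the `xi = 0` basin, with final cost
  agreeing within ~2% across starts.  The basin choice is a consequence of
  the non-identifiability above, and the fitted values of `xi`, `lambda`,
  `delta`, `mu` should be read as one point on a ridge.

## Bayesian stage

Fourteen parameters: the 13 rates plus the likelihood noise SD
`sigma_obs`.  The likelihood is normal on untransformed counts; `sigma` is
interpreted as a standard deviation (the inferred values, ~1e7-3e7 cells,
are on the data's count scale, which is only consistent with the SD
reading).  Priors are truncated normals on `[0, inf)`:

* centers: the least-squares estimates;
* spreads: fixed for the shape/ridge parameters (`A`: 5 cells, `p3`: 5,
  `p2`: 1e-11 /day, `p1`: 0.15 /day), and for every other rate half its
  center, floored at half the literature reference value and at an
  absolute 1e-3 /day.  The reference floor exists because "half the
  center" collapses to a spike whenever the optimizer drives a rate to the
  zero bound; a weakly informative prior should never be narrower than the
  rate's a-priori scale.
* `sigma_obs`: centered at the least-squares residual RMS with spread
  equal to that RMS.

### Samplers

Three gradient-free kernels, implemented from scratch over a generic
`logpost(theta)` callable, all bit-reproducible given a master seed
(per-chain streams spawned from one `SeedSequence`, so execution order is
irrelevant):

* **Random-walk Metropolis-Hastings** — independent Gaussian proposals per
  coordinate.
* **DEMetropolis (DE-MC)** — a population of N >= 4 chains; chain i
  proposes `x_i + gamma (x_a - x_b) + eps` with a, b distinct other
  chains.  The population geometry supplies the proposal scale and
  correlation; `gamma = 2.38/sqrt(2d)` (the DE-MC literature default) and
  a small per-coordinate jitter `eps` complete the kernel.
* **DEMetropolisZ (DE-MC-Z)** — difference vectors come from a thinned
  history Z of the chain's own past states ("parallel direction" updates),
  removing the need for more chains than dimensions; with probability 0.1
  the step uses `gamma = 1` (mode-hopping moves).  The history is seeded
  with the start point and grows with every `thin_history`-th accepted
  state; until it holds two entries the kernel falls back to a Gaussian
  random walk (documented warm-up behavior).

Proposal scales are tied to the prior spreads (`0.01 x` for Metropolis —
the priors overestimate the posterior scale by 1–2 orders of magnitude, and
this factor puts random-walk acceptance near the ~0.23 optimum, measured at
~19% on the patient posterior; jitter `1e-4 x` for the DE kernels), which
is what makes one tuning recipe work across 25 orders of magnitude of
parameter scale.

### Initialization and warm-up

Chains start at the prior centers plus 1% jitter.  Widely dispersed starts
(independent prior draws) were evaluated and leave chains stranded on
separate flat ridges of this weakly identified posterior — split-R-hat
stayed at 2.6-4.1 after 48,000 DEMetropolisZ draws — so the dispersed mode
is kept only as an option (`init="prior"`) for convergence auditing on
better-identified targets.  With center initialization the reported
posterior is explicitly the *local* posterior around the least-squares
solution, which is also what the reference clinical analysis reports.  The
first 20% of each chain is discarded as warm-up.

### Diagnostics

Pooled post-warm-up means, SDs, and 2.5/97.5 percentiles (linear
interpolation between order statistics); the forest-plot spread statistic
`dispersion = (q97.5 - q2.5)/mean` (undefined at zero mean — an error, not
a NaN); split-chain rank-normalized R-hat and bulk ESS via ArviZ, with
1.01 as the "converged" label threshold; pairwise Pearson correlations
with constant parameters reported as 0 with a warning.

## Synthetic patients

`synthetic_data` simulates the assumed data-generating process exactly:
the model's `C(t)` on a sampling schedule plus additive
`Normal(0, sigma)` noise on raw counts.  Defaults mirror the bundled
clinical series: the same irregular 11-day schedule over days 0-26,
`sigma = 3e7` cells (the scale of the inferred noise), dose = day-0 count,
`T0 = 1e7`.  Negative draws are kept by default (model-consistent; a
`clip` option exists for realism at the cost of a slightly misspecified
noise model).  Cohorts jitter the rates by truncated-normal perturbations.
What the generator does *not* emulate: measurement-dependent noise
(real cytometry error grows with the count), detection limits, missed
visits, and any between-visit correlation — so passing recovery tests
validate the inference machinery under its own assumptions, not clinical
robustness.

The recovery study (`analysis/05_parameter_recovery.py`, 20 replicates at
the published posterior point estimates) measures how often each
parameter's posterior mean falls within 3 posterior SDs of the generating
value.  Measured coverage is far below nominal — 30% (`beta`), 65%
(`mu`), 50% (`delta`), 75% (`gamma`) — because the posterior routinely
concentrates tightly on a different ridge point than the generating one
(the `xi`/`lambda`/`delta` trade-off and the `beta`/`gamma`/`eta`
coupling): the bias, not the width, kills coverage.  That is a property
of the design — 11 points, noise SD 3e7 — not of the samplers, which pass
their closed-form analytic-target checks; it quantifies how cautiously
single-rate estimates from data of this design should be read.

## Problem sizes used by the shipped runs

Chosen so the full analysis replays on a laptop-class single core:
the patient posterior uses 8 chains x 6250 DEMetropolisZ draws (40,000
post-warm-up samples, ~4 ms per model evaluation); the three-sampler
comparison uses 8 x 4000 per kernel; the recovery study uses 2 x 3000
draws and a 150-evaluation least-squares cap per replicate.  Longer runs
sharpen the ESS but do not move the pooled means by more than fractions of
a posterior SD.

## Known limitations

* The analysis is single-patient; no hierarchical pooling across patients.
* The posterior is local by construction (see initialization); a
  multimodal global treatment would need tempering or SMC, which the
  package deliberately leaves to external tools via the `ChainSet`
  interface.
* The `xi = 0` basin the optimizer selects fits the bundled series better
  than the historically reported parameter set but implies no direct
  effector death, which is biologically doubtful — a reminder that ridge
  coordinates should not be over-interpreted clinically.
* Wall-clock behavior depends on LSODA step-size control; pathological
  parameter draws (huge rates) can slow a single likelihood evaluation,
  which matters for sampler throughput though not correctness.
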