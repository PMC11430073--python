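# cartmc — CAR-T kinetics by least squares and from-scratch MCMC

`cartmc` estimates the kinetic parameters of a five-compartment ordinary-
differential-equation model of CAR-T cell therapy from a patient's total
CAR-T counts.  It is aimed at people studying immunotherapy dynamics who
want a transparent, fully reproducible pipeline: the ODE model, a bounded
nonlinear least-squares baseline, and three Markov chain Monte Carlo
kernels — random-walk Metropolis–Hastings, DEMetropolis (DE-MC) and
DEMetropolisZ (DE-MC-Z) — implemented from scratch rather than wrapped
from a probabilistic-programming framework.

## The model in brief

Five compartments (cells): distributed `CD`, effector `CT`, memory `CM`
and exhausted `CE` CAR-T cells, plus tumor `T`:

    CD' = -(β+η)CD
    CT' = ηCD + k(t)F(T)CT - (ξ+ε+λ)CT + θT·CM - αT·CT
    CM' = εCT - θT·CM - μCM
    CE' = λCT - δCE
    T'  = rT(1-bT) - γ f(CF,T) T

with `k(t) = r_min + p1/(1+(p2 t)^p3)`, `F(T) = T/(A+T)`,
`f(CF,T) = CF·T/(ϑ+a+CF·T)`, `CF = CD+CT`.  Only `C = CD+CT+CM+CE` is
measurable.  Thirteen patient-specific rates (β, η, r_min, p1, p2, p3, A,
ξ, ε, λ, μ, δ, γ) are estimated; six constants (α, r, b, ϑ, θ, a) are
fixed from the literature.  Inference adds the observation-noise SD σ for
a normal likelihood on raw counts, with truncated-normal priors on
[0, ∞) centered at the least-squares estimates.

An 11-point clinical series for one lymphoma patient ("patient 28",
days 0–26, counts 1.1e7–1.1e9 cells) ships as a packaged fixture, and a
synthetic-patient generator reproduces the same design with known ground
truth so every stage is testable offline.

## Worked example

```python
from cartmc import (
    FixedParams, patient28_fixture, patient28_initial_kinetics,
    patient28_dose, DEFAULT_T0, fit_least_squares, default_priors,
    PosteriorProblem, posterior_summary,
)
from cartmc.cli import run_sampler

obs = patient28_fixture()
ls = fit_least_squares(obs, patient28_initial_kinetics(), FixedParams(),
                       patient28_dose(), DEFAULT_T0)
print(f"residual RMS {(ls.cost / len(obs))**0.5:.3e} cells")

problem = PosteriorProblem(obs, FixedParams(), patient28_dose(),
                           DEFAULT_T0, default_priors(ls))
chains = run_sampler("demetropolisz", problem, n_chains=8, n_draws=6250, seed=1)
s = posterior_summary(chains, discard=0.2)
print(s.table.loc[["beta", "gamma", "sigma_obs"], ["mean", "sd"]])
```

prints (seed 1):

```
residual RMS 1.623e+07 cells
                   mean            sd
beta       1.360750e+00  3.157826e-01
gamma      2.152147e+00  2.121452e-02
sigma_obs  1.912317e+07  3.865206e+06
```

Read: the fitted model tracks the measured counts to ~1.6e7 cells RMS
(peak count is 1.07e9, so ~1.5% of peak); the distribution-phase death
rate β ≈ 1.36/day means infused cells disappear from the distributed pool
with a half-life of ~12 hours, and the cytotoxic rate γ ≈ 2.15/day sets
near-peak tumor-killing speed.  The posterior noise SD ~1.9e7 cells is the
data's own scatter around the model curve.  With 11 observations and 13
rates the problem is underdetermined, so several rates are ridge
coordinates — see `docs/methods.md` before interpreting any single rate
clinically.

## Repository layout

* `src/cartmc/` — the library: `ode_model` (system + LSODA solver),
  `data_io` (CSV dialect + bundled patient), `synthetic_data` (generator),
  `least_squares_fit`, `bayes_model` (likelihood/priors/posterior),
  `samplers` (the three MCMC kernels), `diagnostics`, `cli`
  (`cartmc run|simulate|generate|fit-ls|fit-mcmc|summarize`).
* `analysis/01...05_*.py` — the narrative drivers: forward simulation,
  least squares, the three-sampler comparison, posterior diagnostics,
  and the synthetic recovery study.  Each writes its tables under
  `results/` and prints what it found.
* `tests/` — unit/property tests per module plus end-to-end checks.

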