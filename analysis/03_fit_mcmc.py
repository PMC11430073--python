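#!/usr/bin/env python
"""Bayesian estimation with the three from-scratch MCMC kernels.

Builds the 14-parameter posterior (13 kinetic rates + noise SD; truncated-
normal priors centered at the least-squares estimates) and samples it with
random-walk Metropolis-Hastings, DEMetropolis and DEMetropolisZ.  Writes
per-sampler chain CSVs, run manifests and a combined posterior-summary
table shaped parameter x (mean, sd) per sampler.

Output: results/03_chains_<sampler>.csv, results/03_manifest_<sampler>.json,
        results/03_posterior_summary.csv

What it finds: the three kernels agree on the location of the
data-informed parameters (beta, gamma, p1, sigma) to within about one
posterior SD.  DEMetropolis mixes best per draw here (worst R-hat ~1.1,
median ESS ~300 at 8x4000); DEMetropolisZ is close behind; plain
random-walk Metropolis is the weakest in this correlated 14-d space even
after its proposal scale is tuned to ~20% acceptance.  The posterior
concentrates where the least-squares stage put the prior centers: the
data sharpen beta, gamma, mu and the noise SD but barely move the ridge
coordinates (A, p2, the r_min/p1 split).
"""

import time
from pathlib import Path

import pandas as pd

from cartmc.bayes_model import PARAM_NAMES, PosteriorProblem, default_priors
from cartmc.cli import run_sampler
from cartmc.data_io import DEFAULT_T0, patient28_dose, patient28_fixture, patient28_initial_kinetics
from cartmc.diagnostics import posterior_summary
from cartmc.least_squares_fit import fit_least_squares
from cartmc.ode_model import FixedParams

OUT = Path(__file__).resolve().parent.parent / "results"

SEED = 1
N_CHAINS = 8
N_DRAWS = 4000        # per chain; first 20% discarded
SAMPLERS = ("metropolis", "demetropolis", "demetropolisz")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    obs = patient28_fixture()
    fixed = FixedParams()
    dose = patient28_dose()

    ls = fit_least_squares(obs, patient28_initial_kinetics(), fixed, dose, DEFAULT_T0)
    problem = PosteriorProblem(obs, fixed, dose, DEFAULT_T0, default_priors(ls))

    blocks = []
    for name in SAMPLERS:
        t0 = time.perf_counter()
        chains = run_sampler(name, problem, n_chains=N_CHAINS, n_draws=N_DRAWS, seed=SEED)
        elapsed = time.perf_counter() - t0
        chains.save_csv(OUT / f"03_chains_{name}.csv")
        chains.save_manifest(OUT / f"03_manifest_{name}.json")
        s = posterior_summary(chains, discard=0.2)
        block = s.table[["mean", "sd", "rhat", "ess_bulk"]].copy()
        block.columns = pd.MultiIndex.from_product([[name], block.columns])
        blocks.append(block)
        print(f"{name:14s} acc {s.acceptance_rate:.2f}  worst rhat "
              f"{s.table['rhat'].max():.2f}  median ESS {s.table['ess_bulk'].median():.0f}  {elapsed:.0f}s")

    combined = pd.concat(blocks, axis=1)
    combined.to_csv(OUT / "03_posterior_summary.csv")
    means = combined.xs("mean", axis=1, level=1)
    print("\nposterior means by sampler:")
    print(means.to_string(float_format=lambda v: f"{v:.4g}"))
    print(f"wrote {OUT / '03_posterior_summary.csv'}")


if __name__ == "__main__":
    main()
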