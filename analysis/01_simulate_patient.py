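#!/usr/bin/env python
"""Forward-simulate the compartment model at the literature kinetics.

Integrates the five-compartment CAR-T/tumor system from infusion
(dose = the patient's day-0 count, tumor burden 1e7 cells) over the 26-day
observation window at the published literature rates, and writes the dense
trajectory plus the model total-CAR-T curve against the clinical series.

Output: results/01_trajectory.csv, results/01_fit_at_init.csv

What it shows: the literature parameterization reproduces the qualitative
expansion peak near day 6 but overshoots the measured peak (1.35e9 modelled
at day 6.7 vs 1.07e9 observed at day 6; residual RMS 1.1e8 cells) -- the
motivation for re-fitting the kinetics to this patient.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cartmc.data_io import DEFAULT_T0, patient28_dose, patient28_fixture, patient28_initial_kinetics
from cartmc.ode_model import FixedParams, simulate

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    obs = patient28_fixture()
    kin = patient28_initial_kinetics()
    fixed = FixedParams()
    dose = patient28_dose()

    grid = np.linspace(0.0, float(obs.days[-1]), 261)
    traj = simulate(kin, fixed, dose, DEFAULT_T0, grid)
    traj.to_frame().to_csv(OUT / "01_trajectory.csv", index=False)

    at_obs = simulate(kin, fixed, dose, DEFAULT_T0, obs.days)
    comp = pd.DataFrame({"day": obs.days, "observed": obs.counts, "model": at_obs.C})
    comp["residual"] = comp["observed"] - comp["model"]
    comp.to_csv(OUT / "01_fit_at_init.csv", index=False)

    peak_day = grid[np.argmax(traj.C)]
    print(f"modelled peak {traj.C.max():.3e} cells at day {peak_day:.1f} "
          f"(observed peak {obs.counts.max():.3e} at day {obs.days[np.argmax(obs.counts)]:.0f})")
    print(f"residual RMS at literature kinetics: {np.sqrt(np.mean(comp['residual']**2)):.3e} cells")
    print(f"wrote {OUT / '01_trajectory.csv'} and {OUT / '01_fit_at_init.csv'}")


if __name__ == "__main__":
    main()
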