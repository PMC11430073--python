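#!/usr/bin/env python
"""Parameter-recovery study on synthetic patients.

Generates 20 synthetic patients at the published posterior point estimates
(noise SD 3e7 cells on the clinical 11-day schedule), runs the full
pipeline on each (least squares -> priors -> DEMetropolisZ), and reports
how often each parameter's posterior mean lands within 3 posterior SDs of
the generating value.

Output: results/05_recovery.csv, results/05_recovery_summary.json

What it finds: recovery is far below nominal -- 3-SD coverage of 30%
(beta), 65% (mu), 50% (delta), 75% (gamma) over 20 replicates.  With 11
noisy observations the likelihood has flat ridges (effector death xi
trades against exhaustion lambda and exhausted-cell death delta; beta
couples to gamma and eta), so the posterior routinely concentrates,
tightly and confidently, on a different ridge point than the generating
one: the bias, not the width, kills coverage.  This is a property of the
design (sample size and noise), not of the samplers -- the same kernels
pass their closed-form analytic-target checks -- and it means single
rates from fits of this design should not be read as patient truth.
"""

import json
import time
from pathlib import Path

import pandas as pd

from cartmc.cli import recovery_study
from cartmc.data_io import patient28_reference_posterior_kinetics

OUT = Path(__file__).resolve().parent.parent / "results"

SEED = 20240
N_REPLICATES = 20


def main() -> None:
    OUT.mkdir(exist_ok=True)
    t0 = time.perf_counter()
    report = recovery_study(patient28_reference_posterior_kinetics(), N_REPLICATES, SEED)
    elapsed = time.perf_counter() - t0

    rows = []
    for rec in report["replicates"]:
        for p in ("beta", "mu", "delta", "gamma"):
            rows.append(
                {
                    "replicate": rec["replicate"],
                    "parameter": p,
                    "truth": rec[p]["truth"],
                    "posterior_mean": rec[p]["posterior_mean"],
                    "posterior_sd": rec[p]["posterior_sd"],
                    "abs_z": rec[p]["abs_z"],
                    "covered": rec[p]["covered"],
                }
            )
    pd.DataFrame(rows).to_csv(OUT / "05_recovery.csv", index=False)
    (OUT / "05_recovery_summary.json").write_text(
        json.dumps({"coverage": report["coverage"], "settings": report["settings"]}, indent=2)
    )

    print(f"{N_REPLICATES} replicates in {elapsed / 60:.1f} min")
    print("3-SD coverage of the generating value:")
    for p, c in report["coverage"].items():
        print(f"  {p:8s} {c:.0%}")
    print(f"wrote {OUT / '05_recovery.csv'}")


if __name__ == "__main__":
    main()
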