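"""Synthetic patients with the statistical structure the inference assumes.

A synthetic dataset is the model's total-CAR-T curve C(t) evaluated on a
sampling schedule, plus additive Gaussian noise on the untransformed counts
-- exactly the likelihood the Bayesian stage assumes.  Defaults emulate the
bundled clinical series: an 11-point irregular schedule over days 0-26,
counts spanning ~1e7-1e9 cells, noise SD 3e7 cells (the scale of the
posterior noise estimates), initial tumor burden 1e7 cells and a dose equal
to the day-0 count.

Because the noise is additive normal, a model-consistent draw can be
negative where C(t) is small; by default such draws are kept (so the data
match the likelihood exactly).  Pass ``negative_handling="clip"`` for
realism at the cost of slightly misspecified noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from cartmc.data_io import DEFAULT_T0, ObservationSeries, patient28_fixture, patient28_initial_kinetics, patient28_dose
from cartmc.ode_model import FixedParams, IntegrationError, KineticParams, simulate

__all__ = ["SyntheticSpec", "generate_observations", "generate_schedule", "generate_cohort", "write_ground_truth"]

#: default noise SD, cells; the scale of the inferred measurement noise
DEFAULT_SIGMA = 3.0e7

#: the 11-day schedule of the bundled clinical series
DEFAULT_SCHEDULE = (0.0, 2.0, 3.0, 4.0, 6.0, 11.0, 12.0, 15.0, 19.0, 20.0, 26.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic patient (ground truth + noise + design)."""

    kinetic: KineticParams
    fixed: FixedParams = field(default_factory=FixedParams)
    dose: float = patient28_dose()
    T0: float = DEFAULT_T0
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    sigma: float = DEFAULT_SIGMA
    seed: int = 0
    negative_handling: str = "keep"  # "keep" | "clip"
    patient_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.schedule[0] != 0:
            raise ValueError("schedule must start at day 0 (infusion)")
        if self.negative_handling not in ("keep", "clip"):
            raise ValueError("negative_handling must be 'keep' or 'clip'")


def generate_observations(spec: SyntheticSpec) -> ObservationSeries:
    """Simulate one synthetic patient.

    counts = C_model(day) + Normal(0, sigma), deterministic given
    ``spec.seed``.  The returned series carries the ground truth in its
    ``metadata`` so recovery studies can round-trip it.
    """
    try:
        traj = simulate(spec.kinetic, spec.fixed, spec.dose, spec.T0, np.asarray(spec.schedule, float))
    except IntegrationError as exc:
        raise IntegrationError(
            f"model integration failed for synthetic spec (kinetics={spec.kinetic.as_dict()}): {exc}"
        ) from exc
    rng = np.random.default_rng(spec.seed)
    counts = traj.C + rng.normal(0.0, spec.sigma, size=len(spec.schedule)) if spec.sigma > 0 else traj.C.copy()
    if spec.negative_handling == "clip":
        counts = np.clip(counts, 0.0, None)
    meta = {
        "ground_truth": spec.kinetic.as_dict(),
        "fixed": spec.fixed.as_dict(),
        "dose": spec.dose,
        "T0": spec.T0,
        "sigma": spec.sigma,
        "seed": spec.seed,
        "negative_handling": spec.negative_handling,
    }
    return ObservationSeries(
        days=np.asarray(spec.schedule, float),
        counts=counts,
        patient_id=spec.patient_id,
        allow_negative=True,
        metadata=meta,
    )


def generate_schedule(n_points: int, horizon_days: int, seed: int) -> np.ndarray:
    """Random irregular sampling design: unique integer days, 0 first, end <= horizon."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if n_points > horizon_days + 1:
        raise ValueError(f"cannot place {n_points} unique days in 0..{horizon_days}")
    rng = np.random.default_rng(seed)
    later = rng.choice(np.arange(1, horizon_days + 1), size=n_points - 1, replace=False)
    return np.concatenate([[0.0], np.sort(later).astype(float)])


def generate_cohort(
    n_patients: int,
    param_dispersion: float,
    base: SyntheticSpec,
    seed: int,
) -> list[ObservationSeries]:
    """A cohort of synthetic patients with jittered kinetics.

    Each patient's rates are drawn from normals centered at the base
    kinetics with SD ``param_dispersion`` times the base value, truncated at
    zero by resampling -- the same positivity constraint the priors encode.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if param_dispersion < 0:
        raise ValueError("param_dispersion must be >= 0")
    ss = np.random.SeedSequence(seed)
    out: list[ObservationSeries] = []
    for i, child in enumerate(ss.spawn(n_patients)):
        rng = np.random.default_rng(child)
        base_vals = base.kinetic.to_array()
        vals = base_vals.copy()
        if param_dispersion > 0:
            for j, v in enumerate(base_vals):
                draw = rng.normal(v, param_dispersion * v)
                while draw < 0 or (j == 5 and draw <= 0):  # p3 must stay positive
                    draw = rng.normal(v, param_dispersion * v)
                vals[j] = draw
        spec_i = replace(
            base,
            kinetic=KineticParams.from_array(vals),
            seed=int(rng.integers(2**31)),
            patient_id=f"{base.patient_id}_{i:03d}",
        )
        out.append(generate_observations(spec_i))
    return out


def write_ground_truth(series: ObservationSeries, path) -> Path:
    """Sidecar JSON with the generating parameters and seed of a synthetic series."""
    path = Path(path)
    path.write_text(json.dumps(series.metadata, indent=2, sort_keys=True))
    return path


def patient28_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A spec mirroring the bundled patient's design with literature kinetics."""
    return SyntheticSpec(kinetic=patient28_initial_kinetics(), seed=seed, **overrides)
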