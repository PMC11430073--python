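"""Frequentist baseline: bounded nonlinear least squares of the 13 kinetics.

The objective is the plain sum of squared residuals between observed and
modelled total CAR-T counts on the untransformed cell scale, with lower
bounds of zero on every rate (the positivity condition that guarantees the
ODE solution exists).  The measurement-noise scale is not a least-squares
parameter; it enters only in the Bayesian stage.

The parameters span ~25 orders of magnitude (p2 ~ 1e-25 against rates of
order 1), so the optimizer works on parameters scaled by their initial
guess; otherwise the trust region is hopelessly ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares as _scipy_least_squares

from cartmc.data_io import ObservationSeries
from cartmc.ode_model import (
    FixedParams,
    IntegrationError,
    KineticParams,
    KINETIC_NAMES,
    simulate,
)

__all__ = ["LSResult", "residuals", "fit_least_squares"]


@dataclass(frozen=True)
class LSResult:
    """Outcome of a bounded least-squares fit."""

    estimate: KineticParams
    residual_vector: np.ndarray  # cells, one per observation
    cost: float                  # sum of squared residuals, cell^2
    converged: bool
    n_evals: int
    message: str = ""

    def comparison_frame(self, init: KineticParams):
        """Side-by-side table: parameter, initial value, estimate, |difference|."""
        import pandas as pd

        i = init.to_array()
        e = self.estimate.to_array()
        return pd.DataFrame(
            {
                "parameter": list(KINETIC_NAMES),
                "initial": i,
                "estimate": e,
                "abs_difference": np.abs(e - i),
            }
        )


def residuals(
    kinetic: KineticParams,
    obs: ObservationSeries,
    fixed: FixedParams,
    dose: float,
    T0: float,
) -> np.ndarray:
    """Per-observation residuals r_i = observed_i - C_model(day_i), in cells.

    Raises :class:`IntegrationError` when the model cannot be integrated at
    these parameters; optimizers treat that point as infeasible.
    """
    eval_times = obs.days
    if eval_times[0] != 0.0:
        eval_times = np.concatenate([[0.0], eval_times])
        traj = simulate(kinetic, fixed, dose, T0, eval_times)
        model_c = traj.C[1:]
    else:
        traj = simulate(kinetic, fixed, dose, T0, eval_times)
        model_c = traj.C
    return obs.counts - model_c


def fit_least_squares(
    obs: ObservationSeries,
    init: KineticParams,
    fixed: FixedParams,
    dose: float,
    T0: float,
    *,
    xtol: float = 1e-10,
    ftol: float = 1e-10,
    gtol: float = 1e-10,
    max_nfev: int | None = None,
) -> LSResult:
    """Trust-region least squares with lower bounds 0 on all 13 rates.

    Internally each parameter is scaled by the magnitude of its initial
    guess (``x_scale``), so a unit trust-region step means "change this
    parameter by about its own size".  Deterministic given inputs and
    options.  Non-convergence is reported, not raised: the best point found
    is returned with ``converged=False``.
    """
    x0 = init.to_array()
    if np.any(x0 < 0):
        raise ValueError("initial guess violates the nonnegativity bounds")
    scale = np.where(x0 > 0, x0, 1.0)

    def fun(x: np.ndarray) -> np.ndarray:
        try:
            return residuals(KineticParams.from_array(x), obs, fixed, dose, T0)
        except (IntegrationError, ValueError):
            # infeasible point: a large finite residual keeps trf inside the
            # feasible region without poisoning the Jacobian with inf
            return np.full(len(obs), 1e12)

    res = _scipy_least_squares(
        fun,
        x0,
        bounds=(np.zeros_like(x0), np.full_like(x0, np.inf)),
        method="trf",
        x_scale=scale,
        xtol=xtol,
        ftol=ftol,
        gtol=gtol,
        max_nfev=max_nfev,
    )
    return LSResult(
        estimate=KineticParams.from_array(res.x),
        residual_vector=res.fun,
        cost=float(np.sum(res.fun**2)),
        converged=bool(res.status > 0),
        n_evals=int(res.nfev),
        message=str(res.message),
    )
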