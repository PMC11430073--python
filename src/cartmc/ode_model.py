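"""Five-compartment ODE model of CAR-T cell / tumor dynamics.

State vector (all in cells):

* ``CD`` -- distributed CAR-T cells (freshly infused, not yet engrafted)
* ``CT`` -- effector CAR-T cells (engrafted, proliferating, tumor-killing)
* ``CM`` -- memory CAR-T cells (long-lived, reactivatable)
* ``CE`` -- exhausted CAR-T cells (non-functional)
* ``T``  -- tumor cells

Dynamics::

    dCD/dt = -(beta + eta) CD
    dCT/dt = eta CD + k(t) F(T) CT - (xi + epsilon + lambda) CT
             + theta T CM - alpha T CT
    dCM/dt = epsilon CT - theta T CM - mu CM
    dCE/dt = lambda CT - delta CE
    dT/dt  = r T (1 - b T) - gamma f(CF, T) T

with the saturating rate functions

    k(t)     = r_min + p1 / (1 + (p2 t)^p3)      (antigen-driven expansion)
    F(T)     = T / (A + T)                        (antigen saturation)
    f(CF, T) = CF T / (vartheta + a + CF T)       (cytotoxic saturation)

and ``CF = CD + CT`` the functional (killing-capable) CAR-T pool.  Only the
total CAR-T count ``C = CD + CT + CM + CE`` is clinically measurable.

Time is measured in days with t = 0 the infusion; the infusion dose enters
as ``CD(0)`` and all other CAR-T compartments start empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FixedParams",
    "KineticParams",
    "Trajectory",
    "IntegrationError",
    "expansion_rate_k",
    "antigen_saturation_F",
    "cytotoxic_saturation_f",
    "model_rhs",
    "simulate",
    "total_car_t",
    "distributed_closed_form",
]

#: column order used for state arrays and CSV export
STATE_NAMES = ("CD", "CT", "CM", "CE", "T")

#: canonical ordering of the 13 patient-specific kinetic parameters
KINETIC_NAMES = (
    "beta", "eta", "r_min", "p1", "p2", "p3", "A",
    "xi", "epsilon", "lambda_", "mu", "delta", "gamma",
)

FIXED_NAMES = ("alpha", "r", "b", "vartheta", "theta", "a")


class IntegrationError(RuntimeError):
    """The ODE solver failed (step-size collapse or non-finite state)."""


@dataclass(frozen=True)
class FixedParams:
    """Non-patient-dependent constants, shared across patients.

    Defaults are literature values for B-cell malignancies treated with
    anti-CD19 CAR-T cells.

    alpha : (cell*day)^-1  inhibition of effector cells by tumor contact
    r : day^-1             maximum tumor growth rate
    b : cell^-1            inverse tumor carrying capacity
    vartheta : 1           half-saturation constant of the cytotoxic effect
    theta : (cell*day)^-1  memory->effector re-conversion coefficient
    a : cell               half-saturation constant of f(CF, T)
    """

    alpha: float = 5.500e-7
    r: float = 1.760e-1
    b: float = 5.000e-13
    vartheta: float = 3.050e-1
    theta: float = 6.000e-6
    a: float = 1.000e3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"FixedParams.{f.name} must be strictly positive, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class KineticParams:
    """The 13 patient-specific kinetic rates being estimated.

    All rates are nonnegative (positivity guarantees existence of the ODE
    solution); ``p3`` must additionally be strictly positive so that
    ``(p2*t)**p3`` is defined at t = 0.

    beta : day^-1     distribution-phase death rate
    eta : day^-1      engraftment rate
    r_min : day^-1    minimum effector expansion rate
    p1 : day^-1       initial expansion rate
    p2 : day^-1       expansion-duration rate
    p3 : 1            expansion decay coefficient
    A : cell          half-saturation constant of F(T)
    xi : day^-1       effector death rate
    epsilon : day^-1  effector->memory conversion rate
    lambda_ : day^-1  effector exhaustion rate
    mu : day^-1       memory death rate
    delta : day^-1    exhausted-cell death rate
    gamma : day^-1    cytotoxic rate
    """

    beta: float
    eta: float
    r_min: float
    p1: float
    p2: float
    p3: float
    A: float
    xi: float
    epsilon: float
    lambda_: float
    mu: float
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"KineticParams.{f.name} must be nonnegative and finite, got {v!r}")
        if self.p3 <= 0:
            raise ValueError(f"p3 must be strictly positive ((p2*t)**p3 is undefined at t=0), got {self.p3!r}")

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "KineticParams":
        """Build from values in canonical :data:`KINETIC_NAMES` order."""
        if len(values) != len(KINETIC_NAMES):
            raise ValueError(f"expected {len(KINETIC_NAMES)} values, got {len(values)}")
        return cls(**dict(zip(KINETIC_NAMES, (float(v) for v in values))))

    def to_array(self) -> np.ndarray:
        """Values in canonical :data:`KINETIC_NAMES` order."""
        return np.array([getattr(self, n) for n in KINETIC_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class Trajectory:
    """Solved states on a time grid; ``times[0]`` is the infusion day 0."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 5), columns in STATE_NAMES order

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if s.shape != (t.size, 5):
            raise ValueError(f"states shape {s.shape} inconsistent with {t.size} times")
        if t.size and t[0] != 0.0:
            raise ValueError("trajectory must start at the infusion day t=0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    @property
    def CD(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def CT(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def CM(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def CE(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def CF(self) -> np.ndarray:
        """Functional CAR-T cells, CD + CT."""
        return self.states[:, 0] + self.states[:, 1]

    @property
    def C(self) -> np.ndarray:
        """Total measurable CAR-T cells, CD + CT + CM + CE."""
        return self.states[:, :4].sum(axis=1)

    def to_frame(self):
        """Export as a pandas DataFrame with columns day,CD,CT,CM,CE,T,C."""
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "day", self.times)
        df["C"] = self.C
        return df


def expansion_rate_k(t: float, params: KineticParams) -> float:
    """Antigen-driven effector expansion rate k(t) = r_min + p1/(1+(p2 t)^p3).

    Non-increasing in t, decaying from ``r_min + p1`` at infusion to the
    floor ``r_min``; ``p2`` sets the duration of the maximum-expansion
    window and ``p3`` the sharpness of its end.
    """
    x = params.p2 * t
    # x**p3 overflows for large x*; the rate then underflows to the floor.
    if x <= 0.0:
        pw = 0.0
    else:
        try:
            pw = x ** params.p3
        except OverflowError:
            pw = math.inf
    return params.r_min + params.p1 / (1.0 + pw)


def antigen_saturation_F(T: float, A: float) -> float:
    """Antigen saturation F(T) = T/(A+T), in [0, 1)."""
    if A <= 0:
        raise ValueError("half-saturation constant A must be > 0")
    T = max(T, 0.0)
    return T / (A + T)


def cytotoxic_saturation_f(CF: float, T: float, vartheta: float, a: float) -> float:
    """Cytotoxic saturation f(CF,T) = CF*T/(vartheta + a + CF*T), in [0, 1)."""
    if vartheta <= 0 or a <= 0:
        raise ValueError("vartheta and a must be > 0")
    prod = max(CF, 0.0) * max(T, 0.0)
    return prod / (vartheta + a + prod)


def model_rhs(
    t: float,
    state: Sequence[float],
    fixed: FixedParams,
    kinetic: KineticParams,
) -> np.ndarray:
    """Time derivatives of (CD, CT, CM, CE, T).

    Saturating rate functions are evaluated on states clipped to zero so a
    small solver undershoot cannot flip their sign; the linear terms use the
    raw state, which is what pulls an undershoot back toward zero.
    """
    CD, CT, CM, CE, T = (float(s) for s in state)
    if not all(map(math.isfinite, (CD, CT, CM, CE, T))):
        raise IntegrationError(f"non-finite state at t={t}: {state!r}")

    Tc = max(T, 0.0)
    F = Tc / (kinetic.A + Tc) if kinetic.A + Tc > 0 else 0.0
    k = expansion_rate_k(t, kinetic)
    CF = max(CD, 0.0) + max(CT, 0.0)
    prod = CF * Tc
    f_cyt = prod / (fixed.vartheta + fixed.a + prod)

    dCD = -(kinetic.beta + kinetic.eta) * CD
    dCT = (
        kinetic.eta * CD
        + k * F * CT
        - (kinetic.xi + kinetic.epsilon + kinetic.lambda_) * CT
        + fixed.theta * Tc * CM
        - fixed.alpha * Tc * CT
    )
    dCM = kinetic.epsilon * CT - fixed.theta * Tc * CM - kinetic.mu * CM
    dCE = kinetic.lambda_ * CT - kinetic.delta * CE
    dT = fixed.r * T * (1.0 - fixed.b * T) - kinetic.gamma * f_cyt * T
    return np.array([dCD, dCT, dCM, dCE, dT])


#: default solver tolerances: states are cell counts up to ~1e12, so the
#: absolute tolerance is expressed in cells
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-2


def simulate(
    kinetic: KineticParams,
    fixed: FixedParams,
    dose: float,
    T0: float,
    eval_times: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model forward from infusion.

    Initial condition: (CD, CT, CM, CE, T)(0) = (dose, 0, 0, 0, T0) -- at
    infusion every CAR-T cell is still in the distributed compartment, so
    the measurable total C(0) equals the dose.

    Parameters
    ----------
    dose : cell
        CAR-T cells infused at day 0 (> 0).
    T0 : cell
        Initial tumor burden (>= 0).
    eval_times : days
        Sorted output grid starting at 0.
    method
        Any :func:`scipy.integrate.solve_ivp` method; the default LSODA
        switches automatically between stiff and non-stiff steppers, which
        matters because the rates span many orders of magnitude.

    Raises
    ------
    IntegrationError
        If the solver fails or produces non-finite values.  Callers doing
        inference map this to a log-posterior of -inf (proposal rejected).
    """
    times = np.asarray(eval_times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("eval_times must be a non-empty 1-D sequence")
    if times[0] != 0.0:
        raise ValueError("eval_times must start at 0 (infusion day)")
    if np.any(np.diff(times) <= 0):
        raise ValueError("eval_times must be strictly increasing")
    if not dose > 0:
        raise ValueError(f"dose must be > 0, got {dose!r}")
    if T0 < 0:
        raise ValueError(f"T0 must be >= 0, got {T0!r}")

    y0 = np.array([dose, 0.0, 0.0, 0.0, T0])
    if times.size == 1:  # nothing to integrate
        return Trajectory(times=times, states=y0[None, :])

    try:
        sol = solve_ivp(
            model_rhs,
            (0.0, float(times[-1])),
            y0,
            t_eval=times,
            method=method,
            rtol=rtol,
            atol=atol,
            args=(fixed, kinetic),
        )
    except IntegrationError:
        raise
    except (OverflowError, FloatingPointError) as exc:  # pragma: no cover
        raise IntegrationError(str(exc)) from exc
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=times, states=sol.y.T)


def total_car_t(traj: Trajectory) -> np.ndarray:
    """Total measurable CAR-T count C(t) = CD + CT + CM + CE per time point."""
    return traj.C


def distributed_closed_form(t, CD0: float, beta: float, eta: float):
    """Closed form of the distributed compartment, CD(t) = CD(0) e^{-(beta+eta) t}.

    The CD equation is autonomous and linear, so this is exact; it doubles
    as an independent oracle for the numerical solver.
    """
    return CD0 * np.exp(-(beta + eta) * np.asarray(t, dtype=float))
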