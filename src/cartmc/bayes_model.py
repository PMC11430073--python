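"""Likelihood, priors and joint log-posterior for the 14-parameter model.

Inference runs over the 13 kinetic rates plus the measurement-noise
standard deviation ``sigma_obs`` of a normal likelihood on untransformed
counts:

    log L = sum_i [ -1/2 log(2 pi sigma^2) - (x_i - C(t_i))^2 / (2 sigma^2) ]

Priors are truncated normals on [0, inf): centered at the least-squares
estimates with per-parameter spreads, truncated below at zero because every
rate is biologically nonnegative (which is also the condition for the ODE
solution to exist).  ``sigma_obs`` gets the same family, centered at the
least-squares residual RMS.

A failed ODE integration inside the likelihood is mapped to a log-posterior
of -inf so that the offending proposal is simply rejected; samplers never
see the exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

from cartmc.data_io import ObservationSeries
from cartmc.least_squares_fit import LSResult
from cartmc.ode_model import (
    FixedParams,
    IntegrationError,
    KineticParams,
    KINETIC_NAMES,
    simulate,
)

__all__ = [
    "PARAM_NAMES",
    "PriorSpec",
    "InferenceParams",
    "PosteriorProblem",
    "normal_loglik",
    "truncated_normal_logpdf",
    "log_prior",
    "log_posterior",
    "default_priors",
]

#: canonical order of the 14 inference parameters (13 kinetics + noise SD)
PARAM_NAMES: tuple[str, ...] = KINETIC_NAMES + ("sigma_obs",)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Truncated-normal prior for one parameter."""

    center: float
    spread: float
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        if not self.spread > 0:
            raise ValueError(f"prior spread must be > 0, got {self.spread!r}")
        if not self.lower < self.upper:
            raise ValueError("prior lower bound must be below upper bound")

    @property
    def log_normalizer(self) -> float:
        """log[Phi((upper-center)/spread) - Phi((lower-center)/spread)]."""
        a = (self.lower - self.center) / self.spread
        b = (self.upper - self.center) / self.spread
        if math.isinf(b):
            if math.isinf(a):  # untruncated
                return 0.0
            # log(1 - Phi(a)) = log Phi(-a), stable in the tail
            return float(log_ndtr(-a))
        mass = float(ndtr(b) - ndtr(a))
        if mass <= 0:
            raise ValueError("prior truncation interval carries no probability mass")
        return math.log(mass)


@dataclass(frozen=True)
class InferenceParams:
    """One point in the 14-dimensional inference space."""

    kinetic: KineticParams
    sigma_obs: float

    def __post_init__(self) -> None:
        if not self.sigma_obs > 0:
            raise ValueError("sigma_obs must be > 0")

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.kinetic.to_array(), [self.sigma_obs]])

    @classmethod
    def from_array(cls, values) -> "InferenceParams":
        values = np.asarray(values, dtype=float)
        if values.size != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {values.size}")
        return cls(kinetic=KineticParams.from_array(values[:-1]), sigma_obs=float(values[-1]))


def normal_loglik(obs: ObservationSeries, predictions, sigma_obs: float) -> float:
    """Gaussian log-likelihood of counts given model predictions.

    Returns -inf when any prediction is non-finite (an integration failure
    propagated as a value, not an exception).
    """
    if sigma_obs <= 0:
        raise ValueError("sigma_obs must be > 0")
    pred = np.asarray(predictions, dtype=float)
    x = obs.counts
    if pred.shape != x.shape:
        raise ValueError(f"predictions shape {pred.shape} != observations shape {x.shape}")
    if not np.all(np.isfinite(pred)):
        return -math.inf
    n = x.size
    resid = x - pred
    return float(-0.5 * n * (_LOG_2PI + 2.0 * math.log(sigma_obs)) - np.sum(resid**2) / (2.0 * sigma_obs**2))


def truncated_normal_logpdf(theta: float, center: float, spread: float, lower: float = 0.0, upper: float = math.inf) -> float:
    """Log density of a normal(center, spread) truncated to [lower, upper]."""
    spec = PriorSpec(center=center, spread=spread, lower=lower, upper=upper)
    return _prior_logpdf(theta, spec)


def _prior_logpdf(theta: float, spec: PriorSpec) -> float:
    if theta < spec.lower or theta > spec.upper:
        return -math.inf
    z = (theta - spec.center) / spec.spread
    return -0.5 * (_LOG_2PI + z * z) - math.log(spec.spread) - spec.log_normalizer


def log_prior(params: InferenceParams, priors: dict[str, PriorSpec]) -> float:
    """Sum of the component truncated-normal log densities."""
    missing = [n for n in PARAM_NAMES if n not in priors]
    if missing:
        raise KeyError(f"missing PriorSpec for parameter(s): {missing}")
    values = params.to_array()
    total = 0.0
    for name, value in zip(PARAM_NAMES, values):
        lp = _prior_logpdf(value, priors[name])
        if lp == -math.inf:
            return -math.inf
        total += lp
    return total


def log_posterior(
    params: InferenceParams,
    obs: ObservationSeries,
    fixed: FixedParams,
    dose: float,
    T0: float,
    priors: dict[str, PriorSpec],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> float:
    """log prior + log likelihood; -inf on prior violation or ODE failure.

    The prior is evaluated first so that out-of-support proposals are
    rejected without paying for an ODE solve.
    """
    lp = log_prior(params, priors)
    if lp == -math.inf:
        return -math.inf
    try:
        traj = simulate(params.kinetic, fixed, dose, T0, obs.days, rtol=rtol, atol=atol)
    except IntegrationError:
        return -math.inf
    return lp + normal_loglik(obs, traj.C, params.sigma_obs)


#: default prior spreads for the parameters whose posteriors are
#: prior-dominated (the data barely constrain them); the remaining rates get
#: weakly informative spreads of half their center
_FIXED_SPREADS = {"A": 5.0, "p3": 5.0, "p2": 1.0e-11, "p1": 0.15}
_RELATIVE_SPREAD = 0.5
_SPREAD_FLOOR = 1.0e-3


def default_priors(
    ls_result: LSResult | KineticParams,
    residual_rms: float | None = None,
    reference: KineticParams | None = None,
) -> dict[str, PriorSpec]:
    """Build the default prior table from a least-squares stage.

    Centers are the least-squares estimates.  Spreads: fixed values for the
    saturation/expansion shape parameters (A, p3, p2, p1); every other rate
    gets a weakly informative spread of half its center, floored at half the
    literature reference value (and at an absolute 1e-3 day^-1).  The
    reference floor matters when the optimizer drives a rate to zero: a
    spread of half-of-zero would collapse the prior to a spike at the bound,
    which is the opposite of weakly informative -- the prior should never be
    narrower than the rate's a-priori scale.  The noise SD prior is centered
    at the residual RMS with spread equal to that RMS.

    Parameters
    ----------
    ls_result
        Either a full :class:`LSResult` (residual RMS derived from it) or a
        bare :class:`KineticParams` with ``residual_rms`` given explicitly.
    reference
        Literature point estimates defining each rate's a-priori scale;
        defaults to the bundled patient's published kinetics.
    """
    if isinstance(ls_result, LSResult):
        kinetic = ls_result.estimate
        if residual_rms is None:
            residual_rms = float(np.sqrt(np.mean(ls_result.residual_vector**2)))
    else:
        kinetic = ls_result
        if residual_rms is None:
            raise ValueError("residual_rms is required when passing bare KineticParams")
    if not residual_rms > 0:
        raise ValueError("residual_rms must be > 0")
    if reference is None:
        from cartmc.data_io import patient28_initial_kinetics

        reference = patient28_initial_kinetics()

    priors: dict[str, PriorSpec] = {}
    for name, center, ref in zip(KINETIC_NAMES, kinetic.to_array(), reference.to_array()):
        if name in _FIXED_SPREADS:
            spread = _FIXED_SPREADS[name]
        else:
            spread = max(_RELATIVE_SPREAD * center, _RELATIVE_SPREAD * ref, _SPREAD_FLOOR)
        priors[name] = PriorSpec(center=float(center), spread=float(spread))
    priors["sigma_obs"] = PriorSpec(center=residual_rms, spread=residual_rms)
    return priors


class PosteriorProblem:
    """Callable log-posterior over plain parameter vectors.

    Wraps one observation series, fixed parameters, infusion settings and a
    prior table into the ``f(theta: ndarray) -> float`` interface the
    samplers consume, with ``theta`` in :data:`PARAM_NAMES` order.
    """

    def __init__(
        self,
        obs: ObservationSeries,
        fixed: FixedParams,
        dose: float,
        T0: float,
        priors: dict[str, PriorSpec],
        *,
        rtol: float = 1e-8,
        atol: float = 1e-2,
    ) -> None:
        missing = [n for n in PARAM_NAMES if n not in priors]
        if missing:
            raise KeyError(f"missing PriorSpec for parameter(s): {missing}")
        self.obs = obs
        self.fixed = fixed
        self.dose = dose
        self.T0 = T0
        self.priors = priors
        self.rtol = rtol
        self.atol = atol
        self.param_names = PARAM_NAMES
        self.dim = len(PARAM_NAMES)
        # hot-loop constants
        self._prior_list = [priors[n] for n in PARAM_NAMES]
        self._x = obs.counts
        self._n = obs.counts.size
        self._centers = np.array([p.center for p in self._prior_list])
        self._spreads = np.array([p.spread for p in self._prior_list])
        self._lowers = np.array([p.lower for p in self._prior_list])
        self._uppers = np.array([p.upper for p in self._prior_list])
        self._lognorm_total = float(sum(p.log_normalizer for p in self._prior_list))
        self._logspread_total = float(np.sum(np.log(self._spreads)))

    def prior_spreads(self) -> np.ndarray:
        return np.array([p.spread for p in self._prior_list])

    def prior_centers(self) -> np.ndarray:
        return np.array([p.center for p in self._prior_list])

    def sample_from_priors(self, rng: np.random.Generator, max_tries: int = 1000) -> np.ndarray:
        """One draw from the joint prior with a finite posterior (rejection)."""
        for _ in range(max_tries):
            theta = np.empty(self.dim)
            for i, p in enumerate(self._prior_list):
                v = rng.normal(p.center, p.spread)
                while not (p.lower <= v <= p.upper) or (PARAM_NAMES[i] == "p3" and v <= 0) or (
                    PARAM_NAMES[i] == "sigma_obs" and v <= 0
                ):
                    v = rng.normal(p.center, p.spread)
                theta[i] = v
            if math.isfinite(self(theta)):
                return theta
        raise RuntimeError("could not find a prior draw with finite posterior")

    def __call__(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        # prior first: out-of-support points never pay for an ODE solve
        if np.any(theta < self._lowers) or np.any(theta > self._uppers):
            return -math.inf
        sigma = theta[-1]
        if sigma <= 0 or theta[5] <= 0:  # sigma_obs and p3 strictly positive
            return -math.inf
        z = (theta - self._centers) / self._spreads
        lp = -0.5 * (self.dim * _LOG_2PI + float(z @ z)) - self._logspread_total - self._lognorm_total
        try:
            kin = KineticParams.from_array(theta[:-1])
            traj = simulate(kin, self.fixed, self.dose, self.T0, self.obs.days, rtol=self.rtol, atol=self.atol)
        except (IntegrationError, ValueError):
            return -math.inf
        resid = self._x - traj.C
        return lp - 0.5 * self._n * (_LOG_2PI + 2.0 * math.log(sigma)) - float(np.sum(resid**2)) / (2.0 * sigma**2)
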