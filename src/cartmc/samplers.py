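"""Gradient-free MCMC kernels over an arbitrary log-density.

Three kernels, all accepting a callable ``logpost(theta) -> float``:

* :func:`mh_sample` -- random-walk Metropolis-Hastings with independent
  Gaussian proposals per coordinate.
* :func:`demetropolis_sample` -- differential-evolution Metropolis (DE-MC):
  a population of chains where chain i proposes
  ``x_i + gamma (x_a - x_b) + eps`` with a, b two other randomly chosen
  chains.  The population shape adapts proposals to the posterior's scale
  and correlation without any tuning beyond the single factor gamma.
* :func:`demetropolisz_sample` -- DE-MC-Z: difference vectors are drawn
  from a (thinned) history of the chain's own past states instead of a
  parallel population, so even a single chain can sample a d-dimensional
  target ("parallel direction" updates along ``z_a - z_b``).  Occasional
  gamma = 1 steps allow jumps between modes.

All kernels are deterministic given their seed; per-chain random streams
are spawned from one master ``SeedSequence``, so running chains in any
order (or concurrently) yields bit-identical output.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ChainSet",
    "accept_probability",
    "mh_sample",
    "demetropolis_sample",
    "demetropolisz_sample",
    "DEFAULT_GAMMA",
]

LogDensity = Callable[[np.ndarray], float]


def DEFAULT_GAMMA(dim: int) -> float:
    """The standard DE-MC scaling 2.38/sqrt(2 d), near-optimal for Gaussian targets."""
    return 2.38 / math.sqrt(2.0 * dim)


@dataclass
class ChainSet:
    """MCMC output: draws with log-posterior and acceptance bookkeeping.

    ``draws`` has shape (chains, iterations, dim); ``accept_flags[c, i]``
    records whether iteration i of chain c accepted its proposal, so the
    acceptance rate is exactly ``accept_flags.mean()``.
    """

    draws: np.ndarray
    log_posts: np.ndarray
    accept_flags: np.ndarray
    param_names: tuple[str, ...] | None = None
    tuning_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        if d.ndim != 3:
            raise ValueError("draws must have shape (chains, iterations, dim)")
        if self.log_posts.shape != d.shape[:2] or self.accept_flags.shape != d.shape[:2]:
            raise ValueError("log_posts/accept_flags inconsistent with draws shape")
        if self.param_names is not None and len(self.param_names) != d.shape[2]:
            raise ValueError("param_names length != parameter dimension")
        self.draws = d

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @property
    def dim(self) -> int:
        return self.draws.shape[2]

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accept_flags))

    def discard(self, fraction: float) -> "ChainSet":
        """Drop the first ``fraction`` of every chain (warm-up)."""
        if not 0 <= fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        k = int(round(fraction * self.n_draws))
        return ChainSet(
            draws=self.draws[:, k:, :],
            log_posts=self.log_posts[:, k:],
            accept_flags=self.accept_flags[:, k:],
            param_names=self.param_names,
            tuning_meta={**self.tuning_meta, "discarded": k},
        )

    def pooled(self) -> np.ndarray:
        """All chains concatenated: shape (chains*iterations, dim)."""
        return self.draws.reshape(-1, self.dim)

    def to_dataframe(self):
        """Long-format table with columns chain, draw, parameter, value."""
        import pandas as pd

        names = self.param_names or tuple(f"p{i}" for i in range(self.dim))
        c, n, d = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), n * d),
                "draw": np.tile(np.repeat(np.arange(n), d), c),
                "parameter": np.tile(list(names), c * n),
                "value": self.draws.ravel(),
            }
        )

    def to_arviz(self):
        """Convert to an :class:`arviz.InferenceData` for diagnostics."""
        import arviz as az

        names = self.param_names or tuple(f"p{i}" for i in range(self.dim))
        return az.from_dict({name: self.draws[:, :, i] for i, name in enumerate(names)})

    def save_csv(self, path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def save_manifest(self, path) -> Path:
        """JSON run manifest: settings, seeds, acceptance rate."""
        path = Path(path)
        manifest = {
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "dim": self.dim,
            "param_names": list(self.param_names) if self.param_names else None,
            "acceptance_rate": self.acceptance_rate,
            "tuning_meta": _jsonable(self.tuning_meta),
        }
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def accept_probability(log_p_new: float, log_p_old: float) -> float:
    """Metropolis acceptance probability min(1, exp(log_p_new - log_p_old)).

    A proposal with -inf log density is never accepted; if the current state
    is also at -inf (which a correctly initialized chain never reaches), the
    chain stays put.
    """
    if log_p_new == -math.inf:
        return 0.0
    diff = log_p_new - log_p_old
    if diff >= 0:
        return 1.0
    return math.exp(diff)


def _as_scales(scales, dim: int) -> np.ndarray:
    s = np.asarray(scales, dtype=float)
    if s.ndim == 0:
        s = np.full(dim, float(s))
    if s.shape != (dim,):
        raise ValueError(f"proposal scales must be scalar or length {dim}")
    if np.any(s < 0):
        raise ValueError("proposal scales must be >= 0")
    return s


def _init_matrix(init, n_chains: int, logpost: LogDensity, rng_per_chain) -> tuple[np.ndarray, np.ndarray]:
    """Normalize init to (n_chains, dim) and check finiteness of logpost."""
    if callable(init):
        x0 = np.stack([np.asarray(init(rng), dtype=float) for rng in rng_per_chain])
    else:
        x0 = np.array(init, dtype=float, copy=True)
        if x0.ndim == 1:
            x0 = np.tile(x0, (n_chains, 1))
        if x0.shape[0] != n_chains:
            raise ValueError(f"init has {x0.shape[0]} rows but n_chains={n_chains}")
    lp0 = np.array([logpost(x) for x in x0])
    if not np.all(np.isfinite(lp0)):
        bad = int(np.argmax(~np.isfinite(lp0)))
        raise ValueError(f"initial point of chain {bad} has non-finite log posterior")
    return x0, lp0


def mh_sample(
    logpost: LogDensity,
    init,
    n_draws: int,
    proposal_scales,
    seed: int,
    *,
    n_chains: int = 1,
    param_names: Sequence[str] | None = None,
) -> ChainSet:
    """Random-walk Metropolis-Hastings with independent Gaussian proposals.

    ``init`` may be a single vector (shared by all chains), a matrix of
    per-chain starting points, or a callable ``init(rng) -> vector``.
    """
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(n_chains)]
    x0, lp0 = _init_matrix(init, n_chains, logpost, rngs)
    dim = x0.shape[1]
    scales = _as_scales(proposal_scales, dim)
    if np.all(scales == 0):
        warnings.warn("all proposal scales are zero: chain will remain at its initial point")

    draws = np.empty((n_chains, n_draws, dim))
    lps = np.empty((n_chains, n_draws))
    acc = np.zeros((n_chains, n_draws), dtype=bool)
    for c in range(n_chains):
        rng = rngs[c]
        x, lp = x0[c].copy(), float(lp0[c])
        for i in range(n_draws):
            prop = x + rng.normal(0.0, 1.0, size=dim) * scales
            lp_prop = logpost(prop)
            if rng.random() < accept_probability(lp_prop, lp):
                x, lp = prop, lp_prop
                acc[c, i] = True
            draws[c, i] = x
            lps[c, i] = lp
    return ChainSet(
        draws=draws,
        log_posts=lps,
        accept_flags=acc,
        param_names=tuple(param_names) if param_names else None,
        tuning_meta={"sampler": "metropolis", "proposal_scales": scales, "seed": seed},
    )


def demetropolis_sample(
    logpost: LogDensity,
    init,
    n_chains: int,
    n_draws: int,
    seed: int,
    *,
    gamma: float | None = None,
    epsilon_scale=0.0,
    param_names: Sequence[str] | None = None,
) -> ChainSet:
    """DEMetropolis: population MCMC with difference-vector proposals.

    At each iteration every chain i proposes
    ``x_i + gamma (x_a - x_b) + eps`` with a != b != i drawn uniformly from
    the current population and ``eps ~ Normal(0, epsilon_scale)`` per
    coordinate.  Chains update sequentially within an iteration (each
    proposal sees the partners' latest states), which preserves detailed
    balance chain-by-chain.

    Requires ``n_chains >= 4`` so two distinct partners besides chain i
    always exist.  If every chain starts at the same point with
    ``epsilon_scale = 0`` the difference vectors are all zero and the
    population can never move -- give chains distinct starts (e.g. prior
    draws) or a nonzero jitter.
    """
    if n_chains < 4:
        raise ValueError("DEMetropolis needs n_chains >= 4 (two partners distinct from chain i)")
    ss = np.random.SeedSequence(seed)
    init_rngs = [np.random.default_rng(s) for s in ss.spawn(n_chains)]
    rng = np.random.default_rng(ss.spawn(1)[0])  # population stream
    x, lp = _init_matrix(init, n_chains, logpost, init_rngs)
    dim = x.shape[1]
    if gamma is None:
        gamma = DEFAULT_GAMMA(dim)
    eps = _as_scales(epsilon_scale, dim)

    draws = np.empty((n_chains, n_draws, dim))
    lps = np.empty((n_chains, n_draws))
    acc = np.zeros((n_chains, n_draws), dtype=bool)
    others = {i: np.array([j for j in range(n_chains) if j != i]) for i in range(n_chains)}
    for it in range(n_draws):
        for c in range(n_chains):
            a, b = rng.choice(others[c], size=2, replace=False)
            prop = x[c] + gamma * (x[a] - x[b])
            if np.any(eps > 0):
                prop = prop + rng.normal(0.0, 1.0, size=dim) * eps
            lp_prop = logpost(prop)
            if rng.random() < accept_probability(lp_prop, lp[c]):
                x[c], lp[c] = prop, lp_prop
                acc[c, it] = True
            draws[c, it] = x[c]
            lps[c, it] = lp[c]
    return ChainSet(
        draws=draws,
        log_posts=lps,
        accept_flags=acc,
        param_names=tuple(param_names) if param_names else None,
        tuning_meta={"sampler": "demetropolis", "gamma": gamma, "epsilon_scale": eps, "seed": seed},
    )


def demetropolisz_sample(
    logpost: LogDensity,
    init,
    n_draws: int,
    seed: int,
    *,
    n_chains: int = 1,
    gamma: float | None = None,
    epsilon_scale=0.0,
    thin_history: int = 1,
    p_gamma_one: float = 0.1,
    rw_fallback_scales=None,
    param_names: Sequence[str] | None = None,
) -> ChainSet:
    """DEMetropolisZ: difference vectors from a thinned history of past states.

    Each chain keeps its own history Z, seeded with its starting point and
    extended with every ``thin_history``-th accepted state.  A proposal is
    ``x + g (z_a - z_b) + eps`` with z_a != z_b drawn uniformly from Z and
    ``g = 1`` with probability ``p_gamma_one`` (full parallel-direction
    jumps that can hop between modes), else ``g = gamma``.  Because the
    history accumulates the posterior's own geometry, a single chain
    suffices even when the dimension exceeds any population size.

    Until the history holds two entries the kernel falls back to a Gaussian
    random walk with ``rw_fallback_scales`` (default: ``epsilon_scale``, or
    a unit scale when that is zero) -- documented warm-up behavior.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if thin_history < 1:
        raise ValueError("thin_history must be >= 1")
    if not 0 <= p_gamma_one <= 1:
        raise ValueError("p_gamma_one must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(2 * n_chains)
    init_rngs = [np.random.default_rng(s) for s in chain_seeds[:n_chains]]
    x0, lp0 = _init_matrix(init, n_chains, logpost, init_rngs)
    dim = x0.shape[1]
    if gamma is None:
        gamma = DEFAULT_GAMMA(dim)
    eps = _as_scales(epsilon_scale, dim)
    if rw_fallback_scales is None:
        fb = np.where(eps > 0, eps, 1.0)
    else:
        fb = _as_scales(rw_fallback_scales, dim)

    draws = np.empty((n_chains, n_draws, dim))
    lps = np.empty((n_chains, n_draws))
    acc = np.zeros((n_chains, n_draws), dtype=bool)
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[n_chains + c])
        x, lp = x0[c].copy(), float(lp0[c])
        history: list[np.ndarray] = [x.copy()]
        accepted_count = 0
        for i in range(n_draws):
            if len(history) >= 2:
                a, b = rng.choice(len(history), size=2, replace=False)
                g = 1.0 if rng.random() < p_gamma_one else gamma
                prop = x + g * (history[a] - history[b])
                if np.any(eps > 0):
                    prop = prop + rng.normal(0.0, 1.0, size=dim) * eps
            else:
                prop = x + rng.normal(0.0, 1.0, size=dim) * fb
            lp_prop = logpost(prop)
            if rng.random() < accept_probability(lp_prop, lp):
                x, lp = prop, lp_prop
                acc[c, i] = True
                accepted_count += 1
                if accepted_count % thin_history == 0:
                    history.append(x.copy())
            draws[c, i] = x
            lps[c, i] = lp
    return ChainSet(
        draws=draws,
        log_posts=lps,
        accept_flags=acc,
        param_names=tuple(param_names) if param_names else None,
        tuning_meta={
            "sampler": "demetropolisz",
            "gamma": gamma,
            "epsilon_scale": eps,
            "thin_history": thin_history,
            "p_gamma_one": p_gamma_one,
            "seed": seed,
        },
    )
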