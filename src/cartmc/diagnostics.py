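"""Posterior summaries, spread statistics and pairwise correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cartmc.samplers import ChainSet

__all__ = ["posterior_summary", "dispersion_coefficient", "pairwise_correlations", "PosteriorSummary"]

#: split-chain rank-normalized R-hat below this is labelled converged
RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior table plus chain-level convergence statistics.

    ``table`` columns: mean, sd, q2.5, q97.5, dispersion (the forest-plot
    spread statistic (q97.5 - q2.5)/mean), rhat, ess_bulk; one row per
    parameter.  ``acceptance_rate`` is the post-discard acceptance fraction.
    """

    table: pd.DataFrame
    acceptance_rate: float
    n_chains: int
    n_draws: int

    @property
    def converged(self) -> bool:
        r = self.table["rhat"].dropna()
        return bool((r < RHAT_THRESHOLD).all()) if len(r) else True

    def mean(self, name: str) -> float:
        return float(self.table.loc[name, "mean"])

    def sd(self, name: str) -> float:
        return float(self.table.loc[name, "sd"])


def posterior_summary(chains: ChainSet, discard: float = 0.2, min_draws: int = 100) -> PosteriorSummary:
    """Pooled post-warm-up moments, 95% interval bounds and convergence stats.

    Percentiles use linear interpolation between order statistics.  R-hat is
    the split-chain rank-normalized form and needs >= 2 chains (NaN
    otherwise); effective sample size is the bulk ESS.
    """
    kept = chains.discard(discard)
    if kept.n_draws < min_draws:
        raise ValueError(f"only {kept.n_draws} draws remain after discarding {discard:.0%}; need >= {min_draws}")
    pooled = kept.pooled()
    names = kept.param_names or tuple(f"p{i}" for i in range(kept.dim))

    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    q025, q975 = np.percentile(pooled, [2.5, 97.5], axis=0)
    disp = np.full(kept.dim, np.nan)
    nonzero = mean != 0
    disp[nonzero] = (q975[nonzero] - q025[nonzero]) / mean[nonzero]

    import arviz as az

    idata = kept.to_arviz()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz warns on few chains/draws
        if kept.n_chains >= 2:
            rhat_ds = az.rhat(idata)
            rhat = np.array([float(rhat_ds[n].values) for n in names])
        else:
            rhat = np.full(kept.dim, np.nan)
        ess_ds = az.ess(idata)
        ess = np.array([float(ess_ds[n].values) for n in names])

    table = pd.DataFrame(
        {"mean": mean, "sd": sd, "q2.5": q025, "q97.5": q975, "dispersion": disp, "rhat": rhat, "ess_bulk": ess},
        index=list(names),
    )
    return PosteriorSummary(
        table=table,
        acceptance_rate=float(np.mean(kept.accept_flags)),
        n_chains=kept.n_chains,
        n_draws=kept.n_draws,
    )


def dispersion_coefficient(samples) -> float:
    """Forest-plot spread statistic: (97.5th pct - 2.5th pct) / mean.

    Scale-invariant for positive samples; undefined (raises) at zero mean.
    """
    s = np.asarray(samples, dtype=float)
    m = s.mean()
    if m == 0:
        raise ValueError("dispersion coefficient is undefined for zero-mean samples")
    q025, q975 = np.percentile(s, [2.5, 97.5])
    return float((q975 - q025) / m)


def pairwise_correlations(chains: ChainSet, discard: float = 0.0) -> pd.DataFrame:
    """Pooled Pearson correlation matrix between parameters.

    Constant parameters have undefined correlation; their entries are
    reported as 0 with a warning (diagonal stays 1).
    """
    kept = chains.discard(discard) if discard else chains
    pooled = kept.pooled()
    if pooled.shape[1] < 2:
        raise ValueError("need at least two parameters for pairwise correlations")
    names = kept.param_names or tuple(f"p{i}" for i in range(kept.dim))
    const = pooled.std(axis=0) == 0
    if const.any():
        warnings.warn(f"constant parameter(s) {[n for n, c in zip(names, const) if c]}: correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(pooled, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(names), columns=list(names))
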