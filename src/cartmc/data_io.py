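"""Observation tables: reading, writing, and the bundled patient fixture.

The canonical on-disk dialect is a two-column CSV with header
``day,total_cart``: day of measurement and total circulating CAR-T count
(C = CD + CT + CM + CE, the only state that can be measured clinically).
Scientific notation is accepted on input and emitted on output.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cartmc.ode_model import KineticParams

__all__ = [
    "ObservationSeries",
    "read_observations",
    "write_observations",
    "patient28_fixture",
    "patient28_initial_kinetics",
    "patient28_dose",
    "DEFAULT_T0",
]

#: default initial tumor burden (cells) used throughout the analyses
DEFAULT_T0 = 1.0e7


@dataclass(frozen=True)
class ObservationSeries:
    """A per-patient series of (day, total CAR-T count) pairs.

    Days are unique and strictly increasing; counts are cells.  Real data
    are nonnegative, but synthetic data generated under an additive normal
    noise model may dip below zero at low counts, so negativity is allowed
    (flagged by ``allow_negative``).
    """

    days: np.ndarray
    counts: np.ndarray
    patient_id: str = "unknown"
    allow_negative: bool = False
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if d.ndim != 1 or d.shape != c.shape:
            raise ValueError("days and counts must be 1-D and of equal length")
        if d.size == 0:
            raise ValueError("observation series must contain at least one row")
        if np.any(d < 0):
            raise ValueError("days must be nonnegative")
        if np.unique(d).size != d.size:
            raise ValueError("days must be unique")
        order = np.argsort(d)
        d, c = d[order], c[order]
        if not self.allow_negative and np.any(c < 0):
            raise ValueError("negative counts in a real-data series (set allow_negative for synthetic data)")
        object.__setattr__(self, "days", d)
        object.__setattr__(self, "counts", c)

    def __len__(self) -> int:
        return self.days.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservationSeries):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and np.array_equal(self.days, other.days)
            and np.array_equal(self.counts, other.counts)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "total_cart": self.counts})


def read_observations(path, *, patient_id: str | None = None, allow_negative: bool = False) -> ObservationSeries:
    """Read a ``day,total_cart`` CSV into an :class:`ObservationSeries`.

    Rows are sorted by day; duplicate days, non-numeric cells and empty
    files are rejected with the offending row number where applicable.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty observation file") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: observation file has a header but no rows")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (day, count), found {df.shape[1]}")
    day_col, count_col = df.columns[:2]
    for col in (day_col, count_col):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric value {df[col][parsed.isna()].iloc[0]!r} in column {col!r} at line {row}")
        df[col] = parsed
    if df[day_col].duplicated().any():
        dup = df[day_col][df[day_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate day {dup!r}")
    return ObservationSeries(
        days=df[day_col].to_numpy(float),
        counts=df[count_col].to_numpy(float),
        patient_id=patient_id or path.stem,
        allow_negative=allow_negative,
    )


def write_observations(series: ObservationSeries, path) -> Path:
    """Write a series as canonical CSV; round-trips through
    :func:`read_observations` at full float precision."""
    if len(series) == 0:  # unreachable through the constructor, kept as a contract
        raise ValueError("refusing to write an empty observation series")
    path = Path(path)
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    return path


# -- Patient 28 fixture -------------------------------------------------------
#
# An 11-point total-CAR-T series for one adult B-cell lymphoma patient
# ("Patient 28" of the source clinical study): infusion at day 0, expansion
# to a peak near 1.1e9 cells at day 6, then contraction over four weeks.

_PATIENT28_ROWS: tuple[tuple[float, float], ...] = (
    (0.0, 9.230e7),
    (2.0, 1.128e7),
    (3.0, 4.029e7),
    (4.0, 3.106e8),
    (6.0, 1.070e9),
    (11.0, 4.786e8),
    (12.0, 3.259e8),
    (15.0, 2.245e8),
    (19.0, 1.372e8),
    (20.0, 1.340e8),
    (26.0, 7.801e7),
)


def patient28_fixture() -> ObservationSeries:
    """The bundled Patient 28 series (11 irregular samples over days 0-26)."""
    days, counts = zip(*_PATIENT28_ROWS)
    return ObservationSeries(days=np.array(days), counts=np.array(counts), patient_id="patient28")


def patient28_dose() -> float:
    """Infusion dose for Patient 28.

    The dose is not reported separately from the measurements; since
    C(0) = CD(0) = dose under the model's initial conditions, the day-0
    measured count is used as the dose.
    """
    return _PATIENT28_ROWS[0][1]


def patient28_initial_kinetics() -> KineticParams:
    """Literature point estimates of the 13 kinetic rates for Patient 28.

    These are the published frequentist estimates used as the optimizer's
    starting point and, indirectly, as prior centers.
    """
    return KineticParams(
        beta=1.051,
        eta=5.400e-2,
        r_min=1.000e-3,
        p1=1.750,
        p2=7.539e-25,
        p3=3.100e1,
        A=5.000e1,
        xi=2.548e-1,
        epsilon=6.000e-2,
        lambda_=1.000e-1,
        mu=9.010e-2,
        delta=1.498e-1,
        gamma=2.250,
    )


def patient28_reference_posterior_kinetics() -> KineticParams:
    """Published Bayesian posterior point estimates (means) for Patient 28.

    Used as a realistic ground truth when generating synthetic patients for
    recovery studies: these rates produce an expansion/contraction curve of
    the same shape and scale as the clinical series.
    """
    return KineticParams(
        beta=1.346,
        eta=1.150e-1,
        r_min=6.400e-2,
        p1=1.829,
        p2=1.013e-10,
        p3=3.105e1,
        A=5.024e1,
        xi=2.920e-1,
        epsilon=1.170e-1,
        lambda_=1.690e-1,
        mu=8.800e-2,
        delta=2.240e-1,
        gamma=2.515,
    )


def _fixture_csv_path() -> Path:
    return Path(str(importlib.resources.files("cartmc") / "data" / "patient28.csv"))
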