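"""Uniformly sampled sensor series: ingestion, splitting, windowing, scaling.

The canonical in-memory object is :class:`UniformSeries`, a named scalar
series sampled at a fixed interval (10 minutes for the aquaculture sensor
deployments this package targets).  Everything downstream — decomposition,
denoising, supervised windowing for the forecaster — consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UniformSeries",
    "WindowedDataset",
    "ScalingTransform",
    "read_water_csv",
    "split_train_test",
    "make_windows",
    "fit_apply_scaling",
]

#: Column names used by the aquaculture sensor CSV dialect:
#: dissolved oxygen, water temperature, salinity.
SENSOR_COLUMNS = ("rjy_con", "temp", "salt")


@dataclass(frozen=True)
class UniformSeries:
    """A named, uniformly sampled scalar sensor series.

    Parameters
    ----------
    name : str
        Label of the quantity (e.g. ``"temp"``).
    values : ndarray
        Finite sample values, length >= 2.
    dt_minutes : float
        Sampling interval in minutes; must be positive.  Uniform sampling
        is assumed by the frequency-domain decomposition downstream.
    units : str
        Physical units label (informational).
    """

    name: str
    values: np.ndarray
    dt_minutes: float = 10.0
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("series must be 1-D with length >= 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError("series contains non-finite values")
        if not (self.dt_minutes > 0):
            raise ValueError("dt_minutes must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, name: str | None = None) -> "UniformSeries":
        """Copy of this series with new sample values (same sampling grid)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       name=self.name if name is None else name)


@dataclass(frozen=True)
class WindowedDataset:
    """Sliding-window supervision pairs for one-step-ahead forecasting.

    ``inputs[i]`` is the length-``timesteps`` window ending at sample
    ``i + timesteps - 1`` and ``targets[i]`` is the immediately following
    sample, so there are ``N - timesteps`` pairs for a length-``N`` series.
    """

    inputs: np.ndarray   # shape (n_windows, timesteps)
    targets: np.ndarray  # shape (n_windows,)
    timesteps: int

    def __post_init__(self) -> None:
        if self.inputs.shape != (self.targets.size, self.timesteps):
            raise ValueError("inputs/targets/timesteps shapes inconsistent")

    def __len__(self) -> int:
        return self.targets.size


@dataclass(frozen=True)
class ScalingTransform:
    """Min–max scaling fitted on training data only (no test leakage).

    ``forward`` maps the fitted range onto [0, 1]; values outside the fitted
    range map outside [0, 1] and are deliberately not clipped.
    """

    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.max > self.min):
            raise ValueError("max must exceed min (constant series cannot be scaled)")

    def forward(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.min) / (self.max - self.min)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * (self.max - self.min) + self.min


def read_water_csv(path: str | Path, column: str, dt_minutes: float | None = None) -> UniformSeries:
    """Read one sensor column from a water-quality CSV.

    The expected dialect is comma-separated with a header row containing the
    sensor columns ``rjy_con`` (dissolved oxygen), ``temp`` (water
    temperature) and ``salt`` (salinity), optionally preceded by an ISO-8601
    timestamp column.  Any other numeric column present may also be selected.

    Missing or non-numeric cells are filled by linear interpolation between
    the nearest valid neighbours; leading/trailing gaps take the nearest
    valid value.  If a timestamp column is present and equispaced, the
    sampling interval is inferred from it; otherwise 10 minutes is assumed.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    KeyError
        If *column* is absent from the header.
    ValueError
        If fewer than 2 valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    if column not in df.columns:
        raise KeyError(f"column absent: {column!r} (found {list(df.columns)})")

    vals = pd.to_numeric(df[column], errors="coerce")
    n_valid = int(vals.notna().sum())
    if n_valid < 2:
        raise ValueError(f"fewer than 2 valid rows in column {column!r}")
    vals = vals.interpolate(method="linear", limit_direction="both")

    if dt_minutes is None:
        dt_minutes = 10.0
        first = df.columns[0]
        if first not in SENSOR_COLUMNS:
            ts = pd.to_datetime(df[first], errors="coerce", format="ISO8601")
            if ts.notna().all() and len(ts) > 1:
                deltas = ts.diff().dropna().dt.total_seconds() / 60.0
                if np.allclose(deltas, deltas.iloc[0]):
                    dt_minutes = float(deltas.iloc[0])

    units = {"rjy_con": "mg/L", "temp": "degC", "salt": "ppt"}.get(column, "")
    return UniformSeries(name=column, values=vals.to_numpy(dtype=float),
                         dt_minutes=dt_minutes, units=units)


def split_train_test(series: UniformSeries, train_fraction: float = 0.8
                     ) -> tuple[UniformSeries, UniformSeries]:
    """Chronological split: first ``floor(fraction * N)`` samples train, rest test."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(series)
    if n < 5:
        raise ValueError("series too short to split")
    n_train = int(np.floor(train_fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("split leaves a part shorter than 2")
    return (series.with_values(series.values[:n_train]),
            series.with_values(series.values[n_train:]))


def make_windows(series: UniformSeries | np.ndarray, timesteps: int) -> WindowedDataset:
    """Build stride-1 sliding windows with the next sample as the target."""
    vals = series.values if isinstance(series, UniformSeries) else np.asarray(series, float)
    n = vals.size
    if not (0 < timesteps < n):
        raise ValueError(f"timesteps must satisfy 0 < T < N (got T={timesteps}, N={n})")
    idx = np.arange(timesteps)[None, :] + np.arange(n - timesteps)[:, None]
    return WindowedDataset(inputs=vals[idx], targets=vals[timesteps:], timesteps=timesteps)


def fit_apply_scaling(train: UniformSeries | np.ndarray,
                      others: Sequence[UniformSeries | np.ndarray] = ()
                      ) -> tuple[np.ndarray, list[np.ndarray], ScalingTransform]:
    """Fit min–max scaling on *train* and apply it to train and *others*.

    Returns the scaled training values, the scaled other series (same order),
    and the fitted :class:`ScalingTransform` for inverting predictions back
    to the original physical scale.
    """
    tvals = train.values if isinstance(train, UniformSeries) else np.asarray(train, float)
    tr = ScalingTransform(min=float(tvals.min()), max=float(tvals.max()))
    scaled_others = [
        tr.forward(o.values if isinstance(o, UniformSeries) else np.asarray(o, float))
        for o in others
    ]
    return tr.forward(tvals), scaled_others, tr
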