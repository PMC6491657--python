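"""Sampled (time, concentration) observations — the package's I/O currency.

Times are minutes, concentrations μg/100 ml.  The CSV dialect is a two-column
UTF-8 file with header ``time_min,conc_ug_per_100ml`` and '.' as the decimal
separator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIME_COLUMN = "time_min"
VALUE_COLUMN = "conc_ug_per_100ml"


@dataclass(frozen=True)
class TimeSeries:
    """A finite, strictly time-ordered concentration series."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size == 0:
            raise ValueError("empty series")
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise ValueError("times and values must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def sampling_interval(self, rtol: float = 1e-9) -> float:
        """Return the uniform sampling interval, or raise if non-uniform."""
        if len(self) < 2:
            raise ValueError("need at least two samples to define an interval")
        dt = np.diff(self.times)
        h = float(dt[0])
        if not np.allclose(dt, h, rtol=rtol, atol=1e-9):
            raise ValueError("series is not uniformly sampled")
        return h

    def window(self, t_start: float, t_end: float) -> "TimeSeries":
        """Samples with t_start <= t <= t_end (inclusive, half-open safe)."""
        mask = (self.times >= t_start - 1e-9) & (self.times <= t_end + 1e-9)
        if not mask.any():
            raise ValueError(f"window [{t_start}, {t_end}] contains no samples")
        return TimeSeries(self.times[mask], self.values[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({TIME_COLUMN: self.times, VALUE_COLUMN: self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path)
        if TIME_COLUMN not in df.columns or VALUE_COLUMN not in df.columns:
            raise ValueError(
                f"expected columns {TIME_COLUMN!r}, {VALUE_COLUMN!r}; got {list(df.columns)}"
            )
        return cls(df[TIME_COLUMN].to_numpy(), df[VALUE_COLUMN].to_numpy())
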