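"""The chaotic circadian cortisol secretion model.

Cortisol concentration C(t) (μg/100 ml) obeys a scalar delay differential
equation with a Hill-type secretion term driven by delayed feedback and a
first-order elimination term::

    dC/dt = k1 * a(t)^n * C(t-d) / (a(t)^n + C(t-d)^n) - k2 * C(t)

where the circadian drive is a 24-hour cosine,
``a(t) = alpha * cos((t - tf) * 2*pi/1440) + beta``.  At the nominal
parameters the model is chaotic and produces roughly one secretion burst per
delay period (d = 70 min).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dde import DdeProblem, Trajectory, integrate
from .timeseries import TimeSeries

__all__ = [
    "CYCLE_MINUTES",
    "CortisolParameters",
    "circadian_amplitude",
    "driver_rhs",
    "simulate_driver",
    "simulate_driver_trajectory",
    "replicate_cycle",
]

#: One circadian cycle; all cycle-indexed logic (burn-in, evaluation windows)
#: derives from this.
CYCLE_MINUTES = 1440.0

_TWO_PI_OVER_CYCLE = 2.0 * math.pi / CYCLE_MINUTES


@dataclass(frozen=True)
class CortisolParameters:
    """The seven model constants.

    k1, k2 are the input/output rate constants (1/min, linear-entering);
    alpha, beta shape the circadian cosine drive (μg/100 ml); tf is the
    circadian phase (min); d the feedback delay (min); n the integer switch
    exponent controlling burst sharpness.

    ``beta > alpha`` keeps the drive a(t) positive for all t and is enforced
    unless ``allow_nonpositive_drive`` is set (sensitivity scans sweep alpha
    past beta; there, even n keeps a^n well defined while odd n with a
    negative base raises a domain error at evaluation time).
    """

    k1: float
    k2: float
    alpha: float
    beta: float
    tf: float
    d: float
    n: int
    allow_nonpositive_drive: bool = False

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if not self.k2 > 0:
            raise ValueError("k2 must be positive")
        if not self.d > 0:
            raise ValueError("delay d must be positive")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("switch exponent n must be a positive integer")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not self.beta > self.alpha and not self.allow_nonpositive_drive:
            raise ValueError(
                "beta must exceed alpha so the circadian drive stays positive; "
                "set allow_nonpositive_drive=True to override"
            )

    @classmethod
    def nominal(cls) -> "CortisolParameters":
        """Nominal constants of the cortisol model."""
        return cls(k1=0.0666, k2=0.0333, alpha=0.7, beta=1.0, tf=250.0, d=70.0, n=10)

    @classmethod
    def initial_nls(cls) -> "CortisolParameters":
        """The published starting-value set for classical fitting."""
        return cls(k1=1.0, k2=0.01, alpha=0.01, beta=0.1, tf=0.1, d=50.0, n=10)

    def replace(self, **kwargs) -> "CortisolParameters":
        return replace(self, **kwargs)


def circadian_amplitude(t, params: CortisolParameters):
    """Circadian drive a(t) = alpha*cos((t - tf)*2π/1440) + beta.

    Vectorized over t; lies in [beta - alpha, beta + alpha].
    """
    t = np.asarray(t, dtype=float)
    a = params.alpha * np.cos((t - params.tf) * _TWO_PI_OVER_CYCLE) + params.beta
    return float(a) if a.ndim == 0 else a


def driver_rhs(t: float, C: float, C_delayed: float, params: CortisolParameters) -> float:
    """dC/dt of the cortisol model at time t (scalar fast path)."""
    if C_delayed < 0:
        raise ValueError(
            f"delayed concentration must be non-negative, got {C_delayed} at t={t}"
        )
    a = params.alpha * math.cos((t - params.tf) * _TWO_PI_OVER_CYCLE) + params.beta
    n = params.n
    if a < 0 and n % 2 == 1:
        raise ValueError(
            f"negative circadian drive a={a:.6g} with odd exponent n={n} at t={t}"
        )
    an = a ** n
    cdn = C_delayed ** n
    return params.k1 * an * C_delayed / (an + cdn) - params.k2 * C


def simulate_driver_trajectory(
    params: CortisolParameters,
    n_cycles: int,
    history_value: float = 1.7,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-8,
    max_step: float = 1.0,
    t_end: float | None = None,
) -> Trajectory:
    """Integrate the driver over [0, n_cycles*1440] min with constant history."""
    if n_cycles < 1 and t_end is None:
        raise ValueError("n_cycles must be at least 1")
    end = float(t_end) if t_end is not None else n_cycles * CYCLE_MINUTES

    def rhs(t, y, y_d):
        return (driver_rhs(t, y[0], y_d[0], params),)

    problem = DdeProblem.constant_history(rhs, params.d, history_value, (0.0, end))
    return integrate(problem, rel_tol=rel_tol, abs_tol=abs_tol, max_step=max_step)


def simulate_driver(
    params: CortisolParameters,
    n_cycles: int,
    history_value: float = 1.7,
    sampling_interval: float = 1.0,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-8,
    max_step: float = 1.0,
) -> TimeSeries:
    """Simulate the driver and sample it on a uniform grid.

    Returns samples at t = 0, sampling_interval, ..., up to n_cycles*1440
    (truncating if the interval does not divide the span evenly).
    """
    traj = simulate_driver_trajectory(
        params, n_cycles, history_value, rel_tol, abs_tol, max_step
    )
    end = n_cycles * CYCLE_MINUTES
    n_samples = int(math.floor(end / sampling_interval + 1e-9)) + 1
    times = np.arange(n_samples) * sampling_interval
    values = traj(times)[:, 0]
    return TimeSeries(times, values)


def replicate_cycle(series: TimeSeries, n_copies: int) -> TimeSeries:
    """Tile a single-cycle series periodically over n_copies cycles.

    The input must span exactly one cycle (1440 min) on a uniform grid —
    either including the endpoint sample at t = 1440 (which is dropped; the
    first sample's phase recurs there) or stopping one interval short of it.
    Output times continue monotonically; value at t and t + 1440 are equal.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be at least 1")
    h = series.sampling_interval()
    span = series.span
    t0 = float(series.times[0])
    if abs(span - CYCLE_MINUTES) < 1e-6:
        period_values = series.values[:-1]
    elif abs(span + h - CYCLE_MINUTES) < 1e-6:
        period_values = series.values
    else:
        raise ValueError(
            f"series must span exactly one cycle ({CYCLE_MINUTES} min); spans {span}"
        )
    if n_copies == 1:
        return series
    m = period_values.size
    values = np.tile(period_values, n_copies)
    times = t0 + np.arange(m * n_copies) * h
    return TimeSeries(times, values)
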