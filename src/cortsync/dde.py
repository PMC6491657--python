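"""Constant-delay DDE integration by the method of steps.

The integrator advances interval-by-interval over ``[t0 + k*d, t0 + (k+1)*d]``
so that the delayed state always lies in an already-computed part of the
solution (or in the prescribed history).  Within each interval an embedded
explicit Runge–Kutta 2(3) pair (scipy's RK23) does the stepping; the continuous
solution is the cubic Hermite interpolant through the accepted step endpoints,
which is exactly the dense output of that pair.  Segment boundaries — where
derivative discontinuities propagate from the initial point — are never
stepped across, and the interpolant keeps one-sided derivatives there.

A low-order pair is deliberate: sharp switch-like nonlinearities (Hill
exponents around 10) make higher-order pairs waste effort near
quasi-discontinuities.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["DdeProblem", "Trajectory", "DdeIntegrationError", "integrate", "evaluate"]


class DdeIntegrationError(RuntimeError):
    """Raised when stepping produces a non-finite state or the solver fails.

    Carries ``t``, the time at which integration broke down.
    """

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


@dataclass(frozen=True)
class DdeProblem:
    """A DDE  y'(t) = rhs(t, y(t), y(t - delay))  with a single constant lag.

    Parameters
    ----------
    rhs : callable ``(t, y, y_delayed) -> dy/dt`` returning a length-
        ``dimension`` vector for finite inputs.
    delay : positive constant lag in minutes.
    history : callable ``t -> state`` defined and finite on
        ``[t0 - delay, t0]``.
    t_span : ``(t0, t_end)`` in minutes, ``t_end > t0``.
    dimension : state-space dimension.
    """

    rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    delay: float
    history: Callable[[float], np.ndarray]
    t_span: Tuple[float, float]
    dimension: int

    def __post_init__(self) -> None:
        if not self.delay > 0:
            raise ValueError(f"delay must be positive, got {self.delay}")
        t0, t_end = self.t_span
        if not t_end > t0:
            raise ValueError(f"t_end must exceed t0, got span {self.t_span}")
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")
        # Spot-check the history on its domain.
        for t in (t0 - self.delay, t0 - 0.5 * self.delay, t0):
            h = np.asarray(self.history(t), dtype=float)
            if h.shape != (self.dimension,) or not np.isfinite(h).all():
                raise ValueError(
                    f"history must return a finite vector of length {self.dimension} "
                    f"on [t0 - delay, t0]; failed at t={t}"
                )

    @classmethod
    def constant_history(
        cls,
        rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray],
        delay: float,
        value,
        t_span: Tuple[float, float],
    ) -> "DdeProblem":
        """Convenience constructor for a constant history vector."""
        v = np.atleast_1d(np.asarray(value, dtype=float))
        return cls(rhs=rhs, delay=delay, history=lambda t: v, t_span=t_span,
                   dimension=v.size)


def _hermite_scalar(T: np.ndarray, Y: np.ndarray, F: np.ndarray, t: float) -> np.ndarray:
    """Cubic-Hermite evaluation at scalar t on (possibly breakpoint-duplicated) nodes."""
    m = T.shape[0]
    i = int(np.searchsorted(T, t, side="right")) - 1
    if i < 0:
        i = 0
    if i > m - 2:
        i = m - 2
    h = T[i + 1] - T[i]
    if h == 0.0:  # landed on the left copy of a duplicated breakpoint
        i += 1
        h = T[i + 1] - T[i]
    s = (t - T[i]) / h
    if s == 0.0:
        return Y[i]
    s2 = s * s
    s3 = s2 * s
    h00 = 2.0 * s3 - 3.0 * s2 + 1.0
    h10 = s3 - 2.0 * s2 + s
    h01 = -2.0 * s3 + 3.0 * s2
    h11 = s3 - s2
    return h00 * Y[i] + (h10 * h) * F[i] + h01 * Y[i + 1] + (h11 * h) * F[i + 1]


@dataclass(frozen=True)
class Trajectory:
    """Dense-output DDE solution.

    ``mesh_times``/``states`` hold the accepted solver steps; internal arrays
    duplicate the delay breakpoints so one-sided derivatives are kept on each
    side.  Between adjacent mesh points the dense evaluator is a single cubic
    Hermite piece; evaluation at a mesh time reproduces the stored state
    exactly.
    """

    _T: np.ndarray  # node times, duplicated at delay breakpoints
    _Y: np.ndarray  # (m, dim) states
    _F: np.ndarray  # (m, dim) one-sided derivatives
    t_span: Tuple[float, float]

    @property
    def mesh_times(self) -> np.ndarray:
        """Strictly increasing accepted step times."""
        keep = np.ones(self._T.shape[0], dtype=bool)
        keep[1:] = np.diff(self._T) > 0
        return self._T[keep]

    @property
    def states(self) -> np.ndarray:
        keep = np.ones(self._T.shape[0], dtype=bool)
        keep[1:] = np.diff(self._T) > 0
        return self._Y[keep]

    def __call__(self, times):
        """Evaluate at scalar or array times within t_span."""
        scalar = np.isscalar(times) or np.ndim(times) == 0
        ts = np.atleast_1d(np.asarray(times, dtype=float))
        t0, t_end = self.t_span
        tol = 1e-9 * max(1.0, abs(t_end))
        if ts.min() < t0 - tol or ts.max() > t_end + tol:
            raise ValueError(
                f"evaluation times must lie within t_span {self.t_span}"
            )
        out = np.empty((ts.size, self._Y.shape[1]))
        for j, t in enumerate(ts):
            out[j] = _hermite_scalar(self._T, self._Y, self._F, min(max(t, t0), t_end))
        return out[0] if scalar else out


def evaluate(trajectory: Trajectory, times) -> np.ndarray:
    """Evaluate a trajectory's continuous interpolant at sorted times."""
    return trajectory(times)


def integrate(
    problem: DdeProblem,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-8,
    max_step: float = 1.0,
) -> Trajectory:
    """Integrate a constant-delay DDE over its t_span by the method of steps.

    The delayed state at time t is obtained from the history function for
    ``t - delay <= t0`` and from the trajectory's own dense output otherwise.
    """
    if not (rel_tol > 0 and abs_tol > 0 and max_step > 0):
        raise ValueError("tolerances and max_step must be positive")
    t0, t_end = problem.t_span
    d = problem.delay
    rhs = problem.rhs
    history = problem.history
    dim = problem.dimension

    y0 = np.asarray(history(t0), dtype=float)

    # Accumulated node store (duplicated at segment boundaries).
    T = np.array([], dtype=float)
    Y = np.empty((0, dim))
    F = np.empty((0, dim))

    def delayed(t: float) -> np.ndarray:
        tau = t - d
        if tau <= t0:
            return np.asarray(history(tau), dtype=float)
        return _hermite_scalar(T, Y, F, tau)

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        return np.asarray(rhs(t, y, delayed(t)), dtype=float)

    n_segments = int(np.ceil((t_end - t0) / d))
    y_cur = y0
    for k in range(n_segments):
        a = t0 + k * d
        b = min(a + d, t_end)
        sol = solve_ivp(
            fun, (a, b), y_cur, method="RK23",
            rtol=rel_tol, atol=abs_tol, max_step=max_step,
        )
        if not sol.success:
            raise DdeIntegrationError(
                f"integration failed at t={sol.t[-1]:.6g}: {sol.message}",
                t=float(sol.t[-1]),
            )
        seg_T = sol.t
        seg_Y = sol.y.T
        if not np.isfinite(seg_Y).all():
            bad = seg_T[np.argmax(~np.isfinite(seg_Y).all(axis=1))]
            raise DdeIntegrationError(
                f"non-finite state at t={bad:.6g}", t=float(bad)
            )
        # One-sided (within-segment) derivatives at the nodes.
        seg_F = np.empty_like(seg_Y)
        for j in range(seg_T.size):
            seg_F[j] = fun(seg_T[j], seg_Y[j])
        if not np.isfinite(seg_F).all():
            raise DdeIntegrationError(
                f"non-finite derivative within segment starting t={a:.6g}", t=a
            )
        T = np.concatenate([T, seg_T])
        Y = np.concatenate([Y, seg_Y])
        F = np.concatenate([F, seg_F])
        y_cur = seg_Y[-1]

    return Trajectory(_T=T, _Y=Y, _F=F, t_span=(t0, t_end))
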