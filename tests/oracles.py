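"""Independent numerical oracles used by the tests.

A fixed-step classical RK4 method-of-steps DDE integrator, written without
reference to the package's adaptive engine: the step size must divide the
delay so that delayed lookups fall on (or between) stored grid nodes, where
they are read back through a locally cubic Hermite reconstruction.
"""
from __future__ import annotations

import numpy as np


def rk4_dde(rhs, delay, history, t_end, h):
    """Integrate y' = rhs(t, y, y(t-delay)) from 0 to t_end with fixed step h.

    ``history(t)`` supplies the state on [-delay, 0].  ``h`` must divide the
    delay exactly.  Returns (times, states) on the fixed grid.
    """
    lag_steps = delay / h
    if abs(lag_steps - round(lag_steps)) > 1e-12:
        raise ValueError("step must divide the delay")
    lag = int(round(lag_steps))
    n_steps = int(round(t_end / h))
    y0 = np.atleast_1d(np.asarray(history(0.0), dtype=float))
    dim = y0.size
    Y = np.empty((n_steps + 1, dim))
    F = np.empty((n_steps + 1, dim))
    Y[0] = y0

    def delayed(i_float):
        """State at fractional grid index i_float - lag (cubic Hermite)."""
        j = i_float - lag
        if j <= 0:
            return np.atleast_1d(np.asarray(history(j * h), dtype=float))
        j0 = int(np.floor(j))
        s = j - j0
        if s == 0.0:
            return Y[j0]
        y0_, y1_ = Y[j0], Y[j0 + 1]
        f0_, f1_ = F[j0], F[j0 + 1]
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s * s * (3 - 2 * s)
        h11 = s * s * (s - 1)
        return h00 * y0_ + h10 * h * f0_ + h01 * y1_ + h11 * h * f1_

    def f(i_float, y):
        return np.atleast_1d(
            np.asarray(rhs(i_float * h, y, delayed(i_float)), dtype=float)
        )

    F[0] = f(0.0, Y[0])
    for i in range(n_steps):
        y = Y[i]
        k1 = F[i]
        k2 = f(i + 0.5, y + 0.5 * h * k1)
        k3 = f(i + 0.5, y + 0.5 * h * k2)
        k4 = f(i + 1.0, y + h * k3)
        Y[i + 1] = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        F[i + 1] = f(i + 1.0, Y[i + 1])
    return np.arange(n_steps + 1) * h, Y
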