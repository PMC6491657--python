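"""Exhaustive grid search over the nonlinearly-entering drive constants.

The rate constants k1, k2 enter the cortisol model linearly and are handled
by the adaptive synchronization observer (or a classical baseline); the drive
constants alpha and beta enter nonlinearly and are found by scanning a
rectangular mesh.  Each cell fixes (alpha, beta), runs the inner estimator,
and scores the tracking RMSE on the evaluation cycle; the reported optimum is
the argmin cell.  Cells are independent — the reduction is an explicit argmin
over the emitted table, so evaluation order (or parallel evaluation) cannot
change the result; ties break to the first cell in row-major order (alpha
outer, beta inner, both ascending).

During the scan the observer runs with a high Gamma/delta ratio for fast
convergence; a final pass at Gamma/delta = 1 re-estimates (k1, k2) at the
winning cell.
"""
from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classical import ExtendedLeastSquares, NonlinearLeastSquares
from .model import CYCLE_MINUTES
from .sync import SyncConfig, SynchronizationEstimator
from .timeseries import TimeSeries

__all__ = [
    "GridSpec",
    "GridResult",
    "NonlinearGridSearch",
    "rmse",
    "percent_error",
    "run_grid_search",
]

logger = logging.getLogger(__name__)


def rmse(a: TimeSeries, b: TimeSeries) -> float:
    """Root-mean-square difference of two series on identical time grids."""
    if len(a) != len(b) or not np.allclose(a.times, b.times, rtol=1e-9, atol=1e-6):
        raise ValueError("series must share an identical time grid")
    diff = a.values - b.values
    return float(np.sqrt(np.mean(diff * diff)))


def percent_error(estimate: float, nominal: float) -> float:
    """Absolute percent error, 100 * |estimate - nominal| / |nominal|."""
    if nominal == 0:
        raise ValueError("nominal value must be non-zero")
    return 100.0 * abs(estimate - nominal) / abs(nominal)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular (min, max, step) mesh over alpha and beta."""

    alpha: Tuple[float, float, float] = (0.1, 2.0, 0.1)
    beta: Tuple[float, float, float] = (0.1, 2.0, 0.1)

    def __post_init__(self) -> None:
        for name, (lo, hi, step) in (("alpha", self.alpha), ("beta", self.beta)):
            if lo > hi:
                raise ValueError(f"{name}: min must not exceed max")
            if not step > 0:
                raise ValueError(f"{name}: step must be positive")

    @staticmethod
    def _axis(triple: Tuple[float, float, float]) -> np.ndarray:
        lo, hi, step = triple
        m = int(math.floor((hi - lo) / step + 1e-9))
        return np.round(lo + step * np.arange(m + 1), 12)

    @property
    def alpha_values(self) -> np.ndarray:
        return self._axis(self.alpha)

    @property
    def beta_values(self) -> np.ndarray:
        return self._axis(self.beta)


@dataclass(frozen=True)
class GridResult:
    """Per-cell estimates and RMSE surface with its argmin.

    ``cells`` is a DataFrame with columns alpha, beta, k1_hat, k2_hat, rmse in
    row-major (alpha-outer) order; ``best`` is the first minimum-RMSE row.
    ``k1_refit``/``k2_refit`` come from the final low-ratio pass at the best
    cell (equal to the best cell's estimates when no refit was run).
    """

    cells: pd.DataFrame
    best: pd.Series
    k1_refit: float
    k2_refit: float

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


class NonlinearGridSearch(BaseEstimator):
    """Grid search over (alpha, beta) with an inner linear-parameter estimator.

    ``inner`` selects the per-cell estimator: ``"cs"`` (adaptive chaos
    synchronization, the default), ``"nls"`` or ``"els"``.  ``sync_config``
    carries the observer layout (cycles, tolerances, extraction); during the
    scan its Gamma and delta are overridden by ``scan_gamma``/``scan_delta``,
    and the final refit at the winning cell uses ``refit_gamma``/
    ``refit_delta``.
    """

    def __init__(
        self,
        grid: GridSpec | None = None,
        inner: str = "cs",
        sync_config: SyncConfig | None = None,
        scan_gamma: float = 10.0,
        scan_delta: float = 1.0,
        refit_gamma: float = 1.0,
        refit_delta: float = 1.0,
        final_refit: bool = True,
        refine: bool = False,
        inner_kwargs: Optional[dict] = None,
    ):
        self.grid = grid
        self.inner = inner
        self.sync_config = sync_config
        self.scan_gamma = scan_gamma
        self.scan_delta = scan_delta
        self.refit_gamma = refit_gamma
        self.refit_delta = refit_delta
        self.final_refit = final_refit
        self.refine = refine
        self.inner_kwargs = inner_kwargs

    def _cell_estimate(self, obs: TimeSeries, alpha: float, beta: float,
                       gamma: float, delta: float):
        cfg = self.sync_config or SyncConfig()
        kwargs = self.inner_kwargs or {}
        nonpositive = alpha >= beta
        if self.inner == "cs":
            cs_cfg = replace(
                cfg, alpha=alpha, beta=beta, gamma=gamma,
                delta1=delta, delta2=delta,
                allow_nonpositive_drive=cfg.allow_nonpositive_drive or nonpositive,
            )
            est = SynchronizationEstimator(**asdict(cs_cfg))
            est.fit(obs.times, obs.values)
            return est.k1_, est.k2_, est.rmse_
        if self.inner in ("nls", "els"):
            cls = NonlinearLeastSquares if self.inner == "nls" else ExtendedLeastSquares
            est = cls(alpha=alpha, beta=beta, tf=cfg.tf, d=cfg.d, n=cfg.n, **kwargs)
            est.fit(obs.times, obs.values)
            lo = cfg.burn_in_cycles * CYCLE_MINUTES
            hi = min((cfg.burn_in_cycles + 1) * CYCLE_MINUTES, float(obs.times[-1]))
            window = obs.window(lo, hi)
            pred = TimeSeries(window.times, est.predict(window.times))
            return est.k1_, est.k2_, rmse(pred, window)
        raise ValueError("inner must be 'cs', 'nls' or 'els'")

    def _scan(self, obs: TimeSeries, grid: GridSpec) -> pd.DataFrame:
        rows = []
        for alpha in grid.alpha_values:
            for beta in grid.beta_values:
                try:
                    k1, k2, err = self._cell_estimate(
                        obs, float(alpha), float(beta),
                        self.scan_gamma, self.scan_delta,
                    )
                except Exception as exc:  # noqa: BLE001 - cell failures are scored, not fatal
                    logger.warning(
                        "grid cell (alpha=%g, beta=%g) failed: %s", alpha, beta, exc
                    )
                    k1, k2, err = math.nan, math.nan, math.inf
                rows.append(
                    {"alpha": float(alpha), "beta": float(beta),
                     "k1_hat": k1, "k2_hat": k2, "rmse": err}
                )
        return pd.DataFrame(rows)

    def fit(self, X, y) -> "NonlinearGridSearch":
        obs = TimeSeries(
            np.asarray(X, dtype=float).reshape(-1),
            np.asarray(y, dtype=float).reshape(-1),
        )
        grid = self.grid or GridSpec()
        cells = self._scan(obs, grid)
        best_idx = int(np.argmin(cells["rmse"].to_numpy()))  # first min wins ties
        best = cells.iloc[best_idx]
        if self.refine and np.isfinite(best["rmse"]):
            # optional second stage: step/10 within one step of the incumbent
            a_step = grid.alpha[2]
            b_step = grid.beta[2]
            fine = GridSpec(
                alpha=(max(grid.alpha[0], best["alpha"] - a_step),
                       min(grid.alpha[1], best["alpha"] + a_step), a_step / 10.0),
                beta=(max(grid.beta[0], best["beta"] - b_step),
                      min(grid.beta[1], best["beta"] + b_step), b_step / 10.0),
            )
            fine_cells = self._scan(obs, fine)
            cells = pd.concat([cells, fine_cells], ignore_index=True)
            best_idx = int(np.argmin(cells["rmse"].to_numpy()))
            best = cells.iloc[best_idx]
        k1_refit, k2_refit = float(best["k1_hat"]), float(best["k2_hat"])
        if self.final_refit and self.inner == "cs" and np.isfinite(best["rmse"]):
            k1_refit, k2_refit, _ = self._cell_estimate(
                obs, float(best["alpha"]), float(best["beta"]),
                self.refit_gamma, self.refit_delta,
            )
        self.result_ = GridResult(
            cells=cells, best=best, k1_refit=k1_refit, k2_refit=k2_refit
        )
        self.alpha_ = float(best["alpha"])
        self.beta_ = float(best["beta"])
        self.k1_ = k1_refit
        self.k2_ = k2_refit
        self.rmse_ = float(best["rmse"])
        return self


def run_grid_search(
    obs: TimeSeries,
    grid: GridSpec | None = None,
    inner: str = "cs",
    sync_config: SyncConfig | None = None,
    **kwargs,
) -> GridResult:
    """Scan the (alpha, beta) mesh with an inner estimator (thin wrapper)."""
    est = NonlinearGridSearch(
        grid=grid, inner=inner, sync_config=sync_config, **kwargs
    )
    est.fit(obs.times, obs.values)
    return est.result_
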