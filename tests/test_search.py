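"""Tests for the error metrics and the (alpha, beta) grid search."""
import numpy as np
import pandas as pd
import pytest

from cortsync import GridSpec, TimeSeries, percent_error, rmse
from cortsync.search import NonlinearGridSearch


class TestRmse:
    def test_identical_series_zero(self):
        s = TimeSeries(np.arange(5.0), np.array([1.0, 2.0, 3.0, 2.0, 1.0]))
        assert rmse(s, s) == 0.0

    def test_constant_offset(self):
        t = np.arange(5.0)
        a = TimeSeries(t, np.zeros(5))
        b = TimeSeries(t, np.full(5, -0.3))
        assert rmse(a, b) == pytest.approx(0.3)

    def test_arithmetic_example(self):
        t = np.array([0.0, 1.0])
        assert rmse(
            TimeSeries(t, np.array([1.0, 2.0])),
            TimeSeries(t, np.array([2.0, 4.0])),
        ) == pytest.approx(np.sqrt(2.5))

    def test_grid_mismatch_rejected(self):
        a = TimeSeries(np.arange(5.0), np.ones(5))
        b = TimeSeries(np.arange(4.0), np.ones(4))
        with pytest.raises(ValueError):
            rmse(a, b)


class TestPercentError:
    def test_exact_estimate_zero(self):
        assert percent_error(0.0666, 0.0666) == 0.0

    def test_published_dense_and_sparse_values(self):
        assert percent_error(0.069, 0.0666) == pytest.approx(3.6, abs=0.05)
        assert percent_error(0.0615, 0.0666) == pytest.approx(7.66, abs=0.05)

    def test_zero_nominal_rejected(self):
        with pytest.raises(ValueError):
            percent_error(1.0, 0.0)


class TestGridSpec:
    def test_axis_construction(self):
        spec = GridSpec(alpha=(0.1, 2.0, 0.1), beta=(0.5, 1.2, 0.1))
        assert spec.alpha_values.size == 20
        assert spec.beta_values.size == 8
        np.testing.assert_allclose(spec.beta_values[0], 0.5)
        np.testing.assert_allclose(spec.beta_values[-1], 1.2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(alpha=(2.0, 0.1, 0.1))
        with pytest.raises(ValueError):
            GridSpec(beta=(0.1, 2.0, 0.0))


class _StubSearch(NonlinearGridSearch):
    """Grid search with a deterministic analytic inner objective."""

    def _cell_estimate(self, obs, alpha, beta, gamma, delta):
        err = (alpha - 0.7) ** 2 + (beta - 1.0) ** 2
        return 0.05, 0.03, err


class TestGridSearch:
    def test_single_cell_grid(self, driver_two_cycles):
        est = _StubSearch(grid=GridSpec(alpha=(0.7, 0.7, 0.1), beta=(1.0, 1.0, 0.1)))
        est.fit(driver_two_cycles.times, driver_two_cycles.values)
        assert (est.alpha_, est.beta_) == (0.7, 1.0)

    def test_argmin_matches_brute_force_re_scan(self, driver_two_cycles):
        est = _StubSearch(grid=GridSpec(alpha=(0.3, 1.1, 0.2), beta=(0.6, 1.4, 0.2)))
        est.fit(driver_two_cycles.times, driver_two_cycles.values)
        cells = est.result_.cells
        idx = cells["rmse"].to_numpy().argmin()
        assert est.result_.best.equals(cells.iloc[idx])
        assert (est.alpha_, est.beta_) == (
            cells.iloc[idx]["alpha"], cells.iloc[idx]["beta"]
        )

    def test_tie_breaks_to_first_row_major_cell(self, driver_two_cycles):
        class Flat(NonlinearGridSearch):
            def _cell_estimate(self, obs, alpha, beta, gamma, delta):
                return 0.05, 0.03, 1.0  # all cells tie

        est = Flat(grid=GridSpec(alpha=(0.5, 0.7, 0.1), beta=(0.9, 1.1, 0.1)))
        est.fit(driver_two_cycles.times, driver_two_cycles.values)
        assert (est.alpha_, est.beta_) == (0.5, 0.9)

    def test_refinement_never_increases_best_rmse(self, driver_two_cycles):
        coarse = _StubSearch(grid=GridSpec(alpha=(0.3, 1.1, 0.2), beta=(0.6, 1.4, 0.2)))
        coarse.fit(driver_two_cycles.times, driver_two_cycles.values)
        fine = _StubSearch(
            grid=GridSpec(
                alpha=(coarse.alpha_ - 0.1, coarse.alpha_ + 0.1, 0.1),
                beta=(coarse.beta_ - 0.1, coarse.beta_ + 0.1, 0.1),
            )
        )
        fine.fit(driver_two_cycles.times, driver_two_cycles.values)
        assert fine.rmse_ <= coarse.rmse_

    def test_optional_refine_stage_sharpens_the_optimum(self, driver_two_cycles):
        class OffGrid(NonlinearGridSearch):
            def _cell_estimate(self, obs, alpha, beta, gamma, delta):
                return 0.05, 0.03, (alpha - 0.73) ** 2 + (beta - 1.01) ** 2

        grid = GridSpec(alpha=(0.5, 1.0, 0.1), beta=(0.8, 1.2, 0.1))
        coarse = OffGrid(grid=grid, final_refit=False)
        coarse.fit(driver_two_cycles.times, driver_two_cycles.values)
        fine = OffGrid(grid=grid, refine=True, final_refit=False)
        fine.fit(driver_two_cycles.times, driver_two_cycles.values)
        assert (fine.alpha_, fine.beta_) == (0.73, 1.01)
        assert fine.rmse_ <= coarse.rmse_

    def test_failing_cell_scored_infinite_not_fatal(self, driver_two_cycles):
        class Failing(NonlinearGridSearch):
            def _cell_estimate(self, obs, alpha, beta, gamma, delta):
                if alpha == 0.5:
                    raise RuntimeError("cell blew up")
                return 0.05, 0.03, (alpha - 0.7) ** 2 + (beta - 1.0) ** 2

        est = Failing(grid=GridSpec(alpha=(0.5, 0.7, 0.1), beta=(1.0, 1.0, 0.1)),
                      final_refit=False)
        est.fit(driver_two_cycles.times, driver_two_cycles.values)
        cells = est.result_.cells
        assert np.isinf(cells[cells.alpha == 0.5]["rmse"]).all()
        assert est.alpha_ == pytest.approx(0.7)
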