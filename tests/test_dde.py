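"""Unit and property tests for the method-of-steps DDE engine."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortsync import DdeProblem, DdeIntegrationError, evaluate, integrate
from cortsync.model import CortisolParameters, driver_rhs

from .oracles import rk4_dde


def _decay_problem(rate=0.0333, y0=1.7, t_end=60.0):
    return DdeProblem.constant_history(
        lambda t, y, yd: -rate * y, 70.0, y0, (0.0, t_end)
    )


class TestIntegrate:
    def test_linear_decay_matches_closed_form(self):
        traj = integrate(_decay_problem())
        expected = 1.7 * np.exp(-0.0333 * 60.0)
        assert traj(60.0)[0] == pytest.approx(expected, rel=1e-5)

    def test_equilibrium_is_invariant(self):
        # rhs vanishing on the diagonal keeps a constant history constant
        prob = DdeProblem.constant_history(
            lambda t, y, yd: yd - y, 50.0, 2.5, (0.0, 300.0)
        )
        traj = integrate(prob)
        sampled = traj(np.linspace(0, 300, 31))
        np.testing.assert_allclose(sampled, 2.5, rtol=0, atol=1e-9)

    def test_delayed_negative_feedback_matches_rk4_oracle(self):
        # y' = -y(t - 70), constant history 1: genuinely delay-dominated
        prob = DdeProblem.constant_history(
            lambda t, y, yd: -yd, 70.0, 1.0, (0.0, 140.0)
        )
        traj = integrate(prob, rel_tol=1e-8, abs_tol=1e-10)
        _, Y = rk4_dde(lambda t, y, yd: -yd, 70.0, lambda t: np.array([1.0]),
                       140.0, 0.01)
        assert traj(140.0)[0] == pytest.approx(Y[-1, 0], rel=1e-6)
        # off-mesh point between two adjacent nodes, aligned to the oracle grid
        mesh = traj.mesh_times
        mid = 0.5 * (mesh[10] + mesh[11])
        i_mid = int(np.floor(mid / 0.01))
        t_eval = i_mid * 0.01
        assert mesh[10] < t_eval < mesh[11]
        assert traj(t_eval)[0] == pytest.approx(Y[i_mid, 0], abs=1e-6)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            DdeProblem.constant_history(lambda t, y, yd: -y, -1.0, 1.0, (0.0, 10.0))
        with pytest.raises(ValueError):
            DdeProblem.constant_history(lambda t, y, yd: -y, 5.0, 1.0, (10.0, 0.0))
        with pytest.raises(ValueError):
            integrate(_decay_problem(), rel_tol=-1e-6)

    def test_blowup_reports_failure_time(self):
        prob = DdeProblem.constant_history(
            lambda t, y, yd: y * y * 10.0, 70.0, 5.0, (0.0, 100.0)
        )
        with pytest.raises(DdeIntegrationError) as err:
            integrate(prob)
        assert err.value.t is not None

    def test_determinism(self):
        a = integrate(_decay_problem(t_end=200.0))
        b = integrate(_decay_problem(t_end=200.0))
        np.testing.assert_array_equal(a.mesh_times, b.mesh_times)
        np.testing.assert_array_equal(a.states, b.states)

    @settings(deadline=None, max_examples=20)
    @given(rate=st.floats(0.001, 0.1), y0=st.floats(0.1, 5.0))
    def test_decay_property(self, rate, y0):
        traj = integrate(_decay_problem(rate=rate, y0=y0, t_end=100.0))
        assert traj(100.0)[0] == pytest.approx(
            y0 * np.exp(-rate * 100.0), rel=1e-3, abs=1e-6
        )


class TestEvaluate:
    def test_mesh_knots_reproduced_exactly(self):
        traj = integrate(_decay_problem(t_end=150.0))
        np.testing.assert_array_equal(
            evaluate(traj, traj.mesh_times), traj.states
        )

    def test_closed_form_at_interior_time(self):
        traj = integrate(_decay_problem())
        assert traj(30.0)[0] == pytest.approx(1.7 * np.exp(-0.0333 * 30.0), rel=1e-5)

    def test_out_of_span_raises(self):
        traj = integrate(_decay_problem())
        with pytest.raises(ValueError):
            traj(61.0)
        with pytest.raises(ValueError):
            traj(-1.0)


class TestAgainstDriverOracle:
    """Engine accuracy on the actual cortisol dynamics."""

    def test_tolerance_halving_reduces_error(self, nominal_params):
        p = nominal_params

        def rhs(t, y, yd):
            return (driver_rhs(t, y[0], yd[0], p),)

        prob = DdeProblem.constant_history(rhs, p.d, 1.7, (0.0, 1440.0))
        _, Y = rk4_dde(
            lambda t, y, yd: np.array([driver_rhs(t, y[0], yd[0], p)]),
            p.d, lambda t: np.array([1.7]), 1440.0, 0.02,
        )
        probe = np.arange(0, 1441, 10.0)
        idx = (probe / 0.02).round().astype(int)
        ref = Y[idx, 0]
        errors = []
        for scale in (1.0, 0.5):
            traj = integrate(prob, rel_tol=1e-5 * scale, abs_tol=1e-7 * scale)
            errors.append(np.max(np.abs(traj(probe)[:, 0] - ref)))
        # monotone within a factor-2 slack
        assert errors[1] <= errors[0] * 2.0

    def test_engine_matches_oracle_to_1e4(self, nominal_params):
        p = nominal_params

        def rhs(t, y, yd):
            return (driver_rhs(t, y[0], yd[0], p),)

        prob = DdeProblem.constant_history(rhs, p.d, 1.7, (0.0, 1440.0))
        traj = integrate(prob)
        _, Y = rk4_dde(
            lambda t, y, yd: np.array([driver_rhs(t, y[0], yd[0], p)]),
            p.d, lambda t: np.array([1.7]), 1440.0, 0.02,
        )
        probe = np.arange(0, 1441, 5.0)
        idx = (probe / 0.02).round().astype(int)
        ref = Y[idx, 0]
        rel = np.max(np.abs(traj(probe)[:, 0] - ref) / np.abs(ref))
        assert rel < 1e-4
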