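"""Prediction, Newton-matrix assembly and the simplified Newton solve."""

import numpy as np
import pytest

from odesd import ODEModel, integrate, make_fixture
from odesd.error_control import ErrorNorm
from odesd.exceptions import NewtonMatrixSingularError
from odesd.model import StepHistory, SolverStats, second_derivative
from odesd.stepper import build_newton_matrix, newton_solve, predict


def stability_function(z):
    """One-step amplification of the rule on xdot = lambda x."""
    return (1 + z / 2 + z**2 / 12) / (1 - z / 2 + z**2 / 12)


def _history_from_solution(x_of_t, t, h_prev, lam=None):
    """Exact StepHistory for scalar xdot = lam*x (or a callable triple)."""
    x, xd, xdd = x_of_t(t)
    xp, xdp, xddp = x_of_t(t - h_prev)
    return StepHistory(t=t, h=h_prev, x=x, xdot=xd, xddot=xdd, h_prev=h_prev,
                       x_prev=xp, xdot_prev=xdp, xddot_prev=xddp, has_prev=True)


class TestPredict:
    def test_constant_solution(self):
        z = np.zeros(2)
        hist = StepHistory(t=1.0, h=0.5, x=np.array([3.0, -1.0]), xdot=z, xddot=z,
                           h_prev=0.5, x_prev=np.array([3.0, -1.0]),
                           xdot_prev=z, xddot_prev=z, has_prev=True)
        assert np.allclose(predict(hist, 0.7), [3.0, -1.0])

    def test_quadratic_solution_reproduced(self):
        x_of_t = lambda t: (np.array([t**2]), np.array([2 * t]), np.array([2.0]))
        hist = _history_from_solution(x_of_t, 2.0, 0.3)
        assert predict(hist, 0.4)[0] == pytest.approx(2.4**2, rel=1e-13)

    def test_first_step_taylor(self):
        hist = StepHistory(t=0.0, h=0.0, x=np.array([1.0]),
                           xdot=np.array([-1.0]), xddot=np.array([1.0]))
        assert predict(hist, 0.1)[0] == pytest.approx(0.905, abs=1e-15)


class TestNewtonMatrix:
    def test_scalar_closed_form(self):
        lam, h = -3.0, 0.2
        model = ODEModel(n_states=1, n_params=0,
                         rhs=lambda x, p: lam * x,
                         jacobian=lambda x, p: np.array([[lam]]),
                         second_rhs_jacobian=lambda x, p: np.array([[lam**2]]))
        ws = build_newton_matrix(model, np.array([1.0]), None, h)
        assert ws.M[0, 0] == pytest.approx(h / 2 * lam - h**2 / 12 * lam**2 - 1)

    def test_vanishing_step_gives_minus_identity(self):
        A = np.array([[0.0, 1.0], [-2.0, -3.0]])
        model = ODEModel(n_states=2, n_params=0, rhs=lambda x, p: A @ x,
                         jacobian=lambda x, p: A,
                         second_rhs_jacobian=lambda x, p: A @ A)
        ws = build_newton_matrix(model, np.zeros(2), None, 1e-12)
        assert np.allclose(ws.M, -np.eye(2), atol=1e-11)

    def test_two_by_two_entrywise(self):
        A = np.array([[-1.0, 0.5], [0.25, -2.0]])
        h = 0.5
        model = ODEModel(n_states=2, n_params=0, rhs=lambda x, p: A @ x,
                         jacobian=lambda x, p: A,
                         second_rhs_jacobian=lambda x, p: A @ A)
        ws = build_newton_matrix(model, np.ones(2), None, h)
        assert np.allclose(ws.M, h / 2 * A - h**2 / 12 * (A @ A) - np.eye(2),
                           rtol=1e-15)

    def test_singular_matrix_signals(self):
        # J = (2/h) I, JJ = 0 makes M = 0 exactly
        model = ODEModel(n_states=2, n_params=0, rhs=lambda x, p: 2.0 * x,
                         jacobian=lambda x, p: 2.0 * np.eye(2),
                         second_rhs_jacobian=lambda x, p: np.zeros((2, 2)))
        with pytest.raises(NewtonMatrixSingularError):
            build_newton_matrix(model, np.ones(2), None, 1.0)


class TestNewtonSolve:
    def _decay_model(self):
        return make_fixture("linear_decay").compile()

    def _solve_one_step(self, model, hist, h, p, **kwargs):
        norm = ErrorNorm(1e-12, 1e-10, n=model.n_states)
        x_pred = predict(hist, h)
        ws = build_newton_matrix(model, x_pred, p, h)
        return newton_solve(ws, model, hist, p, h, x_pred, norm, **kwargs)

    def test_linear_problem_lands_on_rational_fixed_point(self):
        model = self._decay_model()
        p = np.array([1.0])
        h = 0.1
        hist = StepHistory(t=0.0, h=0.0, x=np.array([1.0]), xdot=np.array([-1.0]),
                           xddot=np.array([1.0]))
        x_new, f_new, xdd_new, _ = self._solve_one_step(model, hist, h, p)
        assert x_new[0] == pytest.approx(stability_function(-h), rel=1e-14)
        # one-step defect bounded by the h^5/720 truncation term (1.39e-8)
        assert abs(x_new[0] - np.exp(-h)) <= 1.5e-8
        assert f_new[0] == pytest.approx(-x_new[0])
        assert xdd_new[0] == pytest.approx(x_new[0])

    def test_mm_single_step_preserves_conserved_totals(self, mm):
        fx, model = mm
        x0, p, h = fx.x0, fx.p, 0.01
        f0 = model.rhs(x0, p)
        hist = StepHistory(t=0.0, h=0.0, x=x0, xdot=f0,
                           xddot=second_derivative(model, x0, p, f=f0))
        x1, _, _, _ = self._solve_one_step(model, hist, h, p)
        assert x1[0] + x1[2] == pytest.approx(x0[0] + x0[2], abs=1e-12)
        assert x1[1] + x1[2] + x1[3] == pytest.approx(x0[1] + x0[2] + x0[3],
                                                      abs=1e-12)

    def test_jacobians_evaluated_once_per_attempted_step(self, mm):
        """Simplified-Newton contract: J_f/J_Jf frozen at the predictor."""
        fx, model = mm
        calls = {"jac": 0, "jjf": 0}
        counting = ODEModel(
            n_states=4, n_params=3, rhs=model.rhs,
            jacobian=lambda x, p: (calls.__setitem__("jac", calls["jac"] + 1),
                                   model.jacobian(x, p))[1],
            second_rhs_jacobian=lambda x, p: (calls.__setitem__("jjf", calls["jjf"] + 1),
                                              model.second_rhs_jacobian(x, p))[1],
            second_rhs=model.second_rhs,
        )
        sol = integrate(counting, fx.x0, fx.p, (0.0, 10.0), rtol=1e-6, atol=1e-9)
        assert sol.success
        attempts = sol.stats.steps_accepted + sol.stats.steps_rejected
        assert calls["jac"] == attempts
        assert calls["jjf"] == attempts
        assert sol.stats.n_jac == attempts


class TestLinearStability:
    def test_a_stability_on_left_half_plane_grid(self):
        re = np.linspace(-100.0, -1e-3, 40)
        im = np.linspace(-100.0, 100.0, 41)
        Z = re[:, None] + 1j * im[None, :]
        assert np.all(np.abs(stability_function(Z)) < 1.0)

    def test_consistency_with_exponential_to_fifth_order(self):
        for z in (1e-2, -1e-2, 1e-2j, (1 + 1j) * 1e-2):
            assert abs(stability_function(z) - np.exp(z)) < 3 * abs(z) ** 5 / 720

    def test_local_order_five_on_decay(self):
        model = make_fixture("linear_decay").compile()
        p = np.array([1.0])
        errs, hs = [], np.geomspace(0.02, 0.2, 8)
        norm = ErrorNorm(1e-14, 1e-14, n=1)
        for h in hs:
            hist = StepHistory(t=0.0, h=0.0, x=np.array([1.0]),
                               xdot=np.array([-1.0]), xddot=np.array([1.0]))
            x_pred = predict(hist, h)
            ws = build_newton_matrix(model, x_pred, p, h)
            x1, _, _, _ = newton_solve(ws, model, hist, p, h, x_pred, norm,
                                       newton_tol=1e-4, max_iter=20)
            errs.append(abs(x1[0] - np.exp(-h)))
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope == pytest.approx(5.0, abs=0.1)
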