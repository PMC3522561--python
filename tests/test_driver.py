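"""Integration loop: accuracy, order, dense output, statistics, failure."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from odesd import (
    ODEModel,
    SymbolicModel,
    compile_model,
    integrate,
    make_fixture,
    precision_of,
)
from odesd.model import Solution


def _radau_reference(model, x0, p, t_span, rtol=1e-12, atol=1e-14):
    ref = solve_ivp(lambda t, x: model.rhs(x, p), t_span, x0, method="Radau",
                    rtol=rtol, atol=atol, jac=lambda t, x: model.jacobian(x, p))
    assert ref.success
    return ref.y[:, -1]


class TestAccuracy:
    def test_decay_to_t_ten(self, decay):
        fx, model = decay
        sol = integrate(model, fx.x0, fx.p, (0.0, 10.0), rtol=1e-8, atol=1e-12)
        exact = np.exp(-10.0)
        assert abs(sol.final_state[0] - exact) / exact <= 1e-6

    def test_zero_rhs_constant_solution(self):
        model = compile_model(SymbolicModel.from_rates(["x", "y"], [], ["0", "0"]))
        sol = integrate(model, np.array([2.0, -1.0]), np.array([]), (0.0, 100.0),
                        rtol=1e-6, atol=1e-9)
        assert sol.success
        assert np.all(sol.states == sol.states[0])
        assert sol.stats.steps_rejected == 0
        assert sol.stats.steps_accepted <= 15

    def test_mm_against_tight_reference(self, mm):
        fx, model = mm
        sol = integrate(model, fx.x0, fx.p, fx.t_span, rtol=1e-6, atol=1e-12)
        ref = _radau_reference(model, fx.x0, fx.p, fx.t_span)
        assert precision_of(sol, ref) <= 1e-5

    def test_mm_conserved_totals(self, mm):
        fx, model = mm
        sol = integrate(model, fx.x0, fx.p, fx.t_span, rtol=1e-6, atol=1e-12)
        enzyme = sol.states[:, 0] + sol.states[:, 2]
        mass = sol.states[:, 1] + sol.states[:, 2] + sol.states[:, 3]
        assert np.max(np.abs(enzyme - enzyme[0])) <= 1e-9
        assert np.max(np.abs(mass - mass[0])) <= 1e-9

    def test_repressilator_against_tight_reference(self, repressilator):
        fx, model = repressilator
        sol = integrate(model, fx.x0, fx.p, fx.t_span, rtol=1e-8, atol=1e-10)
        ref = _radau_reference(model, fx.x0, fx.p, fx.t_span)
        assert precision_of(sol, ref) <= 1e-4  # oscillatory: phase error dominates

    def test_global_order_four_at_fixed_step(self, decay):
        fx, model = decay
        errs, hs = [], [0.2, 0.1, 0.05, 0.025, 0.0125]
        for h in hs:
            sol = integrate(model, fx.x0, fx.p, (0.0, 1.0), fixed_step=h,
                            rtol=1e-13, atol=1e-13, newton_max_iter=20)
            errs.append(abs(sol.final_state[0] - np.exp(-1.0)))
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope == pytest.approx(4.0, abs=0.1)


class TestDenseOutput:
    def test_endpoints_are_bit_exact(self, mm):
        fx, model = mm
        sol = integrate(model, fx.x0, fx.p, (0.0, 10.0), rtol=1e-6, atol=1e-9)
        for i in (0, len(sol.times) // 2, -1):
            t = sol.times[i]
            assert np.array_equal(sol(t), sol.states[i])

    def test_quartic_solution_exact_in_interior(self):
        # nilpotent linear system: y = (1, t, t^2, t^3, t^4)
        N = np.diag([1.0, 2.0, 3.0, 4.0], k=-1)
        model = ODEModel(n_states=5, n_params=0, rhs=lambda x, p: N @ x,
                         jacobian=lambda x, p: N,
                         second_rhs_jacobian=lambda x, p: N @ N)
        x0 = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        sol = integrate(model, x0, np.array([]), (0.0, 2.0), rtol=1e-8, atol=1e-10)
        for t in (0.31, 1.07, 1.93):
            exact = np.array([1.0, t, t**2, t**3, t**4])
            assert np.allclose(sol(t), exact, rtol=1e-9, atol=1e-9)

    def test_midpoint_of_decay_within_error_bound(self, decay):
        fx, model = decay
        sol = integrate(model, fx.x0, fx.p, (0.0, 5.0), rtol=1e-8, atol=1e-12)
        i = len(sol.times) // 2
        tm = 0.5 * (sol.times[i] + sol.times[i + 1])
        assert sol(tm) == pytest.approx(np.exp(-tm), rel=1e-6)

    def test_output_times_interpolated_without_constraining_steps(self, decay):
        fx, model = decay
        ts = np.linspace(0.1, 4.9, 7)
        plain = integrate(model, fx.x0, fx.p, (0.0, 5.0), rtol=1e-8, atol=1e-12,
                          sensitivities=True)
        sol = integrate(model, fx.x0, fx.p, (0.0, 5.0), rtol=1e-8, atol=1e-12,
                        sensitivities=True, output_times=ts)
        assert np.array_equal(sol.times, plain.times)  # steps unaffected
        assert np.allclose(sol.output_states[:, 0], np.exp(-ts), rtol=1e-6)
        assert np.allclose(sol.output_sensitivities[:, 0, 0], -ts * np.exp(-ts),
                           rtol=1e-5, atol=1e-9)

    def test_out_of_range_query_raises(self, decay):
        fx, model = decay
        sol = integrate(model, fx.x0, fx.p, (0.0, 1.0), rtol=1e-6, atol=1e-9)
        with pytest.raises(ValueError):
            sol(1.5)

    def test_sensitivity_interpolation(self, decay):
        fx, model = decay
        sol = integrate(model, fx.x0, fx.p, (0.0, 2.0), rtol=1e-8, atol=1e-12,
                        sensitivities=True)
        for t in (0.37, 1.21):
            exact = -t * np.exp(-t)
            assert sol.dense_eval_sensitivities(t)[0, 0] == pytest.approx(
                exact, rel=1e-5, abs=1e-9)


class TestStatistics:
    def test_counters_are_consistent(self, mm):
        fx, model = mm
        sol = integrate(model, fx.x0, fx.p, fx.t_span, rtol=1e-6, atol=1e-12)
        s = sol.stats
        assert s.steps_accepted == len(sol.times) - 1
        assert s.n_f >= s.newton_iters
        assert s.n_jac == s.steps_accepted + s.steps_rejected
        assert np.all(np.diff(sol.times) > 0)

    def test_work_precision_monotone_on_mm(self, mm):
        fx, model = mm
        ref = _radau_reference(model, fx.x0, fx.p, (0.0, 50.0))
        precisions = []
        for rtol in (1e-4, 1e-6, 1e-8, 1e-10):
            sol = integrate(model, fx.x0, fx.p, (0.0, 50.0), rtol=rtol,
                            atol=rtol * 1e-4)
            precisions.append(max(precision_of(sol, ref), 1e-16))
        for a, b in zip(precisions, precisions[1:]):
            assert b <= 2 * a  # improves monotonically within a factor 2
        assert precisions[-1] < precisions[0] / 10


class TestPrecisionOf:
    def test_identical_solutions_give_zero(self, decay):
        fx, model = decay
        sol = integrate(model, fx.x0, fx.p, (0.0, 1.0), rtol=1e-6, atol=1e-9)
        assert precision_of(sol, sol) == 0.0

    def test_hand_pair_with_reference_exclusion(self):
        value = np.array([1.0, 1e-20])
        reference = np.array([1.001, 0.0])
        assert precision_of(value, reference) == pytest.approx(1e-3, rel=1e-2)


class TestFailureHandling:
    def test_blowup_returns_partial_solution(self):
        # finite-time singularity at t = 1
        model = compile_model(SymbolicModel.from_rates(["x"], [], ["x**2"]))
        sol = integrate(model, np.array([1.0]), np.array([]), (0.0, 2.0),
                        rtol=1e-6, atol=1e-9, max_steps=5000)
        assert not sol.success
        assert sol.t_end < 2.0
        assert isinstance(sol, Solution)

    def test_invalid_inputs_rejected(self, decay):
        fx, model = decay
        with pytest.raises(ValueError):
            integrate(model, fx.x0, fx.p, (1.0, 0.0))
        with pytest.raises(ValueError):
            integrate(model, fx.x0, fx.p, (0.0, 1.0), rtol=-1.0)
        with pytest.raises(ValueError):
            integrate(model, np.array([np.nan]), fx.p, (0.0, 1.0))
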