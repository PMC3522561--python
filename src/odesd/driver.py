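"""Integration driver: predict → Newton → error estimate → accept/reject →
sensitivities, with dense output and statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .error_control import ErrorNorm, estimate_error, initial_step_size
from .exceptions import StepFailureError, UnsupportedModelError
from .model import ODEModel, Solution, SolverStats, StepHistory, StepRecord, second_derivative
from .rules import hermite_coefficients
from .sensitivity import (
    SensitivityBlock,
    direct_sensitivity_step,
    iterative_sensitivity_step,
    sensitivity_derivatives,
)
from .stepper import build_newton_matrix, newton_solve, predict

logger = logging.getLogger("odesd")


@dataclass
class IntegratorOptions:
    """Tunable integration settings.

    rtol, atol
        Tolerances of the weighted RMS error norm (atol scalar or
        per-component).  The prescribed tolerance tau is absorbed into the
        weights, so acceptance is ||eps||_w <= 1.
    sensitivities
        Compute parameter sensitivities (staggered, after each accepted
        step).  ``s0`` supplies ∂x0/∂p when initial conditions depend on
        the parameters (array or callable ``(x0, p) -> array``); default 0.
    sensitivity_method
        "direct" (one fresh factorization per step, all columns) or
        "iterative" (reuse the state step's factorization).
    jacobian_reuse
        Feed the Jacobians evaluated at the converged state during the
        sensitivity stage into the next step's Newton matrix instead of
        re-evaluating them at the predictor.
    newton_kappa, newton_max_iter
        Simplified-Newton stopping factor (tolerance kappa * tau in the
        error norm) and iteration cap.
    sigma_min, sigma_max
        Per-attempt bounds of the step-scaling factor.
    fixed_step
        Debug mode: constant step size, controller off (order measurement).
    """

    rtol: float = 1e-6
    atol: float | np.ndarray = 1e-9
    sensitivities: bool = False
    s0: Optional[np.ndarray | Callable] = None
    sensitivity_method: str = "direct"
    jacobian_reuse: bool = False
    newton_kappa: float = 0.01
    newton_max_iter: int = 7
    newton_max_restarts: int = 2
    sigma_min: float = 0.1
    sigma_max: float = 5.0
    h0: Optional[float] = None
    h_min: Optional[float] = None
    h_max: Optional[float] = None
    fixed_step: Optional[float] = None
    max_steps: int = 500_000
    sens_in_error_norm: bool = False  # reserved; staggered default excludes them

    def __post_init__(self):
        if self.rtol <= 0 or np.any(np.asarray(self.atol) <= 0):
            raise ValueError("rtol and atol must be positive")
        if self.sensitivity_method not in ("direct", "iterative"):
            raise ValueError("sensitivity_method must be 'direct' or 'iterative'")


def integrate(
    model: ODEModel,
    x0,
    p,
    t_span,
    options: Optional[IntegratorOptions] = None,
    output_times=None,
    **overrides,
) -> Solution:
    """Integrate the model over ``t_span`` and return a :class:`Solution`.

    Keyword overrides are merged into ``options`` (e.g.
    ``integrate(m, x0, p, (0, 10), rtol=1e-8, sensitivities=True)``).
    ``output_times`` never constrain step selection; the requested states
    (and sensitivities) are interpolated from the dense output and stored
    on the solution.
    """
    opts = options or IntegratorOptions()
    if overrides:
        opts = replace(opts, **overrides)
    t0, t_end = float(t_span[0]), float(t_span[1])
    if not t_end > t0:
        raise ValueError("t_span must be increasing")
    span = t_end - t0

    x0 = np.asarray(x0, dtype=float).copy()
    p = np.asarray(p, dtype=float).copy()
    if x0.shape != (model.n_states,):
        raise ValueError(f"x0 must have length {model.n_states}")
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")

    norm = ErrorNorm(opts.atol, opts.rtol, n=model.n_states)
    stats = SolverStats()
    step_log: list[StepRecord] = []

    f0 = np.asarray(model.rhs(x0, p), dtype=float)
    stats.n_f += 1
    xdd0 = second_derivative(model, x0, p, f=f0)
    history = StepHistory(t=t0, h=0.0, x=x0, xdot=f0, xddot=xdd0)

    sens_block: Optional[SensitivityBlock] = None
    if opts.sensitivities:
        if not model.has_param_derivatives:
            raise UnsupportedModelError(
                "sensitivities requested but the model has no analytic "
                "parameter-derivative evaluators"
            )
        S0 = opts.s0(x0, p) if callable(opts.s0) else opts.s0
        S0 = (np.zeros((model.n_states, model.n_params)) if S0 is None
              else np.asarray(S0, dtype=float).copy())
        Sdot0, Sddot0 = sensitivity_derivatives(model, x0, p, S0)
        sens_block = SensitivityBlock(t=t0, S=S0, Sdot=Sdot0, Sddot=Sddot0)

    h_max = opts.h_max if opts.h_max is not None else span
    h_floor = opts.h_min if opts.h_min is not None else 1e-13 * span
    if opts.fixed_step is not None:
        h = float(opts.fixed_step)
    else:
        h = opts.h0 if opts.h0 is not None else initial_step_size(
            x0, f0, xdd0, norm, (t0, t_end), h_max=h_max)
        h = min(h, h_max, span)

    times = [t0]
    states = [x0.copy()]
    sens_out = [sens_block.S.copy()] if sens_block is not None else None
    dense = []
    reuse_J = None
    success = True
    message = "reached t_end"

    t = t0
    while t < t_end:
        if stats.steps_attempted >= opts.max_steps:
            success, message = False, f"max_steps={opts.max_steps} exceeded at t={t:g}"
            break
        if opts.fixed_step is None:
            if t + h >= t_end:
                h = t_end - t
            elif t + 1.4 * h >= t_end:
                h = 0.5 * (t_end - t)
        else:
            h = min(opts.fixed_step, t_end - t)
        if h < h_floor and opts.fixed_step is None:
            success, message = False, f"step size underflow (h={h:.3e}) at t={t:g}"
            break

        x_pred = predict(history, h)
        try:
            ws = build_newton_matrix(model, x_pred, p, h,
                                     stats=stats, jacobians=reuse_J)
            x_new, f_new, xdd_new, ws = newton_solve(
                ws, model, history, p, h, x_pred, norm,
                newton_tol=opts.newton_kappa, max_iter=opts.newton_max_iter,
                stats=stats, max_restarts=opts.newton_max_restarts)
        except StepFailureError as exc:
            stats.steps_rejected += 1
            step_log.append(StepRecord(t, h, np.inf, False, 0, True))
            logger.debug("t=%g h=%g newton failure: %s", t, h, exc)
            reuse_J = None
            h *= 0.5
            if opts.fixed_step is not None:
                success, message = False, f"Newton failure in fixed-step mode at t={t:g}"
                break
            continue

        est = estimate_error(ws, history, h, x_new, f_new, xdd_new, norm,
                             x_pred=x_pred, sigma_min=opts.sigma_min,
                             sigma_max=opts.sigma_max, stats=stats)
        accepted = est.accepted or opts.fixed_step is not None
        step_log.append(StepRecord(t, h, est.eps_norm, accepted,
                                   ws.n_iter, est.fallback))
        logger.debug("t=%g h=%g eps=%.3e iters=%d %s", t, h, est.eps_norm,
                     ws.n_iter, "accept" if accepted else "reject")
        if not accepted:
            stats.steps_rejected += 1
            reuse_J = None
            h = max(est.new_h, h_floor)
            continue

        # ---- accepted ----
        stats.steps_accepted += 1
        coeffs_x = hermite_coefficients(h, history.x, history.xdot, history.xddot,
                                        f_new, xdd_new)
        coeffs_S = None
        reuse_J = None
        if sens_block is not None:
            prev_block = sens_block
            if opts.sensitivity_method == "direct":
                sens_block, J_new, JJ_new = direct_sensitivity_step(
                    model, x_new, p, h, prev_block, stats=stats)
            else:
                sens_block, J_new, JJ_new = iterative_sensitivity_step(
                    ws, model, x_new, p, h, prev_block,
                    newton_tol=opts.newton_kappa, stats=stats)
            if opts.jacobian_reuse:
                reuse_J = (J_new, JJ_new)
            coeffs_S = hermite_coefficients(h, prev_block.S, prev_block.Sdot,
                                            prev_block.Sddot, sens_block.Sdot,
                                            sens_block.Sddot)
            sens_out.append(sens_block.S.copy())

        dense.append((t, h, coeffs_x, coeffs_S))
        history = StepHistory(
            t=t + h, h=h, x=x_new, xdot=f_new, xddot=xdd_new,
            h_prev=h, x_prev=history.x, xdot_prev=history.xdot,
            xddot_prev=history.xddot, has_prev=True)
        t = t + h
        times.append(t)
        states.append(x_new)
        if opts.fixed_step is None:
            # Newton effort limits growth: a step that needed restarts or
            # nearly the full iteration budget must not be enlarged, or the
            # next attempt burns a factorization on a convergence failure.
            if ws.n_restarts > 0 or ws.n_iter >= opts.newton_max_iter - 1:
                growth_cap = 1.0
            elif ws.n_iter >= opts.newton_max_iter - 3:
                growth_cap = 1.2
            else:
                growth_cap = opts.sigma_max
            h = float(np.clip(min(est.new_h, growth_cap * h), h_floor, h_max))

    sol = Solution(
        times=np.array(times),
        states=np.array(states),
        sensitivities=np.array(sens_out) if sens_out is not None else None,
        stats=stats,
        success=success,
        message=message,
        step_log=step_log,
        _dense=dense,
    )
    if output_times is not None and success:
        ts = np.asarray(output_times, dtype=float)
        sol.output_times = ts
        sol.output_states = sol.interpolate(ts)
        if sol.sensitivities is not None:
            sol.output_sensitivities = np.array(
                [sol.dense_eval_sensitivities(t) for t in ts])
    return sol


def precision_of(solution, reference) -> float:
    """Maximum relative final-state error against a reference solution.

    Components whose reference value is not larger than machine precision
    are excluded.  ``reference`` may be a :class:`Solution` or the final
    reference state vector.
    """
    x = np.asarray(solution.final_state if isinstance(solution, Solution) else solution,
                   dtype=float)
    ref = np.asarray(reference.final_state if isinstance(reference, Solution) else reference,
                     dtype=float)
    mask = np.abs(ref) > np.finfo(float).eps
    if not mask.any():
        return 0.0
    return float(np.max(np.abs(x[mask] - ref[mask]) / np.abs(ref[mask])))
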