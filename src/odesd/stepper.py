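"""One integration step: explicit prediction and simplified Newton solve.

The implicit g4 relation is solved with a simplified Newton method: the
Jacobians J_f and J_Jf are evaluated once per attempted step, at the
explicit predictor, and the iteration matrix

    M(t+h) = h/2 J_f - h^2/12 J_Jf - I

is assembled and LU-factorized once.  The same factorization is later
reused for the error estimate (one extra back-substitution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import LinAlgWarning, lu_factor, lu_solve

from .exceptions import (
    ModelEvaluationError,
    NewtonDivergenceError,
    NewtonMatrixSingularError,
)
from .model import ODEModel, SolverStats, StepHistory, second_derivative
from .rules import predictor_weights


@dataclass
class NewtonWorkspace:
    """Iteration matrix, its factorization, and the frozen Jacobians."""

    M: np.ndarray
    lu: tuple
    J_pred: np.ndarray
    JJ_pred: np.ndarray
    h: float
    n_iter: int = 0
    n_restarts: int = 0
    converged: bool = False
    last_correction_norm: float = field(default=np.nan)

    def solve(self, b):
        """Back-substitute with the stored factorization (no refactorization)."""
        return lu_solve(self.lu, b)


def predict(history: StepHistory, h: float) -> np.ndarray:
    """Explicit initial guess for x(t+h).

    With history: the degree-4 extrapolant through x, xdot, xddot at t and
    xdot, xddot at t - h_prev.  On the first step: second-order Taylor.
    """
    if not history.has_prev:
        return history.x + h * history.xdot + 0.5 * h * h * history.xddot
    w = predictor_weights(h, history.h_prev)
    return w.apply(history.x, history.xdot, history.xddot,
                   history.xdot_prev, history.xddot_prev)


def build_newton_matrix(
    model: ODEModel,
    x_pred: np.ndarray,
    p,
    h: float,
    stats: Optional[SolverStats] = None,
    jacobians: Optional[tuple] = None,
) -> NewtonWorkspace:
    """Assemble and factorize M(t+h) at the predictor.

    ``jacobians=(J, JJ)`` injects previously evaluated Jacobians (the
    sensitivity stage's fresh pair), implementing the reuse mode; otherwise
    both are evaluated at ``x_pred``.
    """
    n = model.n_states
    if jacobians is not None:
        J, JJ = jacobians
    else:
        J = np.asarray(model.jacobian(x_pred, p), dtype=float)
        JJ = np.asarray(model.second_rhs_jacobian(x_pred, p), dtype=float)
        if stats is not None:
            stats.n_jac += 1
            stats.n_jjf += 1
    M = (h / 2.0) * J - (h * h / 12.0) * JJ - np.eye(n)
    if not np.all(np.isfinite(M)):
        raise NewtonMatrixSingularError("Newton matrix contains non-finite entries")
    try:
        with warnings.catch_warnings():
            # an exactly singular M warns before we can inspect U's diagonal
            warnings.simplefilter("ignore", LinAlgWarning)
            lu = lu_factor(M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises rarely
        raise NewtonMatrixSingularError(str(exc)) from exc
    udiag = np.abs(np.diag(lu[0]))
    scale = max(np.max(np.abs(M)), 1.0)
    if udiag.min() <= n * np.finfo(float).eps * scale:
        raise NewtonMatrixSingularError(
            f"Newton matrix is numerically singular (|U_ii| min {udiag.min():.3e})"
        )
    if stats is not None:
        stats.n_factorizations += 1
    return NewtonWorkspace(M=M, lu=lu, J_pred=J, JJ_pred=JJ, h=h)


def _newton_iterate(ws, model, p, h, g4c, x_start, x_scale, norm, newton_tol,
                    max_iter, stats):
    """One simplified-Newton sweep with a frozen factorization.

    Returns ``(status, x)`` with status "converged", "slow" (no divergence,
    budget exhausted) or "diverging".
    """
    x = np.array(x_start, dtype=float)
    prev_norm = None
    n_bad = 0
    for _ in range(max_iter):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                f = np.asarray(model.rhs(x, p), dtype=float)
                stats.n_f += 1
                xdd = second_derivative(model, x, p, f=f)
        except (ModelEvaluationError, OverflowError):
            return "diverging", x
        resid = g4c + (h / 2.0) * f - (h * h / 12.0) * xdd - x
        dx = ws.solve(resid)
        x = x - dx
        ws.n_iter += 1
        stats.newton_iters += 1
        if not np.all(np.isfinite(x)):
            return "diverging", x
        nrm = norm(dx, np.maximum(np.abs(x), x_scale))
        ws.last_correction_norm = nrm
        if nrm <= 0.03 * newton_tol:
            return "converged", x
        if prev_norm is not None and prev_norm > 0:
            rate = nrm / prev_norm
            if rate >= 0.9:
                n_bad += 1
                if n_bad >= 2:
                    return "diverging", x
            elif rate / (1.0 - rate) * nrm <= newton_tol:
                return "converged", x
        prev_norm = nrm
    return "slow", x


def newton_solve(
    ws: NewtonWorkspace,
    model: ODEModel,
    history: StepHistory,
    p,
    h: float,
    x_pred: np.ndarray,
    norm,
    newton_tol: float = 0.01,
    max_iter: int = 7,
    stats: Optional[SolverStats] = None,
    max_restarts: int = 0,
):
    """Solve the implicit g4 relation by simplified Newton iteration.

    Convergence is declared from the correction norm with an estimated
    linear rate rho: stop once rho/(1-rho) * ||dx|| <= newton_tol (or the
    correction itself is far below tolerance).

    With ``max_restarts > 0`` (driver mode) a sweep that stalls or diverges
    with a finite iterate is retried at the same h with the iteration matrix
    rebuilt at that iterate — the stiff-direction Jacobians there are much
    closer to the solution's than the extrapolated predictor's.  A restart
    counts as an extra factorization and Jacobian evaluation; the driver
    treats restarted steps as hard and freezes step growth.  Exhausted
    restarts (or non-finite iterates) raise :class:`NewtonDivergenceError`
    and the driver halves h.

    Returns ``(x_new, f_new, xddot_new, ws)`` with the derivatives evaluated
    at the converged state and the (possibly rebuilt) workspace whose
    factorization the error estimator reuses.
    """
    stats = stats if stats is not None else SolverStats()
    g4c = history.x + (h / 2.0) * history.xdot + (h * h / 12.0) * history.xddot
    x_scale = np.abs(history.x)
    x = np.array(x_pred, dtype=float)
    for restart in range(max_restarts + 1):
        status, x = _newton_iterate(ws, model, p, h, g4c, x, x_scale, norm,
                                    newton_tol, max_iter, stats)
        if status == "converged":
            break
        if restart == max_restarts or not np.all(np.isfinite(x)):
            raise NewtonDivergenceError(
                f"Newton {status} after {ws.n_iter} iterations "
                f"(last correction norm {ws.last_correction_norm:.3e})"
            )
        n_iter_sofar = ws.n_iter
        ws = build_newton_matrix(model, x, p, h, stats=stats)
        ws.n_iter = n_iter_sofar
        ws.n_restarts = restart + 1
    else:  # pragma: no cover - loop always breaks or raises
        raise NewtonDivergenceError("Newton failed")
    ws.converged = True
    f = np.asarray(model.rhs(x, p), dtype=float)
    stats.n_f += 1
    xdd = second_derivative(model, x, p, f=f)
    return x, f, xdd, ws
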