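"""Staggered computation of local parameter sensitivities.

The sensitivities s_k = ∂x/∂p_k obey the linear ODE

    sdot_k  = J_f s_k + ∂f/∂p_k
    sddot_k = J_Jf s_k + ∂xddot/∂p_k

Because the states do not depend on the sensitivities, each accepted state
step is followed by a separate sensitivity step using the same implicit
rule.  Applying the rule to the (linear) sensitivity equations and isolating
the unknown s_k(t+h) gives one linear system per parameter,

    [I - h/2 J_f(t+h) + h^2/12 J_Jf(t+h)] s_k(t+h) = r_k,

whose matrix is the same for every k: one fresh factorization per accepted
step serves all n_p columns (the default, direct mode).  The Jacobians are
re-evaluated at the *converged* state here — unlike the simplified-Newton
Jacobians, which were frozen at the predictor — and can optionally be reused
to build the next step's Newton matrix.  An iterative mode that instead
reuses the state step's factorization is provided for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .exceptions import NewtonMatrixSingularError, UnsupportedModelError
from .model import ODEModel, SolverStats
from .stepper import NewtonWorkspace


@dataclass
class SensitivityBlock:
    """Sensitivity matrix S (n_x x n_p, column k = s_k) with time derivatives."""

    t: float
    S: np.ndarray
    Sdot: np.ndarray
    Sddot: np.ndarray


def _require_param_derivatives(model: ODEModel):
    if not model.has_param_derivatives:
        raise UnsupportedModelError(
            "model provides no analytic parameter-derivative evaluators "
            "(rhs_param_jac / second_rhs_param_jac); sensitivity analysis "
            "refuses to fall back to finite differences"
        )


def sensitivity_derivatives(model: ODEModel, x, p, S):
    """(Sdot, Sddot) at state x for sensitivity matrix S."""
    _require_param_derivatives(model)
    S = np.asarray(S, dtype=float)
    if S.shape != (model.n_states, model.n_params):
        raise ValueError(f"S must have shape ({model.n_states}, {model.n_params})")
    J = np.asarray(model.jacobian(x, p), dtype=float)
    JJ = np.asarray(model.second_rhs_jacobian(x, p), dtype=float)
    dfdp = np.asarray(model.rhs_param_jac(x, p), dtype=float)
    dxdddp = np.asarray(model.second_rhs_param_jac(x, p), dtype=float)
    return J @ S + dfdp, JJ @ S + dxdddp


def _assemble_rhs(prev: SensitivityBlock, h: float, dfdp_new, dxdddp_new):
    return (prev.S
            + (h / 2.0) * (prev.Sdot + dfdp_new)
            + (h * h / 12.0) * (prev.Sddot - dxdddp_new))


def direct_sensitivity_step(
    model: ODEModel,
    x_new,
    p,
    h: float,
    prev: SensitivityBlock,
    stats: Optional[SolverStats] = None,
):
    """Advance all sensitivity columns with one fresh factorization.

    Returns ``(block, J_new, JJ_new)``; the freshly evaluated Jacobians are
    exposed so the driver can reuse them in the next step's Newton matrix.
    """
    _require_param_derivatives(model)
    x_new = np.asarray(x_new, dtype=float)
    n = model.n_states
    J = np.asarray(model.jacobian(x_new, p), dtype=float)
    JJ = np.asarray(model.second_rhs_jacobian(x_new, p), dtype=float)
    dfdp = np.asarray(model.rhs_param_jac(x_new, p), dtype=float)
    dxdddp = np.asarray(model.second_rhs_param_jac(x_new, p), dtype=float)
    if stats is not None:
        stats.n_jac += 1
        stats.n_jjf += 1
    A = np.eye(n) - (h / 2.0) * J + (h * h / 12.0) * JJ
    try:
        lu = lu_factor(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NewtonMatrixSingularError(str(exc)) from exc
    udiag = np.abs(np.diag(lu[0]))
    if udiag.min() <= n * np.finfo(float).eps * max(np.max(np.abs(A)), 1.0):
        raise NewtonMatrixSingularError("sensitivity matrix is numerically singular")
    if stats is not None:
        stats.n_sens_factorizations += 1
    B = _assemble_rhs(prev, h, dfdp, dxdddp)
    S_new = lu_solve(lu, B)  # all n_p columns with the single factorization
    block = SensitivityBlock(
        t=prev.t + h,
        S=S_new,
        Sdot=J @ S_new + dfdp,
        Sddot=JJ @ S_new + dxdddp,
    )
    return block, J, JJ


def iterative_sensitivity_step(
    ws: NewtonWorkspace,
    model: ODEModel,
    x_new,
    p,
    h: float,
    prev: SensitivityBlock,
    newton_tol: float = 0.01,
    max_iter: int = 10,
    stats: Optional[SolverStats] = None,
):
    """Advance the sensitivities by Newton iteration on the implicit rule.

    Reuses the state step's factorized iteration matrix (frozen at the
    predictor) instead of factorizing anew; the Jacobians entering the
    residual are still evaluated at the converged state, so the fixed point
    coincides with the direct solve.  Falls back to the direct method if
    the iteration does not converge.  Returns ``(block, J_new, JJ_new)``.
    """
    _require_param_derivatives(model)
    x_new = np.asarray(x_new, dtype=float)
    J = np.asarray(model.jacobian(x_new, p), dtype=float)
    JJ = np.asarray(model.second_rhs_jacobian(x_new, p), dtype=float)
    dfdp = np.asarray(model.rhs_param_jac(x_new, p), dtype=float)
    dxdddp = np.asarray(model.second_rhs_param_jac(x_new, p), dtype=float)
    if stats is not None:
        stats.n_jac += 1
        stats.n_jjf += 1
    C = _assemble_rhs(prev, h, dfdp, dxdddp)
    S = prev.S + h * prev.Sdot  # explicit warm start
    scale = np.max(np.abs(S)) + np.max(np.abs(C)) + 1.0
    converged = False
    for _ in range(max_iter):
        resid = C + (h / 2.0) * (J @ S) - (h * h / 12.0) * (JJ @ S) - S
        dS = ws.solve(resid)
        S = S - dS
        if np.max(np.abs(dS)) <= newton_tol * 1e-3 * scale:
            converged = True
            break
    if not converged or not np.all(np.isfinite(S)):
        return direct_sensitivity_step(model, x_new, p, h, prev, stats=stats)
    block = SensitivityBlock(
        t=prev.t + h,
        S=S,
        Sdot=J @ S + dfdp,
        Sddot=JJ @ S + dxdddp,
    )
    return block, J, JJ
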