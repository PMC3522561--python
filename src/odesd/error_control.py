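"""Local error estimation and step-size control.

The local error of a converged g4 step is estimated by taking a single
Newton step toward the degree-5 reference solution, reusing the already
factorized iteration matrix:

    eps = M(t+h)^{-1} (g5(t+h) - x(t+h))

so the estimate costs one back-substitution and no new factorization.
Acceptance and step scaling use a weighted RMS norm in which the tolerance
is absorbed into the weights: a step is accepted when ||eps||_w <= 1, and
the next step is scaled by sigma = (1/(2 ||eps||_w))^{1/5}, targeting half
the tolerance so that roughly half the estimates do not overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import IllConditionedRuleError
from .model import SolverStats, StepHistory
from .rules import g5_weights
from .stepper import NewtonWorkspace


class ErrorNorm:
    """Weighted RMS norm: ||v||_w = sqrt(mean((v_i / (atol_i + rtol |xref_i|))^2))."""

    def __init__(self, atol, rtol, n: Optional[int] = None):
        atol = np.asarray(atol, dtype=float)
        if np.any(atol <= 0) or rtol <= 0:
            raise ValueError("atol and rtol must be positive")
        if n is not None and atol.ndim == 0:
            atol = np.full(n, float(atol))
        self.atol = atol
        self.rtol = float(rtol)

    def weights(self, x_ref):
        return self.atol + self.rtol * np.abs(np.asarray(x_ref, dtype=float))

    def __call__(self, v, x_ref):
        w = np.asarray(v, dtype=float) / self.weights(x_ref)
        return float(np.sqrt(np.mean(w * w)))


def error_norm(eps_vector, x_ref, atol, rtol) -> float:
    """Functional form of the weighted RMS norm (threshold 1 for acceptance)."""
    return ErrorNorm(atol, rtol)(eps_vector, x_ref)


@dataclass
class ErrorEstimate:
    eps_vector: np.ndarray
    eps_norm: float
    accepted: bool
    sigma: float
    new_h: float
    fallback: bool = False


def step_scaling(eps_norm: float, tau: float = 1.0,
                 sigma_min: float = 0.1, sigma_max: float = 5.0) -> float:
    """Fifth-root controller targeting tau/2 for the next step."""
    if eps_norm < 0 or tau <= 0:
        raise ValueError("eps_norm must be >= 0 and tau > 0")
    if eps_norm == 0.0:
        return sigma_max
    return float(np.clip((tau / (2.0 * eps_norm)) ** 0.2, sigma_min, sigma_max))


def next_step_size(eps_norm: float, tau: float, h: float,
                   sigma_min: float = 0.1, sigma_max: float = 5.0) -> float:
    """Proposed next step size sigma * h with sigma clipped to its limits."""
    return step_scaling(eps_norm, tau, sigma_min, sigma_max) * h


def estimate_error(
    ws: NewtonWorkspace,
    history: StepHistory,
    h: float,
    x_new,
    xdot_new,
    xddot_new,
    norm: ErrorNorm,
    x_pred=None,
    tau: float = 1.0,
    sigma_min: float = 0.1,
    sigma_max: float = 5.0,
    stats: Optional[SolverStats] = None,
) -> ErrorEstimate:
    """Local error estimate for a converged step.

    With history available the g5 reference is assembled from its weights
    and the converged xdot(t+h), xddot(t+h); the single back-substitution
    reuses the workspace factorization (the factorization counter must not
    move here).  Without history (first step) or for extreme step ratios
    the estimate falls back to the predictor-corrector difference, which
    overestimates the degree-4 error and is flagged as lower quality.
    """
    x_new = np.asarray(x_new, dtype=float)
    fallback = not history.has_prev
    w5 = None
    if not fallback:
        try:
            w5 = g5_weights(h, history.h_prev)
        except IllConditionedRuleError:
            fallback = True
    if fallback:
        if x_pred is None:
            raise ValueError("fallback error estimate requires the predictor state")
        eps = x_new - np.asarray(x_pred, dtype=float)
    else:
        g5v = w5.apply(history.x, history.xdot, history.xddot,
                       xdot_new, xddot_new, x_prev=history.x_prev)
        eps = ws.solve(g5v - x_new)
    x_ref = np.maximum(np.abs(x_new), np.abs(history.x))
    eps_norm = norm(eps, x_ref)
    sigma = step_scaling(eps_norm, tau, sigma_min, sigma_max)
    return ErrorEstimate(
        eps_vector=eps,
        eps_norm=eps_norm,
        accepted=bool(eps_norm <= tau),
        sigma=sigma,
        new_h=sigma * h,
        fallback=fallback,
    )


def initial_step_size(x0, f0, xddot0, norm: ErrorNorm, t_span,
                      tau: float = 1.0, h_max: Optional[float] = None) -> float:
    """Heuristic first step from the scales of x, f and xddot.

    h0 ~ 0.01 ||x0||_w / ||f0||_w, additionally capped by the step at which
    the leading h^5/720 error term (with xddot as curvature proxy) would
    reach the tolerance.  The first error estimate validates the choice and
    the controller corrects it within a few attempts.
    """
    span = abs(t_span[1] - t_span[0])
    tiny = 1e-12
    candidates = [0.1 * span]
    d0 = norm(x0, x0)
    d1 = norm(f0, x0)
    d2 = norm(xddot0, x0)
    if d1 > tiny:
        candidates.append(0.01 * max(d0, 1.0) / d1)
    if d2 > tiny:
        candidates.append((720.0 * tau / d2) ** 0.2)
    h0 = min(candidates)
    if h_max is not None:
        h0 = min(h0, h_max)
    return max(h0, tiny * span if span > 0 else tiny)
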