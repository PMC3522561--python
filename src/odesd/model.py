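"""Model contract and shared state containers.

An :class:`ODEModel` bundles the evaluators any integrable system must
provide: the right-hand side f(x, p), its state Jacobian J_f, the Jacobian
J_Jf of the second time derivative xddot = J_f f, and (optionally, for
sensitivity analysis) the parameter derivatives ∂f/∂p and ∂xddot/∂p.  Models
are autonomous: time enters only through the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .exceptions import ModelEvaluationError, ModelValidationError

Evaluator = Callable[..., np.ndarray]


@dataclass
class ODEModel:
    """Bundle of evaluators, dimensions and sparsity for one ODE system.

    All evaluators take ``(x, p)`` with 1-d arrays and return arrays of the
    declared shapes.  ``second_rhs`` is the optional fused closed-form
    evaluator of xddot (symbolic path); it may accept a precomputed ``f`` as
    third argument so f components are reused rather than re-expanded.
    """

    n_states: int
    n_params: int
    rhs: Evaluator
    jacobian: Evaluator
    second_rhs_jacobian: Optional[Evaluator] = None
    second_rhs: Optional[Evaluator] = None
    rhs_param_jac: Optional[Evaluator] = None
    second_rhs_param_jac: Optional[Evaluator] = None
    jac_sparsity: Optional[np.ndarray] = None
    species_names: Optional[Sequence[str]] = None
    param_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        if self.n_states <= 0:
            raise ValueError("n_states must be positive")
        if self.n_params < 0:
            raise ValueError("n_params must be non-negative")
        if self.jac_sparsity is not None:
            self.jac_sparsity = np.asarray(self.jac_sparsity, dtype=bool)
            if self.jac_sparsity.shape != (self.n_states, self.n_states):
                raise ValueError("jac_sparsity must be n_states x n_states")

    @property
    def has_param_derivatives(self) -> bool:
        return self.rhs_param_jac is not None and self.second_rhs_param_jac is not None


def second_derivative(model: ODEModel, x, p, f=None) -> np.ndarray:
    """Second time derivative xddot = J_f(x) f(x).

    Uses the model's fused evaluator when available (the symbolic compiler
    emits one), otherwise falls back to the explicit matrix–vector product.
    A precomputed ``f`` is forwarded so the rate vector is not evaluated
    twice inside Newton iterations.
    """
    x = np.asarray(x, dtype=float)
    if model.second_rhs is not None:
        try:
            xdd = np.asarray(model.second_rhs(x, p, f), dtype=float)
        except TypeError:  # fused evaluator without the f shortcut
            xdd = np.asarray(model.second_rhs(x, p), dtype=float)
    else:
        if f is None:
            f = model.rhs(x, p)
        xdd = np.asarray(model.jacobian(x, p), dtype=float) @ np.asarray(f, dtype=float)
    bad = ~np.isfinite(xdd)
    if bad.any():
        raise ModelEvaluationError("second derivative", int(np.flatnonzero(bad)[0]))
    return xdd


@dataclass
class StepHistory:
    """The integrator's memory at an accepted node.

    Holds the current node (t, x, xdot, xddot), the current and previous
    accepted step sizes, and the previous node's state and derivatives (the
    explicit predictor interpolates xdot/xddot at t - h_prev; the g5 error
    reference interpolates x there).  ``has_prev`` is False before the second
    step.
    """

    t: float
    h: float
    x: np.ndarray
    xdot: np.ndarray
    xddot: np.ndarray
    h_prev: float = 0.0
    x_prev: Optional[np.ndarray] = None
    xdot_prev: Optional[np.ndarray] = None
    xddot_prev: Optional[np.ndarray] = None
    has_prev: bool = False


@dataclass
class SolverStats:
    """Work counters accumulated over one integration."""

    steps_accepted: int = 0
    steps_rejected: int = 0
    n_f: int = 0
    n_jac: int = 0
    n_jjf: int = 0
    newton_iters: int = 0
    n_factorizations: int = 0
    n_sens_factorizations: int = 0

    @property
    def steps_attempted(self) -> int:
        return self.steps_accepted + self.steps_rejected

    def as_dict(self) -> dict:
        return {
            "steps_accepted": self.steps_accepted,
            "steps_rejected": self.steps_rejected,
            "n_f": self.n_f,
            "n_jac": self.n_jac,
            "n_jjf": self.n_jjf,
            "newton_iters": self.newton_iters,
            "n_factorizations": self.n_factorizations,
            "n_sens_factorizations": self.n_sens_factorizations,
        }


@dataclass
class StepRecord:
    """Per-attempt trace entry (supports work–precision reproduction)."""

    t: float
    h: float
    eps_norm: float
    accepted: bool
    newton_iters: int
    fallback_estimate: bool


@dataclass
class Solution:
    """Accepted time grid, trajectory, sensitivities and statistics."""

    times: np.ndarray
    states: np.ndarray
    sensitivities: Optional[np.ndarray]  # (n_t, n_x, n_p) or None
    stats: SolverStats
    success: bool = True
    message: str = ""
    step_log: list = field(default_factory=list)
    # dense output: per accepted step (t0, h, coeffs_x, coeffs_S or None)
    _dense: list = field(default_factory=list)
    # populated when integrate() was given output_times
    output_times: Optional[np.ndarray] = None
    output_states: Optional[np.ndarray] = None
    output_sensitivities: Optional[np.ndarray] = None

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def _locate(self, t: float) -> int:
        t0, t1 = self.times[0], self.times[-1]
        lo, hi = (t0, t1) if t1 >= t0 else (t1, t0)
        if not (lo <= t <= hi):
            raise ValueError(f"t={t!r} outside the integrated range [{t0}, {t1}]")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return min(max(idx, 0), len(self._dense) - 1)

    def dense_eval(self, t: float) -> np.ndarray:
        """Interpolated state at t; grid nodes reproduce stored states exactly."""
        from .rules import hermite_eval

        hit = np.flatnonzero(self.times == t)
        if hit.size:
            return self.states[hit[0]].copy()
        idx = self._locate(t)
        t0, h, coeffs_x, _ = self._dense[idx]
        return hermite_eval(coeffs_x, (t - t0) / h)

    __call__ = dense_eval

    def dense_eval_sensitivities(self, t: float) -> np.ndarray:
        from .rules import hermite_eval

        if self.sensitivities is None:
            raise ValueError("solution carries no sensitivities")
        hit = np.flatnonzero(self.times == t)
        if hit.size:
            return self.sensitivities[hit[0]].copy()
        idx = self._locate(t)
        t0, h, _, coeffs_S = self._dense[idx]
        return hermite_eval(coeffs_S, (t - t0) / h)

    def interpolate(self, ts) -> np.ndarray:
        return np.array([self.dense_eval(t) for t in np.atleast_1d(np.asarray(ts, float))])


@dataclass
class ValidationReport:
    """Finite-difference consistency report from :func:`validate_model`."""

    discrepancies: dict
    worst_entries: dict
    sparsity_violations: list
    fd_step: float

    @property
    def max_discrepancy(self) -> float:
        return max(self.discrepancies.values(), default=0.0)

    def __str__(self):
        lines = [f"model validation (central differences, fd_step={self.fd_step:g}):"]
        for name, disc in self.discrepancies.items():
            lines.append(f"  {name}: max relative discrepancy {disc:.3e} at entry {self.worst_entries[name]}")
        if self.sparsity_violations:
            lines.append(f"  sparsity violations at {self.sparsity_violations}")
        return "\n".join(lines)


def _fd_jacobian(fun, x, fd_step):
    x = np.asarray(x, dtype=float)
    cols = []
    for j in range(x.size):
        delta = fd_step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += delta
        xm[j] -= delta
        cols.append((np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2.0 * delta))
    return np.column_stack(cols)


def validate_model(
    model: ODEModel,
    x0,
    p,
    fd_step: float = 1e-6,
    threshold: Optional[float] = None,
    rng=None,
) -> ValidationReport:
    """Check the analytic derivative evaluators against central differences.

    Compares J_f against differences of f, J_Jf against differences of
    xddot = J_f f, and the parameter-derivative evaluators against
    differences over p.  Entries of J_f that are non-zero outside the
    declared sparsity pattern (probed at x0 and a few random positive
    perturbations) are flagged.

    If ``threshold`` is given, a discrepancy above it raises
    :class:`ModelValidationError` naming the worst entry.
    """
    x0 = np.asarray(x0, dtype=float)
    p = np.asarray(p, dtype=float)
    discrepancies, worst = {}, {}

    def compare(name, analytic, fd):
        diff = np.abs(analytic - fd)
        scale = max(np.max(np.abs(analytic)), 1.0)
        idx = np.unravel_index(int(np.argmax(diff)), diff.shape)
        discrepancies[name] = float(diff[idx] / scale)
        worst[name] = tuple(int(i) for i in idx)

    compare("jacobian", np.asarray(model.jacobian(x0, p), float),
            _fd_jacobian(lambda x: model.rhs(x, p), x0, fd_step))
    if model.second_rhs_jacobian is not None:
        compare("second_rhs_jacobian", np.asarray(model.second_rhs_jacobian(x0, p), float),
                _fd_jacobian(lambda x: second_derivative(model, x, p), x0, fd_step))
    if model.rhs_param_jac is not None:
        compare("rhs_param_jac", np.asarray(model.rhs_param_jac(x0, p), float),
                _fd_jacobian(lambda q: model.rhs(x0, q), p, fd_step))
    if model.second_rhs_param_jac is not None:
        compare("second_rhs_param_jac", np.asarray(model.second_rhs_param_jac(x0, p), float),
                _fd_jacobian(lambda q: second_derivative(model, x0, q), p, fd_step))

    violations = []
    if model.jac_sparsity is not None:
        rng = np.random.default_rng(rng)
        pattern = model.jac_sparsity
        for _ in range(5):
            xt = np.abs(x0) * rng.uniform(0.5, 1.5, size=x0.shape) + rng.uniform(0.01, 0.1, size=x0.shape)
            J = np.asarray(model.jacobian(xt, p), float)
            mask = (np.abs(J) > 1e-12 * max(1.0, np.max(np.abs(J)))) & ~pattern
            violations.extend((int(i), int(j)) for i, j in zip(*np.nonzero(mask)))
        violations = sorted(set(violations))

    report = ValidationReport(discrepancies, worst, violations, fd_step)
    if threshold is not None and report.max_discrepancy > threshold:
        name = max(discrepancies, key=discrepancies.get)
        raise ModelValidationError(
            f"{name} disagrees with finite differences: relative discrepancy "
            f"{discrepancies[name]:.3e} > {threshold:g} at entry {worst[name]}"
        )
    return report
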