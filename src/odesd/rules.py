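"""Interpolation rules of the second-derivative integrator.

The implicit step is defined by the degree-4 polynomial ``g4`` that matches
the state and its first and second time derivatives at both ends of a step::

    x(t+h) = x(t) + h/2 [xdot(t) + xdot(t+h)] + h^2/12 [xddot(t) - xddot(t+h)]

The error reference is the degree-5 polynomial ``g5`` through the same nodes
plus the previously accepted state ``x(t - h_prev)``.  All weights are derived
generically by solving the Hermite–Birkhoff interpolation conditions at unit
scale ``s = (t' - t)/h`` (derivative nodes therefore carry their h, h^2
scaling inside the returned weights), which keeps the solve well conditioned
for moderate step ratios and makes the construction testable through
polynomial-exactness properties.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .exceptions import IllConditionedRuleError

#: admissible range for h/h_prev before g5 is declared ill-conditioned
STEP_RATIO_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class RuleWeights:
    """Weights w such that g(t+h) = sum_i w_i * node_i.

    ``xdot``/``xddot`` weights multiply the *raw* derivative nodes, i.e. the
    h and h^2 factors are folded into the weight.  ``x_prev`` is zero for the
    one-step g4 rule.
    """

    degree: int
    h: float
    h_prev: float | None
    x_prev: float
    x: float
    xdot: float
    xddot: float
    xdot_new: float
    xddot_new: float

    @property
    def step_ratio(self) -> float | None:
        return None if self.h_prev is None else self.h / self.h_prev

    def value_weight_sum(self) -> float:
        """Sum of the value-node weights; 1 by constant reproduction."""
        return self.x_prev + self.x

    def unit_weights(self) -> dict[str, float]:
        """Weights on the s-scale (h, h^2 scaling removed)."""
        h = self.h
        return {
            "x_prev": self.x_prev,
            "x": self.x,
            "xdot": self.xdot / h,
            "xddot": self.xddot / h**2,
            "xdot_new": self.xdot_new / h,
            "xddot_new": self.xddot_new / h**2,
        }

    def apply(self, x, xdot, xddot, xdot_new, xddot_new, x_prev=None):
        """Evaluate the rule polynomial at t+h from its nodes."""
        out = (
            self.x * np.asarray(x)
            + self.xdot * np.asarray(xdot)
            + self.xddot * np.asarray(xddot)
            + self.xdot_new * np.asarray(xdot_new)
            + self.xddot_new * np.asarray(xddot_new)
        )
        if self.x_prev != 0.0:
            if x_prev is None:
                raise ValueError("rule uses x(t - h_prev) but x_prev was not given")
            out = out + self.x_prev * np.asarray(x_prev)
        return out


def g4_weights(h: float) -> RuleWeights:
    """Weights of the implicit degree-4 two-point rule.

    The closed form (x: 1, xdot: h/2, xdot_new: h/2, xddot: h^2/12,
    xddot_new: -h^2/12) is recovered by the generic interpolation solve; the
    closed form is used here and cross-checked against the generic solver in
    the test suite.
    """
    if h <= 0:
        raise ValueError(f"step size must be positive, got h={h!r}")
    return RuleWeights(
        degree=4,
        h=h,
        h_prev=None,
        x_prev=0.0,
        x=1.0,
        xdot=h / 2.0,
        xddot=h * h / 12.0,
        xdot_new=h / 2.0,
        xddot_new=-h * h / 12.0,
    )


@lru_cache(maxsize=256)
def _g5_unit_weights(r: float) -> tuple[float, ...]:
    """Solve the 6x6 interpolation conditions on the s-scale.

    Nodes (in s units): x at -r and 0; first/second derivatives at 0 and 1.
    Exactness on monomials s^j, j = 0..5, at s = 1.
    """
    A = np.zeros((6, 6))
    b = np.ones(6)
    for j in range(6):
        # columns: w_prev, w_x, a (s-deriv at 0), b2 (2nd deriv at 0),
        #          c (deriv at 1), d (2nd deriv at 1)
        A[j, 0] = (-r) ** j
        A[j, 1] = 1.0 if j == 0 else 0.0
        A[j, 2] = 1.0 if j == 1 else 0.0
        A[j, 3] = 2.0 if j == 2 else 0.0
        A[j, 4] = j
        A[j, 5] = j * (j - 1)
    return tuple(np.linalg.solve(A, b))


def g5_weights(h: float, h_prev: float) -> RuleWeights:
    """Weights of the degree-5 error-reference rule for steps (h_prev, h).

    Raises
    ------
    IllConditionedRuleError
        If h/h_prev falls outside :data:`STEP_RATIO_BOUNDS`; the caller is
        expected to fall back to the predictor-difference error estimate.
    """
    if h <= 0 or h_prev <= 0:
        raise ValueError(f"step sizes must be positive, got h={h!r}, h_prev={h_prev!r}")
    ratio = h / h_prev
    lo, hi = STEP_RATIO_BOUNDS
    if not (lo <= ratio <= hi):
        raise IllConditionedRuleError(ratio)
    w_prev, w_x, a, b2, c, d = _g5_unit_weights(h_prev / h)
    return RuleWeights(
        degree=5,
        h=h,
        h_prev=h_prev,
        x_prev=w_prev,
        x=w_x,
        xdot=a * h,
        xddot=b2 * h * h,
        xdot_new=c * h,
        xddot_new=d * h * h,
    )


@dataclass(frozen=True)
class PredictorWeights:
    """Weights of the explicit degree-4 extrapolant used as the Newton guess.

    Nodes: x, xdot, xddot at t and xdot, xddot at t - h_prev, evaluated at
    t + h.  Derivative weights multiply the raw nodes (h-scaling inside).
    """

    h: float
    h_prev: float
    x: float
    xdot: float
    xddot: float
    xdot_prev: float
    xddot_prev: float

    def apply(self, x, xdot, xddot, xdot_prev, xddot_prev):
        return (
            self.x * np.asarray(x)
            + self.xdot * np.asarray(xdot)
            + self.xddot * np.asarray(xddot)
            + self.xdot_prev * np.asarray(xdot_prev)
            + self.xddot_prev * np.asarray(xddot_prev)
        )


@lru_cache(maxsize=256)
def _predictor_unit_weights(r: float) -> tuple[float, ...]:
    # unknowns: a (deriv at 0), b2 (2nd deriv at 0), c (deriv at -r),
    # d (2nd deriv at -r); value weight at 0 is 1 by the j=0 condition.
    A = np.zeros((4, 4))
    b = np.ones(4)
    for row, j in enumerate(range(1, 5)):
        A[row, 0] = 1.0 if j == 1 else 0.0
        A[row, 1] = 2.0 if j == 2 else 0.0
        A[row, 2] = j * (-r) ** (j - 1)
        A[row, 3] = j * (j - 1) * ((-r) ** (j - 2) if j >= 2 else 0.0)
    return tuple(np.linalg.solve(A, b))


def predictor_weights(h: float, h_prev: float) -> PredictorWeights:
    """Degree-4 extrapolation weights for the explicit initial guess."""
    if h <= 0 or h_prev <= 0:
        raise ValueError(f"step sizes must be positive, got h={h!r}, h_prev={h_prev!r}")
    a, b2, c, d = _predictor_unit_weights(h_prev / h)
    return PredictorWeights(
        h=h,
        h_prev=h_prev,
        x=1.0,
        xdot=a * h,
        xddot=b2 * h * h,
        xdot_prev=c * h,
        xddot_prev=d * h * h,
    )


def truncation_constants():
    """Leading local-error constants (coefficient of h^5 x^(5)).

    Both constants are *derived* at call time with exact rational arithmetic:
    the second-derivative rule by solving its interpolation conditions and
    measuring the defect on t^5, the degree-4 Adams–Moulton rule by
    integrating its Lagrange basis (constant step).  Returns sympy Rationals

        {"second_derivative": 1/720, "adams_moulton4": 19/720}
    """
    import sympy as sp

    s = sp.symbols("s")
    # --- second-derivative rule, re-derived exactly at unit step ---
    wx, a, b2, c, d = sp.symbols("wx a b2 c d")
    eqs = []
    for j in range(5):
        mono = s**j
        d1 = sp.diff(mono, s)
        d2 = sp.diff(mono, s, 2)
        eqs.append(
            sp.Eq(
                wx * mono.subs(s, 0)
                + a * d1.subs(s, 0)
                + b2 * d2.subs(s, 0)
                + c * d1.subs(s, 1)
                + d * d2.subs(s, 1),
                mono.subs(s, 1),
            )
        )
    sol = sp.solve(eqs, [wx, a, b2, c, d], dict=True)[0]
    mono = s**5
    defect_sd = (
        sol[wx] * mono.subs(s, 0)
        + sol[a] * sp.diff(mono, s).subs(s, 0)
        + sol[b2] * sp.diff(mono, s, 2).subs(s, 0)
        + sol[c] * sp.diff(mono, s).subs(s, 1)
        + sol[d] * sp.diff(mono, s, 2).subs(s, 1)
        - mono.subs(s, 1)
    )
    c_sd = sp.Abs(defect_sd) / sp.factorial(5)

    # --- degree-4 Adams–Moulton (implicit Adams), constant step ---
    nodes = [1, 0, -1, -2]
    weights = []
    for n in nodes:
        basis = sp.prod([(s - m) / sp.Rational(n - m) for m in nodes if m != n])
        weights.append(sp.integrate(basis, (s, 0, 1)))
    defect_am = sum(w * 5 * sp.Integer(n) ** 4 for w, n in zip(weights, nodes)) - 1
    c_am = sp.Abs(defect_am) / sp.factorial(5)

    return {"second_derivative": sp.nsimplify(c_sd), "adams_moulton4": sp.nsimplify(c_am)}


def truncation_ratio():
    """Adams–Moulton constant over second-derivative constant (exactly 19)."""
    consts = truncation_constants()
    return consts["adams_moulton4"] / consts["second_derivative"]


def hermite_coefficients(h, y, yd, ydd, yd_new, ydd_new):
    """Coefficients (in s = (t'-t)/h) of the step's degree-4 interpolant.

    The polynomial matches y, y', y'' at s=0 and y', y'' at s=1 — the same
    stencil as the implicit rule — and provides dense output inside a step.
    Returns an array of shape (5,) + y.shape.
    """
    y = np.asarray(y, dtype=float)
    c0 = y
    c1 = h * np.asarray(yd, dtype=float)
    c2 = 0.5 * h * h * np.asarray(ydd, dtype=float)
    rhs1 = h * np.asarray(yd_new, dtype=float) - c1 - 2.0 * c2  # 3 c3 + 4 c4
    rhs2 = h * h * np.asarray(ydd_new, dtype=float) - 2.0 * c2  # 6 c3 + 12 c4
    c3 = rhs1 - rhs2 / 3.0
    c4 = rhs2 / 4.0 - rhs1 / 2.0
    return np.stack([c0, c1, c2, c3, c4])


def hermite_eval(coeffs, s):
    """Evaluate dense-output coefficients at scaled position s in [0, 1]."""
    out = coeffs[4] * s
    for k in (3, 2, 1):
        out = (out + coeffs[k]) * s
    return out + coeffs[0]
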