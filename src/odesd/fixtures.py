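"""Built-in test models.

Every fixture is a :class:`~odesd.symbolic.SymbolicModel` bundled with
initial conditions, parameter values and a default time span, so the whole
derivative stack (J_f, xddot, J_Jf, parameter derivatives) is generated by
the symbolic compiler rather than written by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import ODEModel
from .symbolic import SymbolicModel


@dataclass
class Fixture:
    name: str
    symbolic: SymbolicModel
    x0: np.ndarray
    p: np.ndarray
    t_span: tuple[float, float]
    _model: Optional[ODEModel] = field(default=None, repr=False)

    def compile(self) -> ODEModel:
        if self._model is None:
            self._model = self.symbolic.compile()
        return self._model


def _michaelis_menten() -> Fixture:
    # enzyme + substrate <-> complex -> enzyme + product, mass action
    N = [[-1, 1, 1],
         [-1, 1, 0],
         [1, -1, -1],
         [0, 0, 1]]
    orders = [[1, 0, 0],
              [1, 0, 0],
              [0, 1, 1],
              [0, 0, 0]]
    sym = SymbolicModel.from_mass_action(
        ["x1", "x2", "x3", "x4"], ["k1", "k2", "k3"], N, orders)
    return Fixture("michaelis_menten", sym,
                   np.array([1.0, 1.0, 0.0, 0.0]),
                   np.array([1.0, 1.0, 1.0]), (0.0, 100.0))


def _linear_decay() -> Fixture:
    # scalar xdot = -k x: closed-form solution and sensitivity available
    sym = SymbolicModel.from_rates(["x1"], ["k1"], ["-k1*x1"])
    return Fixture("linear_decay", sym, np.array([1.0]), np.array([1.0]), (0.0, 10.0))


def _repressilator_like() -> Fixture:
    # three-gene negative-feedback ring with Hill repression (dimensionless)
    species = ["m1", "m2", "m3", "p1", "p2", "p3"]
    params = ["alpha", "alpha0", "beta"]
    rates = []
    for i, rep in zip(range(3), (3, 1, 2)):  # gene i repressed by protein rep
        rates.append(f"alpha/(1 + p{rep}**2) + alpha0 - m{i + 1}")
    for i in range(3):
        rates.append(f"beta*(m{i + 1} - p{i + 1})")
    sym = SymbolicModel.from_rates(species, params, rates)
    return Fixture("repressilator_like", sym,
                   np.array([0.2, 0.1, 0.3, 0.1, 0.4, 0.5]),
                   np.array([100.0, 1e-3, 5.0]), (0.0, 50.0))


def _robertson() -> Fixture:
    # classic stiff kinetics: A -> B; B + C -> A + C; 2B -> B + C
    N = [[-1, 1, 0],
         [1, -1, -1],
         [0, 0, 1]]
    orders = [[1, 0, 0],
              [0, 1, 2],
              [0, 1, 0]]
    sym = SymbolicModel.from_mass_action(["x1", "x2", "x3"], ["k1", "k2", "k3"],
                                         N, orders)
    return Fixture("robertson", sym, np.array([1.0, 0.0, 0.0]),
                   np.array([0.04, 1e4, 3e7]), (0.0, 1e4))


def _random_massaction(n: int, seed: int) -> Fixture:
    """Random molecule-count-conserving mass-action network.

    All generated reactions conserve the total copy number, so trajectories
    stay in the bounded simplex {x >= 0, sum x = const}: a guaranteed
    positive invariant region for any rate constants.
    """
    if n < 3:
        raise ValueError("random_massaction needs at least 3 species")
    rng = np.random.default_rng(seed)
    n_r = 2 * n
    N = np.zeros((n, n_r), dtype=int)
    orders = np.zeros((n, n_r), dtype=int)
    for r in range(n_r):
        kind = rng.integers(0, 3)
        if kind == 0:  # A -> B
            a, b = rng.choice(n, size=2, replace=False)
            orders[a, r] = 1
            N[a, r] -= 1
            N[b, r] += 1
        elif kind == 1:  # A + B -> C + D
            a, b, c, d = rng.choice(n, size=4, replace=False)
            orders[a, r] = orders[b, r] = 1
            N[a, r] -= 1
            N[b, r] -= 1
            N[c, r] += 1
            N[d, r] += 1
        else:  # 2A -> B + C
            a, b, c = rng.choice(n, size=3, replace=False)
            orders[a, r] = 2
            N[a, r] -= 2
            N[b, r] += 1
            N[c, r] += 1
    k = np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=n_r))
    x0 = rng.dirichlet(np.ones(n)) * n
    sym = SymbolicModel.from_mass_action(
        [f"x{i + 1}" for i in range(n)],
        [f"k{r + 1}" for r in range(n_r)], N, orders)
    return Fixture(f"random_massaction(n={n}, seed={seed})", sym, x0, k, (0.0, 10.0))


FIXTURE_NAMES = ("michaelis_menten", "linear_decay", "repressilator_like",
                 "robertson", "random_massaction")


def make_fixture(name: str, seed: Optional[int] = None, n: Optional[int] = None) -> Fixture:
    """Reproducible model instances by name.

    ``random_massaction`` takes ``n`` (default 6) and ``seed`` (default 0);
    the other fixtures are deterministic.
    """
    if name == "michaelis_menten":
        return _michaelis_menten()
    if name == "linear_decay":
        return _linear_decay()
    if name == "repressilator_like":
        return _repressilator_like()
    if name == "robertson":
        return _robertson()
    if name == "random_massaction":
        return _random_massaction(n if n is not None else 6,
                                  seed if seed is not None else 0)
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
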