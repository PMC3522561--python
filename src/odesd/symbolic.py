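"""Symbolic model definition and compilation to numeric evaluators.

A :class:`SymbolicModel` holds species, parameters and per-species rate
expressions — written directly, or expanded from a reaction network
(stoichiometry + rate laws, including plain mass action).
:func:`compile_model` differentiates the rates symbolically and emits all
evaluators an :class:`~odesd.model.ODEModel` needs: J_f = ∂f/∂x, the fused
second derivative xddot = J_f f (expressed in terms of the already-computed
f components), J_Jf = ∂(J_f f)/∂x, and the parameter derivatives ∂f/∂p and
∂xddot/∂p.  Only structurally non-zero matrix entries are generated, and the
structural pattern is exported as the model's Jacobian sparsity.

A small JSON schema (documented on :func:`save_model_json`) serves as the
on-disk interchange format for models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import sympy as sp

from .exceptions import CompilationError, UnsupportedModelError
from .model import ODEModel


def _as_symbols(names) -> tuple[sp.Symbol, ...]:
    out = []
    for n in names:
        out.append(n if isinstance(n, sp.Symbol) else sp.Symbol(str(n), real=True))
    return tuple(out)


@dataclass
class SymbolicModel:
    """Species, parameters and symbolic per-species rates f_i(x, p).

    ``stoichiometry`` (n_species x n_reactions, integer) and the per-reaction
    ``reaction_rates`` are retained when the model was built from reactions;
    they enable conservation-law analysis.  ``reactant_orders`` is set for
    pure mass-action networks.
    """

    species: tuple[sp.Symbol, ...]
    params: tuple[sp.Symbol, ...]
    rates: tuple[sp.Expr, ...]
    stoichiometry: Optional[np.ndarray] = None
    reaction_rates: Optional[tuple[sp.Expr, ...]] = None
    reactant_orders: Optional[np.ndarray] = None
    reactions: Optional[list] = None  # raw (reactants, products, law) triples
    _compiled: Optional[ODEModel] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.rates) != len(self.species):
            raise CompilationError(
                f"{len(self.rates)} rate expressions for {len(self.species)} species"
            )
        declared = set(self.species) | set(self.params)
        for i, r in enumerate(self.rates):
            extra = sp.sympify(r).free_symbols - declared
            if extra:
                names = ", ".join(sorted(str(s) for s in extra))
                raise CompilationError(
                    f"rate expression for {self.species[i]} uses undeclared symbol(s): {names}"
                )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_rates(cls, species, params, rates) -> "SymbolicModel":
        """Build from per-species rate expressions (strings or sympy)."""
        xs = _as_symbols(species)
        ps = _as_symbols(params)
        local = {str(s): s for s in xs + ps}
        parsed = tuple(sp.sympify(r, locals=local) for r in rates)
        return cls(species=xs, params=ps, rates=parsed)

    @classmethod
    def from_mass_action(cls, species, rate_constants, stoichiometry, reactant_orders
                         ) -> "SymbolicModel":
        """Build a mass-action network.

        ``stoichiometry`` is the net n_species x n_reactions integer matrix,
        ``reactant_orders`` the non-negative reactant-order matrix of the same
        shape; reaction r has rate k_r * prod_i x_i**order[i, r].
        """
        xs = _as_symbols(species)
        ks = _as_symbols(rate_constants)
        N = np.asarray(stoichiometry, dtype=int)
        orders = np.asarray(reactant_orders, dtype=int)
        if N.shape != (len(xs), len(ks)) or orders.shape != N.shape:
            raise CompilationError("stoichiometry/orders must be n_species x n_reactions")
        if (orders < 0).any():
            raise CompilationError("reactant orders must be non-negative")
        rxn_rates = tuple(
            ks[r] * sp.prod([xs[i] ** int(orders[i, r]) for i in range(len(xs))])
            for r in range(len(ks))
        )
        rates = tuple(
            sp.expand(sum(int(N[i, r]) * rxn_rates[r] for r in range(len(ks))))
            for i in range(len(xs))
        )
        return cls(species=xs, params=ks, rates=rates, stoichiometry=N,
                   reaction_rates=rxn_rates, reactant_orders=orders)

    @classmethod
    def from_reactions(cls, species, params, reactions) -> "SymbolicModel":
        """Build from reaction triples.

        Each reaction is a mapping with keys ``reactants`` and ``products``
        (species-name -> stoichiometric count) and either ``rate_constant``
        (mass action over the reactants) or ``rate`` (arbitrary expression).
        """
        xs = _as_symbols(species)
        ps = _as_symbols(params)
        local = {str(s): s for s in xs + ps}
        index = {str(s): i for i, s in enumerate(xs)}
        n_r = len(reactions)
        N = np.zeros((len(xs), n_r), dtype=int)
        orders = np.zeros((len(xs), n_r), dtype=int)
        laws = []
        mass_action = True
        for r, rxn in enumerate(reactions):
            for name, count in rxn.get("reactants", {}).items():
                N[index[name], r] -= int(count)
                orders[index[name], r] += int(count)
            for name, count in rxn.get("products", {}).items():
                N[index[name], r] += int(count)
            if "rate_constant" in rxn:
                k = sp.sympify(rxn["rate_constant"], locals=local)
                law = k * sp.prod([xs[i] ** int(orders[i, r]) for i in range(len(xs))])
            else:
                mass_action = False
                law = sp.sympify(rxn["rate"], locals=local)
            laws.append(law)
        rates = tuple(
            sp.expand(sum(int(N[i, r]) * laws[r] for r in range(n_r)))
            for i in range(len(xs))
        )
        return cls(species=xs, params=ps, rates=rates, stoichiometry=N,
                   reaction_rates=tuple(laws),
                   reactant_orders=orders if mass_action else None,
                   reactions=list(reactions))

    # ------------------------------------------------------------------ #
    @property
    def n_states(self) -> int:
        return len(self.species)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def compile(self, **kwargs) -> ODEModel:
        if self._compiled is None and not kwargs:
            self._compiled = compile_model(self)
            return self._compiled
        return self._compiled if not kwargs else compile_model(self, **kwargs)


def _nonzero_entries(matrix_exprs):
    """(i, j, expr) triples of the structurally non-zero entries."""
    entries = []
    for (i, j), e in matrix_exprs.items():
        if e != 0:
            entries.append((i, j, e))
    return entries


def _lambdify_vector(exprs, args):
    fn = sp.lambdify(args, list(exprs), modules="numpy")

    def ev(*vals):
        return np.asarray(fn(*vals), dtype=float)

    return ev


def _lambdify_sparse(entries, shape, args):
    if not entries:
        def zero(*vals):
            return np.zeros(shape)
        return zero
    rows = np.array([i for i, _, _ in entries])
    cols = np.array([j for _, j, _ in entries])
    fn = sp.lambdify(args, [e for _, _, e in entries], modules="numpy")

    def ev(*vals):
        out = np.zeros(shape)
        out[rows, cols] = fn(*vals)
        return out

    return ev


def compile_model(sym: SymbolicModel, emit_source: bool = False):
    """Generate all ODEModel evaluators by symbolic differentiation.

    Returns the compiled :class:`ODEModel`; with ``emit_source=True`` returns
    ``(model, source)`` where ``source`` is a human-readable listing of the
    generated non-zero expressions for audit.
    """
    xs, ps = sym.species, sym.params
    n, m = sym.n_states, sym.n_params
    f = [sp.expand(e) for e in sym.rates]

    J = {}
    for i in range(n):
        for j in range(n):
            J[(i, j)] = sp.expand(sp.diff(f[i], xs[j]))
    J_entries = _nonzero_entries(J)
    sparsity = np.zeros((n, n), dtype=bool)
    for i, j, _ in J_entries:
        sparsity[i, j] = True

    # fused second derivative: rows of J contracted with placeholder f-symbols,
    # so the generated code reuses the already-computed rate components
    fsyms = sp.symbols(f"_f0:{n}", real=True)
    xdd_fused = [
        sp.Add(*[J[(i, j)] * fsyms[j] for j in range(n) if sparsity[i, j]])
        for i in range(n)
    ]
    xdd_full = [sp.expand(sum(J[(i, j)] * f[j] for j in range(n) if sparsity[i, j]))
                for i in range(n)]

    JJ = {}
    for i in range(n):
        for j in range(n):
            JJ[(i, j)] = sp.expand(sp.diff(xdd_full[i], xs[j]))
    JJ_entries = _nonzero_entries(JJ)

    dfdp = {}
    dxdddp = {}
    for i in range(n):
        for k in range(m):
            dfdp[(i, k)] = sp.expand(sp.diff(f[i], ps[k]))
            dxdddp[(i, k)] = sp.expand(sp.diff(xdd_full[i], ps[k]))
    dfdp_entries = _nonzero_entries(dfdp)
    dxdddp_entries = _nonzero_entries(dxdddp)

    args = tuple(xs) + tuple(ps)
    f_ev = _lambdify_vector(f, args)
    jac_ev = _lambdify_sparse(J_entries, (n, n), args)
    jjf_ev = _lambdify_sparse(JJ_entries, (n, n), args)
    dfdp_ev = _lambdify_sparse(dfdp_entries, (n, m), args)
    dxdddp_ev = _lambdify_sparse(dxdddp_entries, (n, m), args)
    xdd_fused_ev = _lambdify_vector(xdd_fused, args + tuple(fsyms))

    def rhs(x, p):
        return f_ev(*x, *p)

    def jacobian(x, p):
        return jac_ev(*x, *p)

    def second_rhs_jacobian(x, p):
        return jjf_ev(*x, *p)

    def second_rhs(x, p, fvals=None):
        if fvals is None:
            fvals = f_ev(*x, *p)
        return xdd_fused_ev(*x, *p, *fvals)

    def rhs_param_jac(x, p):
        return dfdp_ev(*x, *p)

    def second_rhs_param_jac(x, p):
        return dxdddp_ev(*x, *p)

    model = ODEModel(
        n_states=n,
        n_params=m,
        rhs=rhs,
        jacobian=jacobian,
        second_rhs_jacobian=second_rhs_jacobian,
        second_rhs=second_rhs,
        rhs_param_jac=rhs_param_jac,
        second_rhs_param_jac=second_rhs_param_jac,
        jac_sparsity=sparsity,
        species_names=tuple(str(s) for s in xs),
        param_names=tuple(str(s) for s in ps),
    )
    if not emit_source:
        return model

    lines = ["# generated evaluators (structurally non-zero entries only)", "# f:"]
    for i, e in enumerate(f):
        lines.append(f"f[{i}] = {sp.pycode(e)}")
    lines.append("# xddot (in terms of f components):")
    for i, e in enumerate(xdd_fused):
        lines.append(f"xddot[{i}] = {sp.pycode(e)}")
    for name, entries in [("J_f", J_entries), ("J_Jf", JJ_entries),
                          ("df/dp", dfdp_entries), ("dxddot/dp", dxdddp_entries)]:
        lines.append(f"# {name}:")
        for i, j, e in entries:
            lines.append(f"{name}[{i},{j}] = {sp.pycode(e)}")
    return model, "\n".join(lines)


def jacobian_nnz_fraction(sym: SymbolicModel) -> Fraction:
    """Fraction of structurally non-zero entries of J_f (in (0, 1])."""
    n = sym.n_states
    count = 0
    for i in range(n):
        for j in range(n):
            if sp.expand(sp.diff(sp.expand(sym.rates[i]), sym.species[j])) != 0:
                count += 1
    return Fraction(count, n * n)


def conservation_laws(sym: SymbolicModel) -> list[np.ndarray]:
    """Integer basis of the left null space of the stoichiometric matrix.

    Each returned vector v satisfies v.T @ f(x, p) = 0 identically, i.e.
    v.T x is conserved along exact trajectories.
    """
    if sym.stoichiometry is None:
        raise UnsupportedModelError(
            "conservation laws require a reaction-network (stoichiometric) model"
        )
    NT = sp.Matrix(sym.stoichiometry.T.tolist())
    basis = []
    for vec in NT.nullspace():
        denoms = [sp.fraction(sp.nsimplify(e))[1] for e in vec]
        scale = sp.lcm([sp.Integer(d) for d in denoms]) if denoms else 1
        ints = [sp.Integer(e * scale) for e in vec]
        g = sp.gcd([i for i in ints if i != 0]) if any(ints) else 1
        ints = [int(i / g) for i in ints]
        nz = next((v for v in ints if v != 0), 1)
        if nz < 0:
            ints = [-v for v in ints]
        basis.append(np.array(ints, dtype=int))
    return basis


# ---------------------------------------------------------------------- #
# JSON model format
# ---------------------------------------------------------------------- #

SCHEMA = "odesd-model/1"


def save_model_json(sym: SymbolicModel, path, x0=None, p_values=None):
    """Write a model to the odesd JSON schema.

    Schema (``odesd-model/1``)::

        {
          "schema": "odesd-model/1",
          "species": [{"name": "x1", "initial": 1.0}, ...],
          "parameters": [{"name": "k1", "value": 1.0}, ...],
          "reactions": [{"reactants": {"x1": 1, "x2": 1},
                         "products": {"x3": 1},
                         "rate_constant": "k1"}, ...]     # or "rate": "expr"
        }

    Models without reaction structure are written with per-species ODEs::

        "odes": [{"species": "x1", "rate": "-k1*x1"}, ...]

    ``initial``/``value`` default to 0/1 when not supplied.
    """
    doc = {"schema": SCHEMA}
    x0 = [0.0] * sym.n_states if x0 is None else list(map(float, x0))
    pv = [1.0] * sym.n_params if p_values is None else list(map(float, p_values))
    doc["species"] = [{"name": str(s), "initial": v} for s, v in zip(sym.species, x0)]
    doc["parameters"] = [{"name": str(s), "value": v} for s, v in zip(sym.params, pv)]
    if sym.reactions is not None:
        doc["reactions"] = sym.reactions
    elif sym.stoichiometry is not None and sym.reaction_rates is not None:
        rxns = []
        N = sym.stoichiometry
        for r in range(N.shape[1]):
            reactants, products = {}, {}
            for i in range(N.shape[0]):
                if sym.reactant_orders is not None and sym.reactant_orders[i, r] > 0:
                    reactants[str(sym.species[i])] = int(sym.reactant_orders[i, r])
                net = int(N[i, r])
                base = reactants.get(str(sym.species[i]), 0)
                if net + base > 0:
                    products[str(sym.species[i])] = net + base
            rxns.append({"reactants": reactants, "products": products,
                         "rate": str(sym.reaction_rates[r])})
        doc["reactions"] = rxns
    else:
        doc["odes"] = [{"species": str(s), "rate": str(e)}
                       for s, e in zip(sym.species, sym.rates)]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model_json(path):
    """Read an ``odesd-model/1`` JSON file.

    Returns ``(SymbolicModel, x0, p_values)``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != SCHEMA:
        raise CompilationError(f"unknown model schema {doc.get('schema')!r}")
    species = [s["name"] for s in doc["species"]]
    params = [p["name"] for p in doc["parameters"]]
    x0 = np.array([float(s.get("initial", 0.0)) for s in doc["species"]])
    pv = np.array([float(p.get("value", 1.0)) for p in doc["parameters"]])
    if "reactions" in doc:
        sym = SymbolicModel.from_reactions(species, params, doc["reactions"])
    else:
        by_name = {o["species"]: o["rate"] for o in doc["odes"]}
        missing = [s for s in species if s not in by_name]
        if missing:
            raise CompilationError(f"no ODE given for species: {missing}")
        sym = SymbolicModel.from_rates(species, params, [by_name[s] for s in species])
    return sym, x0, pv
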