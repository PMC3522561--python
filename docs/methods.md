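# Methods notes

## Model class and assumptions

The integrator targets autonomous ODE systems ẋ = f(x, p) arising from
(bio)chemical reaction networks: mass-action or general rate-law kinetics,
sparse Jacobians, frequent stiffness (fast association/dissociation versus
slow conversion), and analytic access to the governing expressions.  Time
enters only through the state; non-autonomous forcing, DAEs, events and
delays are out of scope.  Models supply, besides f, the state Jacobian
J_f, the Jacobian J_Jf = ∂(J_f f)/∂x = ∂J_f/∂x·f + J_f², and — for
sensitivity analysis — ∂f/∂p and ∂ẍ/∂p.  The symbolic compiler generates
all of these; hand-written models may supply a fused ẍ evaluator, or the
solver falls back to the explicit product J_f f.  Parameter derivatives are
never approximated by finite differences internally: if a model lacks them,
sensitivity analysis refuses to run, because the method's efficiency rests
on analytic derivatives (finite differencing would silently change both
cost and accuracy).  Finite differences are used only for *validation*
(`validate_model`) and in tests as an independent oracle.

## Integration rule

The step rule is the two-point Hermite (Obreshkov-type) relation

x(t+h) = x(t) + h/2 (ẋ(t)+ẋ(t+h)) + h²/12 (ẍ(t)−ẍ(t+h)),

exact for polynomials of degree ≤ 4, with leading defect h⁵x⁽⁵⁾/720.  Its
linear stability function is the (2,2) Padé approximant of e^z — A-stable,
|R(∞)| = 1 (not L-stable; heavily damped modes are not annihilated, only
bounded).  The degree-4 Adams–Moulton constant is 19/720, i.e. 19× larger,
which is re-derived exactly at run time by integrating the Adams–Moulton
Lagrange basis; the corresponding BDF comparison (sometimes quoted as
"about 72×") is treated as approximate and not asserted: the exact BDF4
ratio is (12/125)/(1/720) ≈ 69.1.

All rule weights — g4, the degree-5 error reference g5 (same nodes plus
x(t−h₋₁)), and the explicit predictor — are obtained by solving the
Hermite–Birkhoff exactness conditions at unit scale s = (t′−t)/h, not from
hand-derived variable-step formulas.  The generic solve is cross-checked by
polynomial-exactness property tests and reproduces the known equal-step
values (g4: 1/2 and 1/12; g5: 14/31, 2/31, −1/31, 32/31).  Step ratios
h/h₋₁ outside [10⁻³, 10³] are declared ill-conditioned and trigger the
fallback error estimate.

## Newton iteration

The implicit relation is solved by simplified Newton with
M = h/2 J_f − h²/12 J_Jf − I evaluated at the explicit predictor (degree-4
extrapolant through x, ẋ, ẍ at t and ẋ, ẍ at t−h₋₁; second-order Taylor on
the first step) and factorized once per attempted step (dense LU).

Stopping rule (the literature leaves this open; all values configurable):
convergence when the estimated remaining error ρ/(1−ρ)·‖Δx‖_w ≤ κ, with ρ
the observed correction ratio and ‖·‖_w the same weighted RMS norm as the
error control, or immediately when ‖Δx‖_w ≤ 0.03 κ.  Divergence is declared
after two correction ratios ≥ 0.9 or non-finite iterates.  The default
κ = 0.01 is deliberately deep: the g4 rule preserves linear invariants
(conservation laws) *exactly*, so the only conservation drift comes from the
unconverged Newton residual; κ = 0.01 with the rate-based test keeps the
per-step defect orders of magnitude below the local error tolerance and the
accumulated drift near round-off (measured ~1e-15 on the enzymatic fixture
over 100 time units at rtol 1e-6), at the cost of roughly one extra
iteration per step.  A looser κ (e.g. 0.1) is faster but lets conserved
totals drift at ~κ·tolerance per step.

**Restart recovery.**  The h²·J_Jf term makes M quadratically sensitive to
Jacobian errors, so on strongly stiff problems a predictor that extrapolates
poorly in a fast component can stall the iteration at step sizes the error
control would happily accept.  When a sweep stalls or diverges with a finite
iterate, the matrix is rebuilt at that iterate (Jacobians there are far
closer to the solution's) and the iteration continues, up to 2 restarts,
before the step is abandoned and h halved.  Restarted steps are treated as
hard: the controller does not grow h after them, and growth is also capped
(1.2×) when the iteration used most of its budget.  On easy problems
restarts never trigger and the classic contract — Jacobians evaluated
exactly once per attempted step, at the predictor — holds, which the tests
assert on the enzymatic fixture.

## Error estimate and step control

After convergence, one back-substitution with the already-factorized M
gives ε = M⁻¹(g5(t+h) − x(t+h)); no second factorization or Newton run is
needed because the g5 Newton weights (14/31, 2/31 at equal steps) are close
to g4's (1/2, 1/12).  The estimate is a first-order Newton step toward the
degree-5 solution and scales as h⁵ (verified by a slope test).  Acceptance
uses the weighted RMS norm

‖ε‖_w = sqrt(mean((ε_i/(atol_i + rtol·|x_i|))²)) ≤ 1,

with the reference state taken component-wise as max(|x(t)|, |x(t+h)|).
The next step is σh with σ = (1/(2‖ε‖_w))^{1/5} — targeting *half* the
tolerance so that estimates hover below the acceptance threshold rather than
straddling it — clipped to [0.1, 5] per attempt.  On the first step (no
second history node) the estimate falls back to the predictor–corrector
difference, a conservative O(h³) overestimate that is flagged as
lower-quality; the controller recovers the right scale within a few steps.
The initial h comes from the x/f magnitude ratio capped by a
(720τ/‖ẍ‖_w)^{1/5} curvature bound and is always validated by the first
estimate.  Rejected steps retry with the same σ formula (floor 0.1); the
final step is clamped to land on t_end exactly, splitting the last interval
when it would otherwise exceed 1.4 h.

## Parameter sensitivities

The staggered direct scheme advances S = ∂x/∂p after each accepted state
step: one fresh LU of A = I − h/2 J_f + h²/12 J_Jf, with both Jacobians
re-evaluated at the *converged* state (the frozen Newton Jacobians live at
the predictor and would bias S), then one back-substitution per parameter
column.  ṡ and s̈ are stored using those same fresh Jacobians, so the
stored block is internally consistent.  Sensitivity initial conditions
default to zero; a hook (`s0`) accepts ∂x₀/∂p when initial conditions
depend on parameters.  Sensitivities are excluded from the acceptance norm:
the states never depend on S, so the step sequence is bit-identical with
sensitivities on or off (asserted in tests); "same tolerance" is interpreted
as same tolerance settings, not S entering the norm (a `sens_in_error_norm`
option is reserved should that interpretation ever be wanted).

An iterative mode solves the same linear relation by Newton iteration
reusing the state step's factorization instead of factorizing A; both modes
share the same fixed point and are cross-checked against each other.  The
iterative mode falls back to direct on non-convergence.  Rejected steps do
not run the sensitivity stage.  The optional `jacobian_reuse` mode feeds
the sensitivity stage's fresh Jacobians into the next step's Newton matrix,
saving one Jacobian pair per step at the cost of slightly stale iteration
matrices; it changes results only within tolerance.

## Symbolic compilation

The compiler differentiates per-species rate expressions (or mass-action
stoichiometry expanded to rates) with sympy and lambdifies only the
structurally non-zero entries of each matrix, scattered into preallocated
dense arrays; the structural pattern is exported as the model's Jacobian
sparsity and is honest by construction (entries outside it are identically
zero).  ẍ components are expressed in the already-computed f components
rather than re-expanded, so evaluating ẍ costs little more than f.  No
simplification beyond polynomial expansion is attempted; correctness and
structural sparsity are the contract, not minimal operation count.  An
`emit_source` flag returns a human-readable listing for audit.  Models are
exchanged on disk via a small JSON schema (species, parameters, reactions
with stoichiometry and either a mass-action rate constant or a rate
expression); conservation laws are integer bases of the left null space of
the stoichiometric matrix and hold for arbitrary rate laws.

## Built-in fixtures

- `michaelis_menten` — the 4-species enzymatic scheme (E+S⇌C→E+P), k=(1,1,1),
  x₀=(1,1,0,0): two conservation laws, Jacobian 5/8 dense.
- `linear_decay` — scalar ẋ=−kx with closed-form state and sensitivity.
- `repressilator_like` — 6-species negative-feedback ring with Hill
  repression (α=100, α₀=10⁻³, β=5, n=2), oscillatory and non-polynomial.
- `robertson` — the classic 3-species stiff kinetics (rates 0.04, 10⁴,
  3·10⁷) over [0, 10⁴].
- `random_massaction(n, seed)` — seed-deterministic random networks whose
  reactions all conserve total copy number, guaranteeing a bounded positive
  invariant region.

These fixtures exercise stiffness, oscillation, conservation and sparsity,
but they are small and noise-free: passing tests demonstrate the numerics
(orders, estimator fidelity, conservation, sensitivity consistency), not
performance at the scale of large signaling models, and say nothing about
models with events, discontinuous inputs or non-smooth rate laws.

## Problem sizes used in tests and the acceptance script

Order measurements use ẋ = −x over h ∈ [0.0125, 0.2]; estimator and
controller checks run the scalar and 4-species fixtures to t = 10–100;
sensitivity validation integrates the enzymatic scheme to t = 10 at
rtol 10⁻⁸ against central trajectory differences (δ = 10⁻⁶ p_k); stiff
robustness integrates Robertson to t = 10⁴ at rtol 10⁻⁶ against a Radau
reference at rtol 10⁻¹².  These sizes keep the whole suite in well under a
minute of compute per module while exercising every code path.

## Known limitations

- Dense LU only.  The sparsity pattern is tracked and exported, but a
  sparse factorization path (worthwhile above a few hundred states) is not
  implemented; the `IntegratorOptions` surface leaves room for it.
- On strongly stiff quasi-steady trajectories (Robertson tail) the step
  size is limited by simplified-Newton convergence, not accuracy: the
  h²J_Jf term amplifies predictor-induced Jacobian errors, so steps stay
  orders of magnitude below what the error estimate would allow, and the
  run costs ~10⁴ steps where a BDF code needs ~10².  Restarts and growth
  caps make this robust and correct (final state matches the reference to
  ~10⁻⁶ relative) but not fast.
- |R(∞)| = 1: very stiff transients are damped slowly rather than
  annihilated; the controller compensates with smaller steps near sharp
  layers.
- The first step has only the fallback error estimate; extremely bad user
  h₀ values cost a few rejections rather than a failure.
- No event handling, no steady-state detection, no variable order.
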