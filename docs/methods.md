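# Methods

## The reduction method

canonred implements nullcline-based, format-preserving order reduction of
canonical ODE models.  Given a model in one of three canonical families —

* **S-system** (Biochemical Systems Theory):
  `dXi/dt = alpha_i * prod_j Xj**g_ij  -  beta_i * prod_j Xj**h_ij`,
* **GMA** (generalized mass action): a sum of signed power-law terms per
  equation,
* **Lotka–Volterra**: `dXi/dt = a_i*Xi + sum_j b_ij*Xi*Xj`,

— selected ODEs are replaced by the closed-form solutions of their
nullclines (the equation with the derivative set to zero), and those
solutions are substituted **symbolically** into the remaining equations.
Parameters are never merged numerically during substitution: rate constants
of a reduced model are explicit compositions of the parent's named
parameters, so reduced models remain simulable under targeted parameter
changes and expose parameter dependencies directly.

For an S-system, collecting the terms of equation *k* that contain `X_k`
yields the power-product nullcline

    X_k = ( (beta_k/alpha_k) * prod_{j != k} Xj**(h_kj - g_kj) )**(1/(g_kk - h_kk)),

which is undefined only when `g_kk = h_kk` (the variable does not shape its
own balance) — such equations are refused with `NotReducible`.  Because the
solution is itself a power product, substitution followed by canonical
normalization (exponent merging, rate-constant composition) returns an
S-system of dimension n−1: the format is preserved and the procedure can be
iterated.  For an LV model the nullcline is affine,
`X_k = -a_k/b_kk - sum_j (b_kj/b_kk)*Xj` (refused when `b_kk = 0`), and
substitution amounts to the parameter updates
`a~_i = a_i - a_k*b_ik/b_kk`, `b~_ij = b_ij - b_ik*b_kj/b_kk`, again closed
under the format.  GMA and general expression models are reduced when the
nullcline can be solved in closed form — either by collecting the equation
into two aggregate power terms in `X_k`, or when it is affine or
rational-linear in `X_k` (tried in that order; the choice is fixed, and the
two strategies cannot both succeed on the same equation since a two-power
collection with distinct exponents is not linear after clearing
denominators).  There is no numeric fallback: if neither strategy applies,
reduction of that variable is refused.

Eliminated variables are retained as algebraic **add-ons** — explicit
functions of the retained state, evaluated along trajectories but never
integrated, and resolved so they reference only retained variables.
Sequential elimination operates on the already-reduced model at each step;
simultaneous elimination solves the joint nullcline block in one shot (a
log-linear solve for S-systems, guaranteeing power-product solutions; an
affine solve for LV; individual solves plus dependency resolution, or a
joint symbolic solve, for general models).  Both routes produce the same
reduced dynamics wherever both apply, and elimination order is immaterial.

Two properties hold **by construction** and anchor the test suite:

1. every nullcline solution zeroes its source equation identically;
2. every steady state of the parent is a steady state of the reduced model
   (projected on the retained variables), because at a fixed point the
   nullcline relations are satisfied exactly.

No time-scale separation is assumed anywhere.  Setting a derivative to zero
is an *approximation* whose quality depends on the operating region and the
perturbations of interest; it is assessed by simulation, not by an
asymptotic argument.  Transient shapes (overshoots, delays) are the usual
casualty; attractor identity close to a separatrix can be another (see the
bistable example below).

## Recast auxiliaries

Hill terms — repression `k1*K**n/(K**n + X**n)` or activation
`k1*X**n/(K**n + X**n)` — are recast exactly into power-law form by the
auxiliary variable `A = K**n + X**n`: the Hill term becomes
`k1*K**n*A**-1` (or `k1*X**n*A**-1`), and `A` obeys the chain-rule ODE
`dA/dt = n*X**(n-1)*dX/dt` with the regulator's right-hand side substituted
and distributed into signed power-law terms.  This is an identity, not an
approximation; the recast model carries the defining constraint and tests
verify trajectory agreement with the original and constraint drift along
recast trajectories.

Recast auxiliaries need special elimination rules, because the auxiliary
ODE is the chain-rule image of the regulator's and never contains the
auxiliary itself (its self-exponents cancel):

* **Eliminating the auxiliary**: `dA/dt = n*X**(n-1)*dX/dt = 0` is, on the
  positive orthant, equivalent to the *regulator's* nullcline.  The
  auxiliary is therefore slaved to its constraint evaluated at the
  regulator's nullcline value (e.g. `A = (X3/2)**n + 1` when the
  regulator's nullcline is `X4 = X3/2`).
* **Eliminating the regulator** makes the auxiliary's ODE vanish
  identically; integrating a frozen variable would silently decouple the
  feedback, so the auxiliary is automatically slaved through its
  constraint, reported in the elimination record and warnings.

Steady-state analysis of recast models operates on the constraint manifold:
the auxiliary is substituted out, the core system is solved, and auxiliary
components are lifted back through the constraint.  Off-manifold fixed
points of the recast equations form degenerate one-parameter families (the
recast exponent-difference matrix is singular) and are not steady states of
the underlying model.

### A documented impossibility

One published qualitative claim is not reproducible by this substitution
semantics, and provably so: eliminating {X1, X4, X5} from the recast
four-layer repression cascade at Hill exponent n = 18 retains exactly two
ODEs (for X2 and X3) driven by memoryless algebraic add-ons,

    dX2/dt = 200/((X3/2)**n + 1) - X2,      dX3/dt = X2 - 0.1*X3.

The divergence of this planar field is −1 − 0.1 = −1.1 < 0 everywhere on
the positive quadrant, so the Bendixson–Dulac criterion excludes *any*
periodic orbit: no memoryless reduction retaining only {X2, X3} can sustain
a limit cycle, whatever the algebra feeding it.  The corresponding
acceptance test states the published claim and fails; the package reports
the planar reduction honestly as a damped/converging focus (eigenvalues
≈ −0.55 ± 1.26i at n = 18).  Single-variable reductions of X2…X5 at n = 18
do reproduce the published behaviour (the limit cycle degrades to damped
oscillations), as does the bistable example.

## Dynamics

Simulations are piecewise `solve_ivp` integrations (LSODA, stiff-capable;
defaults rtol 1e-8, atol 1e-10 — tightening by 10x moves terminal states by
< 1e-6 relative on the bundled scenarios).  The span is split at every
scheduled event (parameter set/scale, independent-variable set,
discontinuous state reset); the grid value at an event time is the
post-event state.  Add-ons of reduced models are evaluated on the output
grid per segment (so parameter events propagate into them), never
integrated.  A positivity floor of 1e-300 guards power-law evaluation for
models with fractional kinetic orders; crossing it raises a domain error
that the simulator converts into a divergence diagnostic with the last
reachable time, as does a state magnitude above 1e15 (recast auxiliaries
with steep Hill exponents legitimately reach ~1e13 during transients, which
is why the guard is not lower).

Artificial time scaling multiplies every retained right-hand side by a
factor SF > 0; SF < 1 slows the reduced dynamics to partially restore the
delays lost with eliminated intermediates.  Add-ons and steady states are
untouched.

Numerical caveat: a recast auxiliary's ODE does not depend on the auxiliary
itself, so integration error in it accumulates without self-correction.
For very steep Hill exponents (n ≈ 18) the auxiliary spans ten orders of
magnitude along a limit cycle and the achievable absolute accuracy of the
recast run is bounded by rtol times the auxiliary's peak value; tests and
examples compare recast and original trajectories against that scale, and
long n = 18 recast runs benefit from tighter tolerances.

## Steady states, stability, oscillations

S-system fixed points are computed analytically: equating production and
degradation and taking logarithms yields a linear system in
log-concentrations, solvable when the dependent exponent-difference matrix
`(g − h)` is nonsingular.  Arbitrary models use seeded multistart Newton
(scipy `root`/hybr): log-parameterized starts over [1e-2, 1e2]^n for
positive-orthant models (iterates cannot leave the domain), uniform starts
over a box (default [−30, 30]^n) otherwise; roots are filtered by residual
(1e-8 on the state scale), deduplicated at 1e-6 relative tolerance and
sorted by first component.  Stability is classified from the Jacobian
eigenvalues (symbolic differentiation, then numeric evaluation) with a
±1e-9 band on real parts; values inside the band are reported as
`marginal`, never silently classified.

Oscillation classification runs peak detection (scipy `find_peaks`,
prominence 1e-6 of the series range) on the post-transient part of a
series.  Successive peak-to-trough amplitudes over the last four periods
within ±1% classify as `sustained_oscillation` (period = mean peak
spacing); a shrinking amplitude trend as `damped_oscillation`; non-finite,
truncated, or unboundedly growing series as `divergent`; anything else as
`converged`.  The ±1% band over four periods is this package's
operationalization of "stable limit cycle" and is a documented tunable.

Reduction quality is quantified on steady-state-normalized series
`Z_i = X_i / X_i,ss` (a system resting at its steady state has `Z ≡ 1`):
per-variable relative RMSE between original and reduced trajectories, the
maximum pointwise deviation, and a steady-state match flag (terminal states
within 1e-4 relative).  `rank_reductions` reduces each candidate variable
set, simulates both models under a scenario, scores the mean relative RMSE
over the focus variables (normalized by the original run's terminal state),
and sorts ascending; infeasible candidates are recorded with infinite
score, never dropped.  Scores are reported, not thresholded — what counts
as an acceptable reduction depends on the question being asked of the
model.

## Synthetic models

The generators produce random canonical models *around* a prescribed
positive fixed point, so that every reduction and steady-state property is
testable without external data.  For S-systems: off-diagonal kinetic orders
are drawn from [−1, 1] (the classic pathway heuristic of ~0.5 for
substrates and −1 for inhibitors), diagonal degradation orders from
[0.1, 1], production is not autoregulated (hence `g_kk − h_kk < 0` always:
every variable is admissible for elimination), degradation constants from
[0.5, 2], and the production constants are then set so the prescribed point
(log-uniform in [0.1, 10]^n by default) zeroes every equation exactly.  For
LV: strictly negative self-interactions, sparse off-diagonal couplings in
[−0.5, 0.5], and `a = −B x*`.  `require_stable` rejects and redraws until
the Jacobian at the fixed point has eigenvalue real parts below −1e-9.  All
draws come from one named, seeded `numpy` generator; a seed reproduces a
model field-by-field.

What the generators do **not** emulate: realistic metabolic topologies,
conservation relations, oscillatory or chaotic design, wide parameter
scales, or measurement noise.  Passing property tests therefore establish
the *algebraic* correctness of the machinery (format preservation,
steady-state preservation, commutativity) on well-conditioned instances,
not the practical accuracy of any particular reduction of a real network —
that is exactly what the simulation-based comparison and ranking tools are
for.

## Numerical and design choices

* Printed decimal kinetic orders are stored as exact rationals
  (`0.8 → 4/5`), so exponent arithmetic such as `2.5 · 0.4 = 1` holds
  symbolically and the pathway substitution identity is exact.  Rate
  constant *values* are ordinary floats.
* Power-law manipulation uses forced power expansion/denesting, valid on
  the positive orthant (the domain convention of power-law models); root
  selection under `1/(g_kk − h_kk)` takes the principal positive real
  branch.
* Variables are referenced by name, never by position; elimination never
  renumbers.  The reduced model keeps parent names, and the original-vs-
  reduced naming convention of a report is metadata, not a renaming.
* `collapse_numeric` folds symbolic parameter compositions into single
  numeric rate constants and exponents on demand; the result carries a
  warning that targeted parameter changes are no longer possible.
  Structure-only models (unbound parameters) are refused.
* The five-variable feedback pathway's published steady state differs from
  the exact analytic fixed point by ~0.3% (a not-fully-converged numerical
  state); the package reports the analytic value and flags the discrepancy
  rather than correcting either.
* Model documents (`canonred-model/1`) are validated with pydantic;
  expressions are serialized as full-precision infix strings and re-parsed
  against the declared names, so documents round-trip losslessly.

## Problem sizes

The bundled examples are small (3–8 ODEs) and every analysis in the test
suite and the reproduction script runs in seconds: multistart searches use
30–80 seeded starts, property suites sample 20–100 random 4-variable
models, and simulation horizons are 80–600 time units chosen to contain the
relevant transients (at least five extrema for oscillation classification,
full relaxation for steady-state comparisons).
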