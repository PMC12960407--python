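# canonred

Format-preserving, nullcline-based order reduction of canonical nonlinear
ODE models: S-systems and GMA systems from Biochemical Systems Theory, and
Lotka–Volterra models.

## The problem

Biochemical and ecological models keep growing, but usually only a few
variables truly drive a system's dynamics.  canonred lets you *eliminate*
the others: the ODE of a variable `X_k` is replaced by the closed-form
solution of its nullcline (its right-hand side set to zero), and that
solution is substituted **symbolically** into the remaining equations.  For
an S-system

```
dXi/dt = alpha_i * prod_j Xj**g_ij  -  beta_i * prod_j Xj**h_ij
```

the nullcline is the power product

```
X_k = ( (beta_k/alpha_k) * prod_{j!=k} Xj**(h_kj - g_kj) )**(1/(g_kk - h_kk))
```

and for a Lotka–Volterra model `dXi/dt = a_i*Xi + sum_j b_ij*Xi*Xj` it is
the affine expression `X_k = -a_k/b_kk - sum_{j!=k} (b_kj/b_kk)*Xj`, with
the substitution realized by the parameter updates
`a~_i = a_i - a_k*b_ik/b_kk` and `b~_ij = b_ij - b_ik*b_kj/b_kk`.  In both
families the reduced model is again of the same canonical class, the
parent's named parameters survive as symbolic compositions, every steady
state of the parent is preserved by construction, and eliminated variables
remain available as algebraic "add-on" series along any trajectory.  No
time-scale separation is assumed: the reduction is an approximation whose
quality you assess by simulating and comparing, which is what the ranking
tools automate.  Hill-type saturating terms enter the machinery exactly via
recasting with an auxiliary variable `A = K**n + X**n`.

See `docs/methods.md` for the full method description, numerical choices
and limitations.

## Worked example

Reduce the five-variable feedback-inhibited pathway to its boundary
variables and check that a perturbed simulation still lands on the right
steady state:

```python
import numpy as np
import canonred as cr
from canonred import PerturbationEvent as E

pathway = cr.zoo("linear_pathway")          # S-system, X1..X5, input X0
red = cr.reduce(pathway, ["X2", "X3", "X4"])
print(red.model.rhs_exprs())
# {'X1': X0*X5**g*a1 - X1*b1, 'X5': X1*b1 - X5**(3/5)*b5}
print(red.addons["X4"].expr)
# X1**(5/2)*b1**(5/2)/b4**(5/2)    (resolved to retained variables; the
#                                   exponents composed exactly along the chain)

sched = [E(5, "set_independent", "X0", 4.0),   # quadruple the input ...
         E(6, "set_independent", "X0", 1.0),   # ... for one time unit
         E(40, "set_parameter", "b5", 0.8)]    # then double the efflux
x0 = np.array([pathway.initial[v] for v in red.model.dependent])
traj = cr.simulate(red, x0=x0, span=(0, 200), schedule=sched)
print(traj.series["X5"][-1])
# 1.1496582445666557

full = cr.simulate(pathway, span=(0, 200), schedule=sched)
print(full.series["X5"][-1])
# 1.149658244562377   -> same steady state, by design of the method
# (the doubled efflux lowers X5 from 2.5**0.625 = 1.773 to 1.25**0.625 = 1.150)
```

The reduced two-ODE system tracks the full model's post-perturbation steady
states to ~1e-9 while using three fewer ODEs; transient overshoot shapes
are where the two differ, and

```python
cr.rank_reductions(pathway, [("X4",), ("X2", "X3", "X4")],
                   {"span": (0, 120), "schedule": sched}, focus=["X5"])
```

quantifies that: eliminating only `X4` scores a smaller focus-variable RMSE
than eliminating all three intermediates, ranking it first.

Other bundled examples (`cr.zoo_names()`): a bistable Hill-regulated system
and its exact power-law recast, the four-layer Goodwin oscillator in recast
form (free Hill exponent), the Roessler chaotic and hyperchaotic
oscillators, a mass-action cascade for artificial time scaling, and seeded
random S-system/LV generators (`canonred.synthgen`) for property testing.

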