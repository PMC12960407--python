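"""Nullcline-based, format-preserving model reduction.

The reduction replaces selected ODEs by the closed-form solutions of their
nullclines (derivative set to zero) and substitutes those solutions
*symbolically* into the remaining equations.  For S-systems the nullcline of
variable ``k`` is the power product

    X_k = ((beta_k/alpha_k) * prod_{j != k} X_j**(h_kj - g_kj))**(1/(g_kk - h_kk)),

so substitution followed by canonical normalization yields again an
S-system.  For Lotka-Volterra models the nullcline is affine,

    X_k = -a_k/b_kk - sum_{j != k} (b_kj/b_kk) * X_j,

and substitution redefines the parameters as

    a~_i = a_i - a_k*b_ik/b_kk,    b~_ij = b_ij - b_ik*b_kj/b_kk,

which retains the LV format.  GMA and general models are reduced whenever
their nullcline admits a closed form (two aggregate power terms, or an
equation affine/rational-linear in the eliminated variable); the result may
leave the canonical class, in which case it is downgraded to a general
expression model with a warning.

Eliminated variables live on as algebraic "add-ons": explicit functions of
the retained state that are evaluated along trajectories but never
integrated.  No time-scale separation is assumed anywhere -- setting a
derivative to zero is an approximation whose quality is assessed by
simulation, not an asymptotic limit.

Recast auxiliaries (variables introduced to write a Hill term in power-law
form, carrying a defining constraint ``A = phi(X_reg)``) get special
treatment, because their ODE is the chain-rule image of the regulator's and
never contains the auxiliary itself.  The nullcline ``dA/dt = 0`` is
equivalent to the regulator's nullcline, so eliminating an auxiliary slaves
it to the constraint evaluated at the regulator's nullcline value.
Conversely, eliminating the *regulator* makes the auxiliary's ODE vanish
identically; the auxiliary is then slaved automatically through its
constraint and reported in the elimination record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

from .errors import (
    AlreadyDecoupled,
    CannotCollapse,
    CyclicDependency,
    NotReducible,
    NotSolvable,
    SingularElimination,
    ValidationError,
)
from .expressions import as_power_product, sym
from .model_core import (
    GMAModel,
    GeneralODEModel,
    LVModel,
    PowerLawTerm,
    SSystemModel,
)

__all__ = [
    "NullclineSolution",
    "ReducedModel",
    "solve_nullcline",
    "solve_nullcline_ssystem",
    "solve_nullcline_lv",
    "solve_nullcline_general",
    "substitute",
    "reduce",
    "reduce_lv",
    "collapse_numeric",
]


def _flatten(expr: sp.Expr) -> sp.Expr:
    return sp.powsimp(
        sp.expand_power_base(sp.powdenest(expr, force=True), force=True),
        force=True,
        combine="exp",
    )


@dataclass
class NullclineSolution:
    """Closed-form solution of one nullcline: ``variable = expr`` over
    retained variables and symbolic parameters."""

    variable: str
    expr: sp.Expr
    kind: str  # power_product | affine | rational | other
    validity: str = ""

    def __post_init__(self):
        self.expr = sp.sympify(self.expr)
        if self.kind not in {"power_product", "affine", "rational", "other"}:
            raise ValidationError(f"unknown solution kind {self.kind!r}")

    def references(self) -> set[str]:
        return {s.name for s in self.expr.free_symbols}


@dataclass
class ReducedModel:
    """Retained ODE system plus algebraic add-ons and an elimination record."""

    model: object  # SSystemModel | GMAModel | LVModel | GeneralODEModel
    addons: dict[str, NullclineSolution]
    elimination_record: list[str]
    parent: object
    warnings: list[str] = field(default_factory=list)

    # Convenience delegation so dynamics/analysis treat ReducedModel like a model
    @property
    def dependent(self):
        return self.model.dependent

    @property
    def independent(self):
        return self.model.independent

    @property
    def parameters(self):
        return self.model.parameters

    @property
    def initial(self):
        return self.model.initial

    @property
    def n(self):
        return self.model.n

    def rhs_exprs(self):
        return self.model.rhs_exprs()

    def addon_exprs(self) -> dict[str, sp.Expr]:
        return {k: s.expr for k, s in self.addons.items()}

    def check_partition(self):
        retained = set(self.model.dependent)
        eliminated = set(self.addons)
        parent_dep = set(self.parent.dependent)
        if retained | eliminated != parent_dep or retained & eliminated:
            raise ValidationError(
                "retained + eliminated variables do not partition the parent's "
                f"dependent set: retained={sorted(retained)}, "
                f"eliminated={sorted(eliminated)}"
            )


# ---------------------------------------------------------------------------
# Nullcline solvers
# ---------------------------------------------------------------------------


def _variable_appears(model, k: str) -> bool:
    xk = sym(k)
    return any(xk in expr.free_symbols for expr in model.rhs_exprs().values())


def solve_nullcline_ssystem(model: SSystemModel, k: str) -> NullclineSolution:
    """Solve the k-th S-system nullcline in closed power-product form."""
    if k in model.aux_constraints:
        return _aux_solution(model, k)
    if k not in model.dependent:
        raise ValidationError(f"{k!r} is not a dependent variable")
    prod, deg = model.production[k], model.degradation[k]
    d = prod.exponent(k) - deg.exponent(k)
    if sp.simplify(d) == 0:
        if not _variable_appears(model, k):
            raise AlreadyDecoupled(k, "variable appears in no equation")
        raise NotReducible(
            k, "g_kk equals h_kk: the ODE cannot be solved for its own variable"
        )
    inner = deg.rate / prod.rate
    names = set(model.dependent) | set(model.independent)
    for j in names:
        if j == k:
            continue
        e = deg.exponent(j) - prod.exponent(j)
        if e != 0:
            inner *= sym(j) ** e
    expr = _flatten(inner ** (1 / d))
    return NullclineSolution(k, expr, "power_product", "positive orthant")


def solve_nullcline_lv(model: LVModel, k: str) -> NullclineSolution:
    """Affine LV nullcline: X_k = -a_k/b_kk - sum_{j != k} (b_kj/b_kk) X_j."""
    if k not in model.dependent:
        raise ValidationError(f"{k!r} is not a dependent variable")
    i = model.dependent.index(k)
    bkk = model.interaction[i][i]
    if _is_zero(bkk, model):
        raise NotReducible(k, "self-interaction b_kk is zero")
    expr = -model.growth[i] / bkk
    for j, w in enumerate(model.dependent):
        if j == i:
            continue
        bkj = model.interaction[i][j]
        if bkj != 0:
            expr -= (bkj / bkk) * sym(w)
    return NullclineSolution(k, expr, "affine", "X_k > 0 on the solution branch")


def _is_zero(expr, model) -> bool:
    expr = sp.sympify(expr)
    if expr.is_number:
        return expr == 0
    vals = model.parameter_values()
    subbed = expr.subs(vals)
    if subbed.is_number:
        return abs(float(subbed)) == 0.0
    return bool(sp.simplify(expr) == 0)


def solve_nullcline_general(model, k: str) -> NullclineSolution:
    """Closed-form nullcline for GMA/general models.

    Strategy (a): collect the equation into two aggregate power terms in
    X_k (S-system-like).  Strategy (b): equations affine or rational-linear
    in X_k.  Tried in that order; anything else is refused -- there is no
    numeric fallback.
    """
    if k in model.aux_constraints:
        return _aux_solution(model, k)
    if k not in model.dependent:
        raise ValidationError(f"{k!r} is not a dependent variable")
    xk = sym(k)
    f = model.rhs_exprs()[k]
    if xk not in f.free_symbols:
        if not _variable_appears(model, k):
            raise AlreadyDecoupled(k, "variable appears in no equation")
        raise NotReducible(k, "equation does not contain its own variable")

    # (a) two aggregate power terms
    terms = sp.Add.make_args(sp.expand(f))
    with_k = [t for t in terms if xk in t.free_symbols]
    without_k = [t for t in terms if xk not in t.free_symbols]
    sol = _two_term_power_solve(xk, with_k, without_k, model)
    if sol is not None:
        return NullclineSolution(k, sol, _classify_kind(sol, model), "positive orthant")

    # (b) affine / rational-linear in X_k
    num, _den = sp.fraction(sp.together(f))
    try:
        poly = sp.Poly(sp.expand(num), xk)
    except sp.PolynomialError:
        poly = None
    if poly is not None and poly.degree() == 1:
        c1 = poly.coeff_monomial(xk)
        c0 = poly.coeff_monomial(1)
        expr = sp.together(-c0 / c1)
        kind = "affine" if c1.is_number or not (
            c1.free_symbols & {sym(v) for v in model.dependent + model.independent}
        ) else "rational"
        validity = ""
        if kind == "rational":
            validity = f"denominator {sp.sstr(c1)} != 0"
        return NullclineSolution(k, expr, kind, validity)

    raise NotSolvable(
        k, "nullcline admits no closed form (neither two-power-term nor linear)"
    )


def _two_term_power_solve(xk, with_k, without_k, model):
    """A*X_k**p = -B  with A, B power products free of X_k."""
    if not with_k or not without_k:
        return None
    variables = list(model.dependent) + list(model.independent)
    grouped = sp.powsimp(sp.factor_terms(sp.Add(*with_k)), force=True)
    coeff_free, kpart = grouped.as_independent(xk)
    base, p = kpart.as_base_exp()
    if base != xk:
        return None
    if as_power_product(coeff_free, variables) is None:
        return None
    rest = sp.powsimp(sp.factor_terms(sp.Add(*without_k)), force=True)
    if as_power_product(rest, variables) is None:
        return None
    #  coeff_free * xk**p + rest = 0
    return _flatten((-rest / coeff_free) ** (1 / p))


def _classify_kind(expr, model) -> str:
    variables = list(model.dependent) + list(model.independent)
    if as_power_product(expr, variables) is not None:
        return "power_product"
    return "other"


def _aux_solution(model, k: str) -> NullclineSolution:
    """Nullcline of a recast auxiliary: the constraint evaluated at the
    regulator's own nullcline value."""
    constraint = model.aux_constraints[k]
    regulators = [
        v for v in model.dependent if sym(v) in constraint.free_symbols and v != k
    ]
    if len(regulators) != 1:
        raise NotReducible(
            k, f"auxiliary constraint must have one dynamic regulator, got {regulators}"
        )
    reg = regulators[0]
    reg_sol = solve_nullcline(model, reg)
    if k in reg_sol.references():
        raise CyclicDependency(
            f"regulator {reg!r} nullcline references auxiliary {k!r}; "
            "solve simultaneously"
        )
    expr = constraint.subs(sym(reg), reg_sol.expr)
    return NullclineSolution(
        k, expr, "other", f"auxiliary slaved through its constraint via {reg!r}"
    )


def solve_nullcline(model, k: str) -> NullclineSolution:
    """Dispatch on the model class."""
    if isinstance(model, ReducedModel):
        model = model.model
    if k in getattr(model, "aux_constraints", {}):
        return _aux_solution(model, k)
    if isinstance(model, SSystemModel):
        return solve_nullcline_ssystem(model, k)
    if isinstance(model, LVModel):
        return solve_nullcline_lv(model, k)
    return solve_nullcline_general(model, k)


# ---------------------------------------------------------------------------
# Substitution
# ---------------------------------------------------------------------------


def substitute(model, solutions) -> ReducedModel:
    """Replace every occurrence of each eliminated variable by its nullcline
    expression; the eliminated equations become algebraic add-ons.

    The canonical class is preserved when all solutions are power products
    (S-system/GMA) or affine (LV); otherwise the result is downgraded to a
    general expression model with a warning.  Solutions must not reference
    each other -- resolve first via :func:`reduce` with ``simultaneous=True``.
    """
    if isinstance(solutions, NullclineSolution):
        solutions = [solutions]
    solutions = list(solutions)
    eliminated = [s.variable for s in solutions]
    for s in solutions:
        if s.variable not in model.dependent:
            raise ValidationError(
                f"{s.variable!r} is not a dependent variable of the model"
            )
        mutual = set(eliminated) & (s.references() - {s.variable})
        if mutual:
            raise CyclicDependency(
                f"solution for {s.variable!r} references eliminated "
                f"{sorted(mutual)}; use reduce(..., simultaneous=True)"
            )

    warnings: list[str] = []
    retained = [v for v in model.dependent if v not in eliminated]
    if not retained:
        raise ValidationError("cannot eliminate every dependent variable")
    submap = {sym(s.variable): s.expr for s in solutions}

    if isinstance(model, SSystemModel):
        reduced = _substitute_power_law(model, retained, submap, warnings)
    elif isinstance(model, GMAModel):
        reduced = _substitute_power_law(model, retained, submap, warnings)
    elif isinstance(model, LVModel):
        reduced = _substitute_lv(model, retained, solutions, warnings)
    else:
        reduced = _substitute_general(model, retained, submap)

    addons = {s.variable: s for s in solutions}
    out = ReducedModel(reduced, addons, list(eliminated), model, warnings)
    _auto_slave_degenerate_auxiliaries(out)
    out.check_partition()
    return out


def _prune_fields(model, retained):
    initial = {v: model.initial[v] for v in retained + list(model.independent)}
    aux = {v: c for v, c in model.aux_constraints.items() if v in retained}
    return initial, aux


def _substitute_power_law(model, retained, submap, warnings):
    """Term-by-term substitution for S-system/GMA; falls back to a general
    model when a substituted term leaves the power-law family."""
    variables = retained + list(model.independent)
    all_ok = True
    new_terms: dict[str, list[PowerLawTerm]] = {}
    for v in retained:
        terms = []
        for term in model.terms(v):
            expr = term.unsigned_expression().subs(submap)
            pp = as_power_product(expr, variables)
            if pp is None:
                all_ok = False
                break
            coeff, exponents = pp
            terms.append(PowerLawTerm(term.sign, coeff, exponents))
        if not all_ok:
            break
        new_terms[v] = terms
    initial, aux = _prune_fields(model, retained)
    if all_ok:
        if isinstance(model, SSystemModel):
            return SSystemModel(
                dependent=retained,
                independent=list(model.independent),
                production={v: new_terms[v][0] for v in retained},
                degradation={v: new_terms[v][1] for v in retained},
                parameters=dict(model.parameters),
                initial=initial,
                aux_constraints=aux,
                metadata=dict(model.metadata),
            )
        return GMAModel(
            dependent=retained,
            independent=list(model.independent),
            term_lists=new_terms,
            parameters=dict(model.parameters),
            initial=initial,
            aux_constraints=aux,
            metadata=dict(model.metadata),
        )
    warnings.append(
        "substitution left the power-law family; result downgraded to a "
        "general expression model"
    )
    return _substitute_general(model, retained, submap)


def _substitute_general(model, retained, submap):
    rhs = {v: model.rhs_exprs()[v].subs(submap) for v in retained}
    initial, aux = _prune_fields(model, retained)
    return GeneralODEModel(
        dependent=retained,
        independent=list(model.independent),
        rhs=rhs,
        parameters=dict(model.parameters),
        initial=initial,
        aux_constraints=aux,
        metadata=dict(model.metadata),
    )


def _substitute_lv(model, retained, solutions, warnings):
    """Affine substitution redefines LV parameters and retains the format."""
    for s in solutions:
        if s.kind != "affine":
            warnings.append(
                f"solution for {s.variable!r} is {s.kind}, not affine; "
                "result downgraded to a general expression model"
            )
            submap = {sym(t.variable): t.expr for t in solutions}
            return _substitute_general(model, retained, submap)
    # X_k = c_k0 + sum_j c_kj X_j  for each eliminated k
    coeffs = {}
    for s in solutions:
        c0 = s.expr
        cj = {}
        for w in retained:
            cj[w] = sp.expand(s.expr).coeff(sym(w), 1)
            c0 = c0 - cj[w] * sym(w)
        c0 = sp.simplify(c0)
        if c0.free_symbols & {sym(w) for w in model.dependent}:
            warnings.append(
                f"solution for {s.variable!r} is not affine in the retained "
                "variables; result downgraded to a general expression model"
            )
            submap = {sym(t.variable): t.expr for t in solutions}
            return _substitute_general(model, retained, submap)
        coeffs[s.variable] = (c0, cj)
    idx = {v: i for i, v in enumerate(model.dependent)}
    growth, interaction = [], []
    for v in retained:
        i = idx[v]
        a_i = model.growth[i]
        row = {w: model.interaction[i][idx[w]] for w in retained}
        for k, (c0, cj) in coeffs.items():
            b_ik = model.interaction[i][idx[k]]
            a_i = a_i + b_ik * c0
            for w in retained:
                row[w] = row[w] + b_ik * cj[w]
        growth.append(sp.together(a_i))
        interaction.append([sp.together(row[w]) for w in retained])
    initial, aux = _prune_fields(model, retained)
    return LVModel(
        dependent=retained,
        growth=growth,
        interaction=interaction,
        parameters=dict(model.parameters),
        initial=initial,
        aux_constraints=aux,
        metadata=dict(model.metadata),
    )


def _auto_slave_degenerate_auxiliaries(reduced: ReducedModel):
    """After eliminating a regulator, a recast auxiliary's ODE vanishes
    identically; slave it through its constraint instead of integrating a
    frozen variable."""
    while True:
        model = reduced.model
        target = None
        for v in model.dependent:
            if v in model.aux_constraints and sp.simplify(model.rhs_exprs()[v]) == 0:
                target = v
                break
        if target is None:
            return
        constraint = model.aux_constraints[target]
        expr = constraint.subs({sym(k): s.expr for k, s in reduced.addons.items()})
        sol = NullclineSolution(
            target, expr, "other", "auxiliary slaved after its regulator was eliminated"
        )
        inner = substitute(model, [sol])
        reduced.model = inner.model
        reduced.addons.update(inner.addons)
        reduced.elimination_record.extend(inner.elimination_record)
        reduced.warnings.extend(inner.warnings)
        reduced.warnings.append(
            f"auxiliary {target!r} became degenerate and was slaved to its constraint"
        )


# ---------------------------------------------------------------------------
# Full reduction driver
# ---------------------------------------------------------------------------


def reduce(model, eliminate, simultaneous: bool = False) -> ReducedModel:
    """Eliminate a set of variables, sequentially (each elimination operates
    on the already-reduced model) or simultaneously (joint nullcline solve).

    Both routes agree wherever both apply: eliminating a set of variables in
    any order leads to the same reduced model.
    """
    if isinstance(model, ReducedModel):
        raise ValidationError("reduce() expects an unreduced model")
    order = list(eliminate)
    unknown = set(order) - set(model.dependent)
    if unknown:
        raise ValidationError(f"cannot eliminate non-dependent variables {sorted(unknown)}")
    if not order:
        return ReducedModel(model, {}, [], model, [])

    if simultaneous:
        solutions = _joint_solve(model, order)
        return substitute(model, solutions)

    current = model
    addons: dict[str, NullclineSolution] = {}
    record: list[str] = []
    warnings: list[str] = []
    for k in order:
        if k in addons:  # auto-slaved by an earlier step
            continue
        sol = solve_nullcline(current, k)
        step = substitute(current, [sol])
        stepmap = {sym(v): s.expr for v, s in step.addons.items()}
        for name, old in addons.items():
            addons[name] = replace(old, expr=old.expr.subs(stepmap))
        addons.update(step.addons)
        record.extend(step.elimination_record)
        warnings.extend(step.warnings)
        current = step.model
    out = ReducedModel(current, addons, record, model, warnings)
    _resolve_addons(out)
    out.check_partition()
    return out


def _resolve_addons(reduced: ReducedModel):
    """Iterate substitution until add-ons reference only retained variables."""
    eliminated = set(reduced.addons)
    for _ in range(len(eliminated) + 1):
        submap = {sym(v): s.expr for v, s in reduced.addons.items()}
        dirty = False
        for name, s in reduced.addons.items():
            refs = s.references() & eliminated
            if refs:
                reduced.addons[name] = replace(s, expr=s.expr.subs(submap))
                dirty = True
        if not dirty:
            return
    raise CyclicDependency(
        "add-on expressions could not be resolved to retained variables"
    )


def _joint_solve(model, eliminate) -> list[NullclineSolution]:
    """Solve the joint nullcline system of the eliminated block."""
    aux = [k for k in eliminate if k in getattr(model, "aux_constraints", {})]
    core = [k for k in eliminate if k not in aux]
    if isinstance(model, SSystemModel):
        solutions = _joint_solve_ssystem(model, core)
    elif isinstance(model, LVModel):
        solutions = _joint_solve_lv(model, core)
    else:
        solutions = _joint_solve_general(model, core)
    by_name = {s.variable: s for s in solutions}
    submap = {sym(v): s.expr for v, s in by_name.items()}
    for k in aux:
        constraint = model.aux_constraints[k]
        regs = [v for v in model.dependent if sym(v) in constraint.free_symbols and v != k]
        if len(regs) != 1:
            raise NotReducible(k, "auxiliary constraint must have one regulator")
        reg = regs[0]
        if reg in by_name:
            expr = constraint.subs(sym(reg), by_name[reg].expr)
        else:
            expr = _aux_solution(model, k).expr
        by_name[k] = NullclineSolution(
            k, expr.subs(submap), "other", "auxiliary slaved through its constraint"
        )
    ordered = [by_name[k] for k in eliminate]
    # resolve any remaining cross-references among core solutions
    tmp = ReducedModel(model, {s.variable: s for s in ordered}, list(eliminate), model)
    _resolve_addons(tmp)
    return [tmp.addons[k] for k in eliminate]


def _joint_solve_ssystem(model: SSystemModel, core) -> list[NullclineSolution]:
    """Log-linear solve of the eliminated block: guarantees power products."""
    if not core:
        return []
    retained = [v for v in model.dependent if v not in core] + list(model.independent)
    m = len(core)
    A = sp.zeros(m, m)
    targets = []  # target_l = (beta_l/alpha_l) * prod_{j retained} X_j**(h_lj-g_lj)
    for r, k in enumerate(core):
        prod, deg = model.production[k], model.degradation[k]
        for c, j in enumerate(core):
            A[r, c] = prod.exponent(j) - deg.exponent(j)
        t = deg.rate / prod.rate
        for j in retained:
            e = deg.exponent(j) - prod.exponent(j)
            if e != 0:
                t *= sym(j) ** e
        targets.append(t)
    det = sp.simplify(A.det())
    if det == 0:
        raise SingularElimination(
            f"joint log-linear system of {core} is singular (det = 0)"
        )
    _condition_warning(A, model)
    Ainv = A.inv()
    solutions = []
    for r, k in enumerate(core):
        expr = sp.Integer(1)
        for l in range(m):
            w = Ainv[r, l]
            if w != 0:
                expr *= targets[l] ** w
        solutions.append(
            NullclineSolution(k, _flatten(expr), "power_product", "positive orthant")
        )
    return solutions


def _condition_warning(A: sp.Matrix, model):
    vals = model.parameter_values()
    try:
        M = np.array(
            [[float(sp.sympify(a).subs(vals)) for a in A.row(i)] for i in range(A.rows)]
        )
    except (TypeError, ValueError):
        return
    if M.size and np.linalg.cond(M) > 1e12:
        import warnings as _w

        _w.warn(
            "joint elimination system is near-singular "
            f"(condition number {np.linalg.cond(M):.2e})",
            stacklevel=3,
        )


def _joint_solve_lv(model: LVModel, core) -> list[NullclineSolution]:
    """Affine linear solve: B_EE x_E = -a_E - B_ER x_R."""
    if not core:
        return []
    idx = {v: i for i, v in enumerate(model.dependent)}
    retained = [v for v in model.dependent if v not in core]
    m = len(core)
    B = sp.Matrix(m, m, lambda r, c: model.interaction[idx[core[r]]][idx[core[c]]])
    rhs = []
    for k in core:
        i = idx[k]
        e = -model.growth[i]
        for w in retained:
            e -= model.interaction[i][idx[w]] * sym(w)
        rhs.append(e)
    det = sp.simplify(B.det())
    if det == 0:
        raise SingularElimination(f"joint affine system of {core} is singular")
    _condition_warning(B, model)
    x = B.LUsolve(sp.Matrix(rhs))
    return [
        NullclineSolution(k, sp.together(sp.expand(x[r])), "affine", "")
        for r, k in enumerate(core)
    ]


def _joint_solve_general(model, core) -> list[NullclineSolution]:
    """Individual solves with cross-references, resolved by substitution;
    genuinely cyclic blocks are attempted with a simultaneous symbolic solve."""
    solutions = {}
    for k in core:
        solutions[k] = solve_nullcline(model, k)
    # detect cycles among the core block
    try:
        tmp = ReducedModel(model, dict(solutions), list(core), model)
        _resolve_addons(tmp)
        return [tmp.addons[k] for k in core]
    except CyclicDependency:
        pass
    eqs = [model.rhs_exprs()[k] for k in core]
    sols = sp.solve(eqs, [sym(k) for k in core], dict=True)
    if not sols:
        raise NotSolvable(
            ",".join(core), "cyclic nullcline block has no closed-form solution"
        )
    chosen = sols[0]
    return [
        NullclineSolution(k, chosen[sym(k)], "other", "joint symbolic solve")
        for k in core
    ]


# ---------------------------------------------------------------------------
# LV single-variable reduction (closed formulas)
# ---------------------------------------------------------------------------


def reduce_lv(model: LVModel, k: str) -> LVModel:
    """Eliminate one LV variable via the closed parameter-update formulas
    (a~_i = a_i - a_k*b_ik/b_kk, b~_ij = b_ij - b_ik*b_kj/b_kk)."""
    sol = solve_nullcline_lv(model, k)
    return substitute(model, [sol]).model


# ---------------------------------------------------------------------------
# Numeric collapse
# ---------------------------------------------------------------------------

_COLLAPSE_WARNING = (
    "parameter combinations were collapsed to numbers; targeted changes in "
    "individual parameter values are no longer possible"
)


def collapse_numeric(reduced):
    """Fold every symbolic parameter composition into a single numeric rate
    constant (and numeric exponents).

    Works on a :class:`ReducedModel` or a bare model.  Refuses structure-only
    models (unbound parameters).
    """
    if isinstance(reduced, ReducedModel):
        model = reduced.model
        new_model = _collapse_model(model)
        addons = {
            k: replace(s, expr=_collapse_expr(s.expr, model))
            for k, s in reduced.addons.items()
        }
        return ReducedModel(
            new_model,
            addons,
            list(reduced.elimination_record),
            reduced.parent,
            reduced.warnings + [_COLLAPSE_WARNING],
        )
    out = _collapse_model(reduced)
    out.metadata["collapse_warning"] = _COLLAPSE_WARNING
    return out


def _require_bound(model):
    unbound = [p.name for p in model.parameters.values() if p.value is None]
    if unbound:
        raise CannotCollapse(
            f"parameters {unbound} have no numeric binding (structure-only model)"
        )


def _collapse_expr(expr, model):
    vals = model.parameter_values()
    out = sp.sympify(expr).subs(vals)
    bad = {s.name for s in out.free_symbols} - set(model.dependent) - set(model.independent)
    if bad:
        raise CannotCollapse(f"parameters {sorted(bad)} have no numeric binding")
    return sp.nfloat(out, n=15)


def _collapse_term(term: PowerLawTerm, model) -> PowerLawTerm:
    vals = model.parameter_values()
    rate = term.rate.subs(vals)
    if rate.free_symbols:
        raise CannotCollapse(
            f"rate {term.rate} has unbound parameters {sorted(map(str, rate.free_symbols))}"
        )
    exponents = {}
    for v, e in term.exponents.items():
        e2 = sp.sympify(e).subs(vals)
        if e2.free_symbols:
            raise CannotCollapse(f"exponent {e} has unbound parameters")
        if e2 != 0:
            exponents[v] = e2
    return PowerLawTerm(term.sign, sp.Float(float(rate), 15), exponents)


def _collapse_model(model):
    _require_bound(model)
    if isinstance(model, SSystemModel):
        return model.with_updates(
            production={v: _collapse_term(t, model) for v, t in model.production.items()},
            degradation={v: _collapse_term(t, model) for v, t in model.degradation.items()},
            parameters={},
            aux_constraints={
                v: _collapse_expr(c, model) for v, c in model.aux_constraints.items()
            },
        )
    if isinstance(model, GMAModel):
        return model.with_updates(
            term_lists={
                v: [_collapse_term(t, model) for t in ts]
                for v, ts in model.term_lists.items()
            },
            parameters={},
            aux_constraints={
                v: _collapse_expr(c, model) for v, c in model.aux_constraints.items()
            },
        )
    if isinstance(model, LVModel):
        return model.with_updates(
            growth=[_collapse_expr(g, model) for g in model.growth],
            interaction=[[_collapse_expr(b, model) for b in row] for row in model.interaction],
            parameters={},
        )
    if isinstance(model, GeneralODEModel):
        return model.with_updates(
            rhs={v: _collapse_expr(e, model) for v, e in model.rhs.items()},
            parameters={},
            aux_constraints={
                v: _collapse_expr(c, model) for v, c in model.aux_constraints.items()
            },
        )
    raise ValidationError(f"cannot collapse model of class {model.model_class!r}")
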