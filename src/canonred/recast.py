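"""Exact recasting of Hill terms into power-law form.

A saturating Hill term -- repression ``k1*K**n/(K**n + X**n)`` or activation
``k1*X**n/(K**n + X**n)`` -- is not a power product, so models containing it
fall outside the canonical power-law classes.  Introducing the auxiliary
variable ``A = K**n + X**n`` restores the power-law form *exactly* (no
approximation): the Hill term becomes ``k1*K**n*A**-1`` (repression) or
``k1*X**n*A**-1`` (activation), and the auxiliary obeys the chain-rule ODE

    dA/dt = n*X**(n-1) * dX/dt,

expanded by substituting the regulator's right-hand side and distributing
into signed power-law terms.  The recast model carries the defining
constraint so analysis and reduction can work on the constraint manifold.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp

from .errors import ValidationError
from .expressions import as_power_product, exact, sym
from .model_core import (
    GMAModel,
    GeneralODEModel,
    PowerLawTerm,
    SSystemModel,
)

__all__ = ["HillTermSpec", "recast_hill"]


@dataclass
class HillTermSpec:
    """Location and parameters of one Hill term to recast.

    ``n`` may be a number or the name of a declared model parameter (so a
    family of models over the Hill exponent can be recast once).
    """

    equation: str
    k1: float
    K: float
    n: float | str
    regulator: str
    mode: str  # repression | activation
    aux_name: str | None = None

    def __post_init__(self):
        if self.mode not in ("repression", "activation"):
            raise ValidationError(f"Hill mode must be repression/activation, not {self.mode!r}")
        if not self.k1 > 0 or not self.K > 0:
            raise ValidationError("Hill parameters k1 and K must be positive")
        if not isinstance(self.n, str) and not self.n > 0:
            raise ValidationError("Hill exponent n must be positive")


def _terms_from_expr(expr, variables, param_values):
    """Split an expanded expression into signed power-law terms, or None."""
    terms = []
    for t in sp.Add.make_args(sp.expand(expr)):
        pp = as_power_product(t, variables)
        if pp is None:
            return None
        coeff, exponents = pp
        cval = sp.sympify(coeff).subs(param_values)
        if not cval.is_number:
            return None
        sign = 1 if float(cval) > 0 else -1
        terms.append(PowerLawTerm(sign, sign * coeff, exponents))
    return terms or None


def recast_hill(model: GeneralODEModel, spec: HillTermSpec):
    """Replace one Hill term by its exact power-law recast.

    Returns an :class:`SSystemModel` when every equation ends up with exactly
    one production and one degradation power-law term, a :class:`GMAModel`
    when all terms are power-law, and otherwise a :class:`GeneralODEModel`
    with a warning in its metadata (the regulator's RHS could not be
    distributed into signed power-law terms).
    """
    if spec.equation not in model.dependent:
        raise ValidationError(f"host equation {spec.equation!r} is not a dependent variable")
    if spec.regulator not in model.dependent:
        raise ValidationError(f"regulator {spec.regulator!r} is not a dependent variable")

    if isinstance(spec.n, str):
        if spec.n not in model.parameters:
            raise ValidationError(f"Hill exponent parameter {spec.n!r} is not declared")
        n = sym(spec.n)
        n_value = model.parameters[spec.n].value
    else:
        n = exact(spec.n)
        n_value = float(spec.n)
    K = exact(spec.K)
    k1 = exact(spec.k1)
    x = sym(spec.regulator)
    denom = K**n + x**n

    aux = spec.aux_name
    if aux is None:
        i = len(model.dependent) + 1
        while f"X{i}" in model.declared_names():
            i += 1
        aux = f"X{i}"
    if aux in model.declared_names():
        raise ValidationError(f"auxiliary name {aux!r} is already declared")
    A = sym(aux)

    rhs = model.rhs_exprs()
    host = rhs[spec.equation]
    new_host = host.subs(denom, A)
    if new_host == host:
        raise ValidationError(
            f"equation for {spec.equation!r} contains no Hill denominator "
            f"{sp.sstr(denom)}"
        )
    rhs = dict(rhs)
    rhs[spec.equation] = new_host
    # chain rule: dA/dt = n * X**(n-1) * dX/dt, with dX/dt substituted
    rhs[aux] = sp.expand(n * x ** (n - 1) * rhs[spec.regulator])

    dependent = list(model.dependent) + [aux]
    variables = dependent + list(model.independent)
    param_values = model.parameter_values()

    if n_value is None:
        raise ValidationError(
            "the Hill exponent must be numerically bound to compute the "
            "auxiliary initial value"
        )
    x0 = float(model.initial[spec.regulator])
    a0 = float(spec.K) ** n_value + x0**n_value
    initial = {**model.initial, aux: a0}
    aux_constraints = {**model.aux_constraints, aux: denom}
    metadata = {**model.metadata}
    metadata.setdefault("recast_regulator", {})
    metadata["recast_regulator"] = {
        **metadata["recast_regulator"],
        aux: spec.regulator,
    }
    parameters = dict(model.parameters)

    term_lists = {}
    power_law = True
    for v in dependent:
        terms = _terms_from_expr(rhs[v], variables, param_values)
        if terms is None:
            power_law = False
            break
        term_lists[v] = terms

    if not power_law:
        metadata["recast_warning"] = (
            "recast result is not a pure power-law system; returned as a "
            "general expression model"
        )
        return GeneralODEModel(
            dependent=dependent,
            independent=list(model.independent),
            rhs=rhs,
            parameters=parameters,
            initial=initial,
            aux_constraints=aux_constraints,
            metadata=metadata,
        )

    is_ssystem = all(
        len(ts) == 2 and {t.sign for t in ts} == {+1, -1} for ts in term_lists.values()
    )
    if is_ssystem:
        production = {v: next(t for t in ts if t.sign == +1) for v, ts in term_lists.items()}
        degradation = {v: next(t for t in ts if t.sign == -1) for v, ts in term_lists.items()}
        return SSystemModel(
            dependent=dependent,
            independent=list(model.independent),
            production=production,
            degradation=degradation,
            parameters=parameters,
            initial=initial,
            aux_constraints=aux_constraints,
            metadata=metadata,
        )
    return GMAModel(
        dependent=dependent,
        independent=list(model.independent),
        term_lists=term_lists,
        parameters=parameters,
        initial=initial,
        aux_constraints=aux_constraints,
        metadata=metadata,
    )
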