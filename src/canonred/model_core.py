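"""Canonical model classes and their core operations.

Three canonical ODE families are represented explicitly, following the
conventions of Biochemical Systems Theory (BST) and ecology:

* **S-system** -- each dependent variable has exactly one power-law
  production term and one power-law degradation term,
  ``dXi/dt = alpha_i * prod X_j**g_ij - beta_i * prod X_j**h_ij``.
* **GMA system** (generalized mass action) -- each process keeps its own
  signed power-law term.
* **Lotka-Volterra** -- ``dXi/dt = a_i*X_i + sum_j b_ij*X_i*X_j``.

A fourth class, :class:`GeneralODEModel`, holds arbitrary expression
right-hand sides (Hill-type models, chaotic oscillators, and downgraded
reduction results).

Parameters are named objects with numeric bindings kept *separate* from the
symbolic structure: reductions substitute symbolically, so rate constants of
reduced models become symbolic compositions of the original parameters while
their numeric values remain recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import sympy as sp

from .errors import DomainError, NormalizationError, ValidationError
from .expressions import as_power_product, exact, sym

__all__ = [
    "Parameter",
    "PowerLawTerm",
    "SSystemModel",
    "GMAModel",
    "LVModel",
    "GeneralODEModel",
    "evaluate_rhs",
    "canonical_normalize",
    "POSITIVITY_FLOOR",
]

#: States below this floor are treated as having left the positive orthant.
POSITIVITY_FLOOR = 1e-300

_ROLES = {"rate_constant", "kinetic_order", "lv_growth", "lv_interaction", "other"}


@dataclass
class Parameter:
    """A named model parameter with an optional numeric binding.

    ``value is None`` marks a structure-only parameter (e.g. a model whose
    rate constants were never published); such models can be manipulated
    symbolically but not simulated.
    """

    name: str
    value: Optional[float] = None
    role: str = "other"

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValidationError(f"unknown parameter role {self.role!r}")
        if (
            self.role == "rate_constant"
            and self.value is not None
            and self.value <= 0
        ):
            raise ValidationError(
                f"rate constant {self.name!r} must be strictly positive, "
                f"got {self.value}"
            )


@dataclass
class PowerLawTerm:
    """One signed power-law process ``sign * rate * prod X_j**e_j``.

    ``rate`` is a sympy expression over parameter symbols (a bare symbol for
    original models, a composition after reduction).  ``exponents`` maps
    variable names to exponent expressions; absent variables implicitly have
    exponent zero.
    """

    sign: int
    rate: sp.Expr
    exponents: dict[str, sp.Expr] = field(default_factory=dict)

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValidationError(f"term sign must be +1 or -1, got {self.sign}")
        self.rate = sp.sympify(self.rate)
        self.exponents = {v: exact(e) for v, e in self.exponents.items()}

    def expression(self) -> sp.Expr:
        expr = sp.Integer(self.sign) * self.rate
        for v, e in self.exponents.items():
            expr *= sym(v) ** e
        return expr

    def unsigned_expression(self) -> sp.Expr:
        return self.expression() * self.sign

    def exponent(self, variable: str) -> sp.Expr:
        return self.exponents.get(variable, sp.Integer(0))


def _check_unique(names):
    seen = set()
    for n in names:
        if n in seen:
            raise ValidationError(f"duplicate name {n!r}")
        seen.add(n)


class _ModelBase:
    """Shared plumbing: symbol tables, compiled RHS, Jacobians."""

    model_class: str = "abstract"

    dependent: list[str]
    independent: list[str]
    parameters: dict[str, Parameter]
    initial: dict[str, float]
    aux_constraints: dict[str, sp.Expr]
    metadata: dict

    # -- structure ---------------------------------------------------------

    def rhs_exprs(self) -> dict[str, sp.Expr]:
        raise NotImplementedError

    @property
    def n(self) -> int:
        return len(self.dependent)

    def declared_names(self) -> set[str]:
        return set(self.dependent) | set(self.independent) | set(self.parameters)

    def parameter_values(self) -> dict[sp.Symbol, float]:
        out = {}
        for p in self.parameters.values():
            if p.value is not None:
                out[sym(p.name)] = float(p.value)
        return out

    @property
    def structure_only(self) -> bool:
        return any(p.value is None for p in self.parameters.values())

    def independent_values(self) -> dict[sp.Symbol, float]:
        return {sym(v): float(self.initial[v]) for v in self.independent}

    def initial_state(self) -> np.ndarray:
        return np.array([float(self.initial[v]) for v in self.dependent])

    def _validate_symbols(self):
        declared = self.declared_names()
        for v, expr in self.rhs_exprs().items():
            unknown = {s.name for s in expr.free_symbols} - declared
            if unknown:
                raise ValidationError(
                    f"equation for {v!r} references undeclared symbols "
                    f"{sorted(unknown)}"
                )

    # -- domain ------------------------------------------------------------

    @property
    def requires_positive(self) -> bool:
        """Positive-orthant models: any fractional (non-integer) exponent on
        a variable makes negative states meaningless."""
        for expr in self.rhs_exprs().values():
            for p in expr.atoms(sp.Pow):
                base, e = p.as_base_exp()
                if base.is_Symbol and base.name in self.dependent:
                    if not (e.is_number and e.is_integer):
                        return True
        return False

    # -- numerics ----------------------------------------------------------

    def _arg_symbols(self):
        return (
            [sym(v) for v in self.dependent]
            + [sym(v) for v in self.independent]
            + [sym(p) for p in self.parameters]
        )

    def _compiled(self):
        cache = self.__dict__.get("_compiled_cache")
        if cache is None:
            args = self._arg_symbols()
            exprs = [self.rhs_exprs()[v] for v in self.dependent]
            f = sp.lambdify(args, exprs, modules="numpy")
            jac_mat = sp.Matrix(exprs).jacobian([sym(v) for v in self.dependent])
            j = sp.lambdify(args, jac_mat, modules="numpy")
            cache = (f, j)
            self.__dict__["_compiled_cache"] = cache
        return cache

    def _tail_args(self, overrides=None):
        """Numeric values for independent variables and parameters."""
        vals = []
        overrides = overrides or {}
        for v in self.independent:
            vals.append(float(overrides.get(v, self.initial[v])))
        for name, p in self.parameters.items():
            if name in overrides:
                vals.append(float(overrides[name]))
            elif p.value is not None:
                vals.append(float(p.value))
            else:
                raise ValidationError(
                    f"parameter {name!r} has no numeric binding; "
                    "structure-only models cannot be evaluated"
                )
        return vals

    def rhs_function(self, overrides=None):
        """Return ``f(t, x) -> dx/dt`` with current numeric bindings."""
        f, _ = self._compiled()
        tail = self._tail_args(overrides)
        positive = self.requires_positive

        def rhs(t, x):
            x = np.asarray(x, dtype=float)
            if positive and np.any(x < POSITIVITY_FLOOR):
                bad = [self.dependent[i] for i in np.where(x < POSITIVITY_FLOOR)[0]]
                raise DomainError(
                    f"state left the positive orthant in {bad} "
                    "(power-law model with fractional kinetic orders)"
                )
            return np.asarray(f(*x, *tail), dtype=float)

        return rhs

    def jacobian_function(self, overrides=None):
        _, j = self._compiled()
        tail = self._tail_args(overrides)

        def jac(x):
            x = np.asarray(x, dtype=float)
            return np.asarray(j(*x, *tail), dtype=float)

        return jac

    # -- copies ------------------------------------------------------------

    def with_updates(self, **changes):
        """Shallow functional update (dataclasses.replace semantics)."""
        import dataclasses

        new = dataclasses.replace(self, **changes)
        return new


@dataclass
class SSystemModel(_ModelBase):
    """S-system: one production and one degradation power-law term per
    dependent variable."""

    dependent: list[str]
    independent: list[str]
    production: dict[str, PowerLawTerm]
    degradation: dict[str, PowerLawTerm]
    parameters: dict[str, Parameter]
    initial: dict[str, float]
    aux_constraints: dict[str, sp.Expr] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    model_class = "ssystem"

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("an S-system needs at least one dependent variable")
        _check_unique(self.dependent + self.independent)
        for v in self.dependent:
            if v not in self.production or v not in self.degradation:
                raise ValidationError(
                    f"dependent variable {v!r} needs exactly one production and "
                    "one degradation term"
                )
            if self.production[v].sign != +1 or self.degradation[v].sign != -1:
                raise ValidationError(
                    f"S-system terms for {v!r} must be signed (+ production, "
                    "- degradation)"
                )
        self._validate_symbols()

    def rhs_exprs(self) -> dict[str, sp.Expr]:
        return {
            v: self.production[v].expression() + self.degradation[v].expression()
            for v in self.dependent
        }

    def terms(self, v: str) -> list[PowerLawTerm]:
        return [self.production[v], self.degradation[v]]


@dataclass
class GMAModel(_ModelBase):
    """Generalized mass action system: a list of signed power-law terms per
    dependent variable."""

    dependent: list[str]
    independent: list[str]
    term_lists: dict[str, list[PowerLawTerm]]
    parameters: dict[str, Parameter]
    initial: dict[str, float]
    aux_constraints: dict[str, sp.Expr] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    model_class = "gma"

    def __post_init__(self):
        _check_unique(self.dependent + self.independent)
        for v in self.dependent:
            if not self.term_lists.get(v):
                raise ValidationError(f"equation for {v!r} needs at least one term")
        self._validate_symbols()

    def rhs_exprs(self) -> dict[str, sp.Expr]:
        return {
            v: sp.Add(*[t.expression() for t in self.term_lists[v]])
            for v in self.dependent
        }

    def terms(self, v: str) -> list[PowerLawTerm]:
        return list(self.term_lists[v])


@dataclass
class LVModel(_ModelBase):
    """Lotka-Volterra model.

    ``growth`` and ``interaction`` hold sympy expressions (bare parameter
    symbols for freshly built models, compositions after reduction); numeric
    values come from the parameter table.  Entries may be numeric literals.
    """

    dependent: list[str]
    growth: list[sp.Expr]
    interaction: list[list[sp.Expr]]
    parameters: dict[str, Parameter]
    initial: dict[str, float]
    independent: list[str] = field(default_factory=list)
    aux_constraints: dict[str, sp.Expr] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    model_class = "lv"

    def __post_init__(self):
        n = self.n
        _check_unique(self.dependent)
        if len(self.growth) != n or len(self.interaction) != n or any(
            len(row) != n for row in self.interaction
        ):
            raise ValidationError(
                "LV growth vector and interaction matrix must match the "
                f"variable count ({n})"
            )
        self.growth = [sp.sympify(g) for g in self.growth]
        self.interaction = [[sp.sympify(b) for b in row] for row in self.interaction]
        self._validate_symbols()

    def rhs_exprs(self) -> dict[str, sp.Expr]:
        out = {}
        for i, v in enumerate(self.dependent):
            xi = sym(v)
            expr = self.growth[i] * xi
            for j, w in enumerate(self.dependent):
                expr += self.interaction[i][j] * xi * sym(w)
            out[v] = expr
        return out

    def growth_values(self) -> np.ndarray:
        vals = self.parameter_values()
        return np.array([float(sp.sympify(g).subs(vals)) for g in self.growth])

    def interaction_values(self) -> np.ndarray:
        vals = self.parameter_values()
        return np.array(
            [[float(sp.sympify(b).subs(vals)) for b in row] for row in self.interaction]
        )


@dataclass
class GeneralODEModel(_ModelBase):
    """Arbitrary expression-tree right-hand sides (non-canonical sources and
    downgraded reduction results)."""

    dependent: list[str]
    independent: list[str]
    rhs: dict[str, sp.Expr]
    parameters: dict[str, Parameter]
    initial: dict[str, float]
    aux_constraints: dict[str, sp.Expr] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    model_class = "general"

    def __post_init__(self):
        _check_unique(self.dependent + self.independent)
        self.rhs = {v: sp.sympify(e) for v, e in self.rhs.items()}
        missing = set(self.dependent) - set(self.rhs)
        if missing:
            raise ValidationError(f"missing right-hand sides for {sorted(missing)}")
        self._validate_symbols()

    def rhs_exprs(self) -> dict[str, sp.Expr]:
        return dict(self.rhs)


CanonicalModel = SSystemModel | GMAModel | LVModel | GeneralODEModel


def evaluate_rhs(model, state, t: float = 0.0) -> np.ndarray:
    """Evaluate the derivative vector at ``state`` (ordered as
    ``model.dependent``)."""
    from .reduction import ReducedModel  # local import to avoid cycle

    if isinstance(model, ReducedModel):
        model = model.model
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n,):
        raise ValidationError(
            f"state dimension {state.shape} does not match n={model.n}"
        )
    return model.rhs_function()(t, state)


def _normalize_term(term: PowerLawTerm, variables) -> PowerLawTerm:
    pp = as_power_product(term.unsigned_expression(), variables)
    if pp is None:
        raise NormalizationError(
            f"term {term.unsigned_expression()} is not a power product"
        )
    coeff, exponents = pp
    return PowerLawTerm(sign=term.sign, rate=coeff, exponents=exponents)


def canonical_normalize(model):
    """Merge repeated variables within each term and compose nested rate
    constants, so substitution results re-enter canonical form.

    Numerically neutral: the RHS values are unchanged.  Idempotent.
    """
    variables = list(model.dependent) + list(model.independent)
    if isinstance(model, SSystemModel):
        production = {v: _normalize_term(t, variables) for v, t in model.production.items()}
        degradation = {v: _normalize_term(t, variables) for v, t in model.degradation.items()}
        return model.with_updates(production=production, degradation=degradation)
    if isinstance(model, GMAModel):
        term_lists = {
            v: [_normalize_term(t, variables) for t in ts]
            for v, ts in model.term_lists.items()
        }
        return model.with_updates(term_lists=term_lists)
    raise ValidationError(
        f"canonical_normalize applies to S-systems and GMA systems, "
        f"not {model.model_class!r}"
    )
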