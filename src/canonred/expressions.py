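"""Symbolic expression helpers.

Right-hand sides, power-law terms and nullcline solutions are all plain
:mod:`sympy` expressions over named symbols (one symbol per variable or
parameter).  This module centralizes symbol creation, exact handling of
decimal exponents, the "power product" predicate that decides whether an
expression still fits the canonical power-law shape ``c * prod X_j**e_j``,
and the infix grammar used by the JSON model documents.

Kinetic orders printed as decimals (0.8, 2.5, ...) are stored as exact
rationals so that exponent arithmetic such as ``2.5 * 0.4 == 1`` holds
symbolically, not merely to rounding error.  Rate-constant *values* remain
ordinary floats; only the structure is exact.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from numbers import Real

import numpy as np
import sympy as sp
from sympy.parsing.sympy_parser import parse_expr

from .errors import NormalizationError, ParseError

__all__ = [
    "sym",
    "exact",
    "as_power_product",
    "is_power_product",
    "evaluate",
    "format_expression",
    "parse_expression",
    "free_names",
]


def sym(name: str) -> sp.Symbol:
    """Return the canonical symbol for a variable or parameter name."""
    return sp.Symbol(name)


def exact(value) -> sp.Expr:
    """Convert a numeric literal to an exact sympy number.

    Decimal floats become rationals via their shortest decimal repr, so the
    printed constant 0.8 is stored as 4/5.  Sympy expressions pass through.
    """
    if isinstance(value, sp.Expr):
        return value
    if isinstance(value, (int, np.integer)):
        return sp.Integer(int(value))
    if isinstance(value, Real):
        return sp.Rational(repr(float(value)))
    if isinstance(value, str):
        return sp.Rational(value)
    raise TypeError(f"cannot convert {value!r} to an exact number")


def _flatten_powers(expr: sp.Expr) -> sp.Expr:
    """Push powers through products and nested powers, assuming the
    positive-orthant convention of power-law models."""
    expr = sp.powdenest(expr, force=True)
    expr = sp.expand_power_base(expr, force=True)
    # combine only exponents of a common base; combining common exponents
    # across bases would undo the expansion just performed
    expr = sp.powsimp(expr, force=True, combine="exp")
    return expr


def as_power_product(
    expr: sp.Expr, variables: Iterable[str]
) -> tuple[sp.Expr, dict[str, sp.Expr]] | None:
    """Decompose ``expr`` as ``coeff * prod X_j**e_j`` over ``variables``.

    Returns ``(coeff, exponents)`` where ``coeff`` is free of all listed
    variables, or ``None`` if the expression is not a power product (for
    example if it contains a sum involving a variable).  Exponents may be
    symbolic (they can reference parameters).
    """
    varset = {sp.Symbol(v) for v in variables}
    expr = sp.sympify(expr)
    if not (expr.free_symbols & varset):
        return expr, {}
    expr = _flatten_powers(expr)
    coeff = sp.Integer(1)
    exponents: dict[str, sp.Expr] = {}
    factors = expr.as_ordered_factors() if expr.is_Mul else [expr]
    for factor in factors:
        if not (factor.free_symbols & varset):
            coeff *= factor
            continue
        base, exp = factor.as_base_exp()
        if base in varset:
            if exp.free_symbols & varset:
                return None  # variable in an exponent: not a power product
            name = base.name
            exponents[name] = exponents.get(name, sp.Integer(0)) + exp
        else:
            return None
    exponents = {v: e for v, e in exponents.items() if e != 0}
    return coeff, exponents


def is_power_product(expr: sp.Expr, variables: Iterable[str]) -> bool:
    """True if ``expr`` has the canonical shape ``c * prod X_j**e_j``."""
    return as_power_product(expr, variables) is not None


def require_power_product(expr, variables):
    pp = as_power_product(expr, variables)
    if pp is None:
        raise NormalizationError(f"expression {expr} is not a power product")
    return pp


def evaluate(expr: sp.Expr, env: Mapping[str, float]) -> float:
    """Numerically evaluate ``expr`` with every symbol bound via ``env``."""
    subs = {sp.Symbol(k): float(v) for k, v in env.items()}
    value = sp.sympify(expr).evalf(subs=subs)
    return float(value)


def free_names(expr: sp.Expr) -> set[str]:
    return {s.name for s in sp.sympify(expr).free_symbols}


def format_expression(expr: sp.Expr) -> str:
    """Serialize an expression in the document infix grammar.

    The grammar is plain Python/sympy infix: ``+ - * / **``, function-free
    except for ``exp`` and ``log``, with full-precision numeric literals.
    """
    return sp.sstr(expr, full_prec=True)


_ALLOWED_FUNCS = {"exp": sp.exp, "log": sp.log, "sqrt": sp.sqrt, "Rational": sp.Rational}


def parse_expression(text: str, declared: Iterable[str]) -> sp.Expr:
    """Parse an infix expression string against a set of declared names.

    Any symbol not in ``declared`` raises :class:`ParseError` so document
    typos surface immediately.
    """
    local = {name: sp.Symbol(name) for name in declared}
    local.update(_ALLOWED_FUNCS)
    try:
        expr = parse_expr(text, local_dict=local, evaluate=True)
    except Exception as err:  # sympy raises many types here
        raise ParseError(f"cannot parse expression {text!r}: {err}") from err
    unknown = free_names(expr) - set(declared)
    if unknown:
        raise ParseError(
            f"expression {text!r} references undeclared symbols: {sorted(unknown)}"
        )
    return expr
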