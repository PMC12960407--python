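"""Model document I/O (schema ``canonred-model/1``).

A model document is a JSON object with top-level keys ``schema``, ``class``
(``ssystem`` | ``gma`` | ``lv`` | ``general``), ``variables`` (name, kind,
initial), ``parameters`` (name, value, role) and ``equations`` (class
specific).  Expressions -- rates, exponents, general right-hand sides,
auxiliary constraints and algebraic add-ons -- are stored as infix strings
(``+ - * / **``; exact rationals print as ``4/5``) and parsed back against
the declared names, so documents round-trip losslessly.

Reduced models add an ``algebraic`` section (eliminated variable plus its
closed-form expression) and an ``elimination_record``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pydantic
import sympy as sp

from .errors import ParseError, ValidationError
from .expressions import format_expression, parse_expression
from .model_core import (
    GMAModel,
    GeneralODEModel,
    LVModel,
    Parameter,
    PowerLawTerm,
    SSystemModel,
)
from .reduction import NullclineSolution, ReducedModel

__all__ = ["load_model", "save_model", "model_to_document", "model_from_document"]

SCHEMA = "canonred-model/1"


class _VariableDoc(pydantic.BaseModel):
    name: str
    kind: Literal["dependent", "independent"]
    initial: float


class _ParameterDoc(pydantic.BaseModel):
    name: str
    value: Optional[float] = None
    role: str = "other"


class _TermDoc(pydantic.BaseModel):
    sign: Literal[1, -1]
    rate: str
    exponents: dict[str, str] = pydantic.Field(default_factory=dict)


class _EquationDoc(pydantic.BaseModel):
    variable: str
    # ssystem
    production: Optional[_TermDoc] = None
    degradation: Optional[_TermDoc] = None
    # gma
    terms: Optional[list[_TermDoc]] = None
    # lv
    growth: Optional[str] = None
    interactions: Optional[dict[str, str]] = None
    # general
    expression: Optional[str] = None


class _AlgebraicDoc(pydantic.BaseModel):
    variable: str
    expression: str
    kind: str = "other"
    validity: str = ""


class _ModelDoc(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(populate_by_name=True)

    schema_id: str = pydantic.Field(default=SCHEMA, alias="schema")
    model_class: Literal["ssystem", "gma", "lv", "general"] = pydantic.Field(
        alias="class"
    )
    variables: list[_VariableDoc]
    parameters: list[_ParameterDoc] = pydantic.Field(default_factory=list)
    equations: list[_EquationDoc]
    aux_constraints: dict[str, str] = pydantic.Field(default_factory=dict)
    algebraic: list[_AlgebraicDoc] = pydantic.Field(default_factory=list)
    elimination_record: list[str] = pydantic.Field(default_factory=list)
    metadata: dict = pydantic.Field(default_factory=dict)


def _term_to_doc(term: PowerLawTerm) -> _TermDoc:
    return _TermDoc(
        sign=term.sign,
        rate=format_expression(term.rate),
        exponents={v: format_expression(e) for v, e in term.exponents.items()},
    )


def _term_from_doc(doc: _TermDoc, declared) -> PowerLawTerm:
    return PowerLawTerm(
        sign=doc.sign,
        rate=parse_expression(doc.rate, declared),
        exponents={v: parse_expression(e, declared) for v, e in doc.exponents.items()},
    )


def model_to_document(model) -> dict:
    """Serialize a model (or ReducedModel) to a plain document dict."""
    algebraic: list[_AlgebraicDoc] = []
    record: list[str] = []
    if isinstance(model, ReducedModel):
        algebraic = [
            _AlgebraicDoc(
                variable=v,
                expression=format_expression(s.expr),
                kind=s.kind,
                validity=s.validity,
            )
            for v, s in model.addons.items()
        ]
        record = list(model.elimination_record)
        model = model.model

    variables = [
        _VariableDoc(name=v, kind="dependent", initial=float(model.initial[v]))
        for v in model.dependent
    ] + [
        _VariableDoc(name=v, kind="independent", initial=float(model.initial[v]))
        for v in model.independent
    ]
    parameters = [
        _ParameterDoc(name=p.name, value=p.value, role=p.role)
        for p in model.parameters.values()
    ]

    if isinstance(model, SSystemModel):
        equations = [
            _EquationDoc(
                variable=v,
                production=_term_to_doc(model.production[v]),
                degradation=_term_to_doc(model.degradation[v]),
            )
            for v in model.dependent
        ]
    elif isinstance(model, GMAModel):
        equations = [
            _EquationDoc(variable=v, terms=[_term_to_doc(t) for t in model.term_lists[v]])
            for v in model.dependent
        ]
    elif isinstance(model, LVModel):
        equations = [
            _EquationDoc(
                variable=v,
                growth=format_expression(model.growth[i]),
                interactions={
                    w: format_expression(model.interaction[i][j])
                    for j, w in enumerate(model.dependent)
                    if model.interaction[i][j] != 0
                },
            )
            for i, v in enumerate(model.dependent)
        ]
    elif isinstance(model, GeneralODEModel):
        equations = [
            _EquationDoc(variable=v, expression=format_expression(model.rhs[v]))
            for v in model.dependent
        ]
    else:
        raise ValidationError(f"cannot serialize model of class {type(model).__name__}")

    doc = _ModelDoc(
        model_class=model.model_class,
        variables=variables,
        parameters=parameters,
        equations=equations,
        aux_constraints={
            v: format_expression(c) for v, c in model.aux_constraints.items()
        },
        algebraic=algebraic,
        elimination_record=record,
        metadata={
            k: v for k, v in model.metadata.items() if isinstance(v, (str, int, float, bool, list, dict))
        },
    )
    return doc.model_dump(by_alias=True, mode="json")


def model_from_document(data: dict):
    """Build a validated model from a document dict."""
    try:
        doc = _ModelDoc.model_validate(data)
    except pydantic.ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ParseError(f"invalid model document at {loc!r}: {first['msg']}") from err
    if doc.schema_id != SCHEMA:
        raise ParseError(f"unsupported schema {doc.schema_id!r}; expected {SCHEMA!r}")

    dependent = [v.name for v in doc.variables if v.kind == "dependent"]
    independent = [v.name for v in doc.variables if v.kind == "independent"]
    initial = {v.name: v.initial for v in doc.variables}
    parameters = {
        p.name: Parameter(p.name, p.value, p.role) for p in doc.parameters
    }
    declared = set(dependent) | set(independent) | set(parameters)
    aux = {
        v: parse_expression(c, declared) for v, c in doc.aux_constraints.items()
    }
    eq_by_var = {e.variable: e for e in doc.equations}
    missing = set(dependent) - set(eq_by_var)
    if missing:
        raise ParseError(f"missing equations for dependent variables {sorted(missing)}")

    common = dict(
        dependent=dependent,
        independent=independent,
        parameters=parameters,
        initial=initial,
        aux_constraints=aux,
        metadata=dict(doc.metadata),
    )
    if doc.model_class == "ssystem":
        production, degradation = {}, {}
        for v in dependent:
            e = eq_by_var[v]
            if e.production is None or e.degradation is None:
                raise ParseError(
                    f"equation for {v!r} must declare production and degradation terms"
                )
            production[v] = _term_from_doc(e.production, declared)
            degradation[v] = _term_from_doc(e.degradation, declared)
        model = SSystemModel(production=production, degradation=degradation, **common)
    elif doc.model_class == "gma":
        term_lists = {}
        for v in dependent:
            e = eq_by_var[v]
            if not e.terms:
                raise ParseError(f"equation for {v!r} must declare a term list")
            term_lists[v] = [_term_from_doc(t, declared) for t in e.terms]
        model = GMAModel(term_lists=term_lists, **common)
    elif doc.model_class == "lv":
        growth, interaction = [], []
        for v in dependent:
            e = eq_by_var[v]
            if e.growth is None:
                raise ParseError(f"LV equation for {v!r} must declare a growth entry")
            growth.append(parse_expression(e.growth, declared))
            inter = e.interactions or {}
            unknown = set(inter) - set(dependent)
            if unknown:
                raise ParseError(
                    f"LV interactions of {v!r} reference unknown variables {sorted(unknown)}"
                )
            interaction.append(
                [
                    parse_expression(inter[w], declared) if w in inter else sp.Integer(0)
                    for w in dependent
                ]
            )
        model = LVModel(growth=growth, interaction=interaction, **common)
    else:
        rhs = {}
        for v in dependent:
            e = eq_by_var[v]
            if e.expression is None:
                raise ParseError(f"general equation for {v!r} must declare an expression")
            rhs[v] = parse_expression(e.expression, declared)
        model = GeneralODEModel(rhs=rhs, **common)

    if doc.algebraic:
        addons = {
            a.variable: NullclineSolution(
                a.variable,
                parse_expression(a.expression, declared | {a.variable}),
                a.kind,
                a.validity,
            )
            for a in doc.algebraic
        }
        return ReducedModel(model, addons, list(doc.elimination_record), None)
    return model


def load_model(path):
    """Load and validate a model document from a JSON file."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as err:
        raise ParseError(f"{path}: not valid JSON: {err}") from err
    return model_from_document(data)


def save_model(model, path) -> None:
    """Write a model document (pretty-printed, stable key order)."""
    data = model_to_document(model)
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
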