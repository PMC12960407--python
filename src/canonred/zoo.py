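"""Built-in model zoo.

Small, fully parameterized canonical models that exercise every part of the
reduction machinery: a feedback-inhibited linear pathway, a bistable
Hill-regulated system (plus its exact power-law recast), the four-layer
Goodwin oscillator in recast S-system form, the Roessler chaotic and
hyperchaotic oscillators, a mass-action signalling cascade, the structural
skeleton of an aspartate-pathway S-system (rate constants unbound), and a
one-equation GMA fragment of a fungal biomass model.

All numeric settings are the published values for these textbook systems.
"""

from __future__ import annotations

import sympy as sp

from .errors import ValidationError
from .expressions import exact, sym
from .model_core import (
    GMAModel,
    GeneralODEModel,
    Parameter,
    PowerLawTerm,
    SSystemModel,
)

__all__ = ["zoo", "zoo_names"]


def _linear_pathway() -> SSystemModel:
    """Five-step linear pathway with end-product feedback inhibition.

    dX1 = a1*X0*X5**g - b1*X1, dX2 = b1*X1 - b2*X2**0.5, ... with generic
    settings X0=1, a1=1, b1=0.2, b2=1.5, b3=3, b4=2, b5=0.4, g=-1.
    Initial values are the system's (numerically reported) steady state.
    """
    a1, b1, b2, b3, b4, b5, g = (sym(s) for s in ["a1", "b1", "b2", "b3", "b4", "b5", "g"])
    params = {
        "a1": Parameter("a1", 1.0, "rate_constant"),
        "b1": Parameter("b1", 0.2, "rate_constant"),
        "b2": Parameter("b2", 1.5, "rate_constant"),
        "b3": Parameter("b3", 3.0, "rate_constant"),
        "b4": Parameter("b4", 2.0, "rate_constant"),
        "b5": Parameter("b5", 0.4, "rate_constant"),
        "g": Parameter("g", -1.0, "kinetic_order"),
    }
    production = {
        "X1": PowerLawTerm(+1, a1, {"X0": 1, "X5": g}),
        "X2": PowerLawTerm(+1, b1, {"X1": 1}),
        "X3": PowerLawTerm(+1, b2, {"X2": 0.5}),
        "X4": PowerLawTerm(+1, b3, {"X3": 0.8}),
        "X5": PowerLawTerm(+1, b4, {"X4": 0.4}),
    }
    degradation = {
        "X1": PowerLawTerm(-1, b1, {"X1": 1}),
        "X2": PowerLawTerm(-1, b2, {"X2": 0.5}),
        "X3": PowerLawTerm(-1, b3, {"X3": 0.8}),
        "X4": PowerLawTerm(-1, b4, {"X4": 0.4}),
        "X5": PowerLawTerm(-1, b5, {"X5": 0.6}),
    }
    initial = {
        "X0": 1.0,
        # Reported steady state; carries ~0.3% numerical residual against the
        # exact analytic fixed point (see analysis module docs).
        "X1": 2.826188,
        "X2": 0.1419327,
        "X3": 0.1240745,
        "X4": 0.04240996,
        "X5": 1.766654,
    }
    return SSystemModel(
        dependent=["X1", "X2", "X3", "X4", "X5"],
        independent=["X0"],
        production=production,
        degradation=degradation,
        parameters=params,
        initial=initial,
        metadata={"zoo": "linear_pathway"},
    )


def _bistable() -> GeneralODEModel:
    """Four-variable bistable system with Hill activation.

    The basal constant 4 and the Hill term are summed *before* multiplying
    by X3**-0.5; only this grouping makes the three known steady states
    zero the first equation.
    """
    X1, X2, X3, X4 = (sym(v) for v in ["X1", "X2", "X3", "X4"])
    hill = 8 * X4**4 / (4**4 + X4**4)
    rhs = {
        "X1": (4 + hill) * X3 ** exact(-0.5) - exact(0.5) * X1 ** exact(0.5),
        "X2": X1 - 5 * X2 ** exact(0.5),
        "X3": 2 * X2 - 3 * X3,
        "X4": 3 * X3 - 12 * X4 ** exact(0.75),
    }
    initial = {"X1": 27.251, "X2": 29.705, "X3": 19.804, "X4": 8.4381}  # upper state
    return GeneralODEModel(
        dependent=["X1", "X2", "X3", "X4"],
        independent=[],
        rhs=rhs,
        parameters={},
        initial=initial,
        metadata={"zoo": "bistable"},
    )


def _bistable_recast() -> GMAModel:
    """Exact power-law recast of the bistable model.

    Auxiliary X5 = 4**4 + X4**4 turns the Hill activation into
    8*X4**4*X5**-1; the auxiliary ODE follows by the chain rule,
    dX5 = 4*X4**3*dX4 = 12*X3*X4**3 - 48*X4**3.75.
    """
    terms = {
        "X1": [
            PowerLawTerm(+1, sp.Integer(4), {"X3": -0.5}),
            PowerLawTerm(+1, sp.Integer(8), {"X4": 4, "X5": -1, "X3": -0.5}),
            PowerLawTerm(-1, exact(0.5), {"X1": 0.5}),
        ],
        "X2": [
            PowerLawTerm(+1, sp.Integer(1), {"X1": 1}),
            PowerLawTerm(-1, sp.Integer(5), {"X2": 0.5}),
        ],
        "X3": [
            PowerLawTerm(+1, sp.Integer(2), {"X2": 1}),
            PowerLawTerm(-1, sp.Integer(3), {"X3": 1}),
        ],
        "X4": [
            PowerLawTerm(+1, sp.Integer(3), {"X3": 1}),
            PowerLawTerm(-1, sp.Integer(12), {"X4": 0.75}),
        ],
        "X5": [
            PowerLawTerm(+1, sp.Integer(12), {"X3": 1, "X4": 3}),
            PowerLawTerm(-1, sp.Integer(48), {"X4": 3.75}),
        ],
    }
    x4_0 = 8.4381
    initial = {
        "X1": 27.251,
        "X2": 29.705,
        "X3": 19.804,
        "X4": x4_0,
        "X5": 256.0 + x4_0**4,
    }
    return GMAModel(
        dependent=["X1", "X2", "X3", "X4", "X5"],
        independent=[],
        term_lists=terms,
        parameters={},
        initial=initial,
        aux_constraints={"X5": 256 + sym("X4") ** 4},
        metadata={"zoo": "bistable_recast", "recast_regulator": {"X5": "X4"}},
    )


def _goodwin(n_value: float = 4.0) -> SSystemModel:
    """Four-layer Goodwin cascade with inverse-Hill repression, in recast
    S-system form.

    The auxiliary X5 = X4**n + 1 (half-saturation K = 1) converts the
    repression 50*K**n/(K**n + X4**n) into 50*X5**-1.  The Hill exponent n
    is a free parameter: moderate n gives damped oscillations toward a
    stable steady state, large n a stable limit cycle.
    """
    n = sym("n")
    production = {
        "X1": PowerLawTerm(+1, sp.Integer(50), {"X5": -1}),
        "X2": PowerLawTerm(+1, exact(0.4), {"X1": 1}),
        "X3": PowerLawTerm(+1, sp.Integer(1), {"X2": 1}),
        "X4": PowerLawTerm(+1, sp.Integer(1), {"X3": 1}),
        "X5": PowerLawTerm(+1, n, {"X3": 1, "X4": n - 1}),
    }
    degradation = {
        "X1": PowerLawTerm(-1, exact(0.1), {"X1": 1}),
        "X2": PowerLawTerm(-1, sp.Integer(1), {"X2": 1}),
        "X3": PowerLawTerm(-1, exact(0.1), {"X3": 1}),
        "X4": PowerLawTerm(-1, sp.Integer(2), {"X4": 1}),
        "X5": PowerLawTerm(-1, 2 * n, {"X4": n}),
    }
    # Start at the positive steady state of the chosen n: the fixed point
    # satisfies X1 = X4/2, X2 = X4/5, X3 = 2*X4 with X4**(n+1) + X4 = 1000,
    # and the auxiliary sits on its constraint.
    from scipy.optimize import brentq

    x4_0 = brentq(lambda x: x ** (n_value + 1) + x - 1000.0, 1e-3, 1000.0, xtol=1e-12)
    initial = {
        "X1": 0.5 * x4_0,
        "X2": 0.2 * x4_0,
        "X3": 2.0 * x4_0,
        "X4": x4_0,
        "X5": x4_0**n_value + 1.0,
    }
    return SSystemModel(
        dependent=["X1", "X2", "X3", "X4", "X5"],
        independent=[],
        production=production,
        degradation=degradation,
        parameters={"n": Parameter("n", n_value, "kinetic_order")},
        initial=initial,
        aux_constraints={"X5": sym("X4") ** n + 1},
        metadata={"zoo": "goodwin", "recast_regulator": {"X5": "X4"}},
    )


def _roessler() -> GeneralODEModel:
    X1, X2, X3 = (sym(v) for v in ["X1", "X2", "X3"])
    rhs = {
        "X1": -X2 - X3,
        "X2": X1 + exact(0.36) * X2,
        "X3": exact(0.4) * X1 - exact(4.5) * X3 + X1 * X3,
    }
    return GeneralODEModel(
        dependent=["X1", "X2", "X3"],
        independent=[],
        rhs=rhs,
        parameters={},
        initial={"X1": 0.0, "X2": 3.0, "X3": 0.0},
        metadata={"zoo": "roessler"},
    )


def _roessler_hyper() -> GeneralODEModel:
    X1, X2, X3, X4 = (sym(v) for v in ["X1", "X2", "X3", "X4"])
    rhs = {
        "X1": -X2 - X4,
        "X2": X1 + exact(0.25) * X2 + X3,
        "X3": exact(0.05) * X3 - exact(0.5) * X4,
        "X4": 3 + X1 * X4,
    }
    return GeneralODEModel(
        dependent=["X1", "X2", "X3", "X4"],
        independent=[],
        rhs=rhs,
        parameters={},
        initial={"X1": -20.0, "X2": 0.0, "X3": 15.0, "X4": 0.0},
        metadata={"zoo": "roessler_hyper"},
    )


def _cascade() -> SSystemModel:
    """Five-step activation cascade as a mass-action model (a special case
    of an S-system); the stated initial values form a fixed point."""
    names = ["X1", "X2", "X3", "X4", "X5"]
    a_vals = [1.0, 10.0, 0.5, 2.0, 0.01]
    params = {}
    production = {}
    degradation = {}
    for i, v in enumerate(names, start=1):
        a, b = f"a{i}", f"b{i}"
        params[a] = Parameter(a, a_vals[i - 1], "rate_constant")
        params[b] = Parameter(b, 1.0, "rate_constant")
        upstream = "X0" if i == 1 else f"X{i-1}"
        production[v] = PowerLawTerm(+1, sym(a), {upstream: 1})
        degradation[v] = PowerLawTerm(-1, sym(b), {v: 1})
    initial = {"X0": 1.0, "X1": 1.0, "X2": 10.0, "X3": 5.0, "X4": 10.0, "X5": 0.1}
    return SSystemModel(
        dependent=names,
        independent=["X0"],
        production=production,
        degradation=degradation,
        parameters=params,
        initial=initial,
        metadata={"zoo": "cascade"},
    )


def _iwata_structure() -> SSystemModel:
    """Structural skeleton of the eight-variable aspartate-derived amino
    acid pathway S-system; all parameters are symbolic (unbound), so the
    model supports symbolic reduction but not simulation."""
    spec = {
        # var: (production exponents, degradation exponents)
        "X1": ({"X0": 1, "X3": "g13", "X6": "g16"}, {"X1": "h11"}),
        "X2": ({"X1": "g21"}, {"X2": "h22"}),
        "X3": ({"X2": "g32", "X3": "g33"}, {"X3": "h33"}),
        "X4": ({"X2": "g42", "X6": "g46"}, {"X4": "h44"}),
        "X5": ({"X4": "g54"}, {"X5": "h55"}),
        "X6": ({"X5": "g65"}, {"X6": "h66"}),
        "X7": ({"X6": "g76", "X7": "g77"}, {"X7": "h77"}),
        "X8": ({"X6": "g86"}, {"X8": "h88"}),
    }
    params: dict[str, Parameter] = {}
    production = {}
    degradation = {}
    for i, (v, (g_exp, h_exp)) in enumerate(spec.items(), start=1):
        a, b = f"alpha{i}", f"beta{i}"
        params[a] = Parameter(a, None, "rate_constant")
        params[b] = Parameter(b, None, "rate_constant")
        for e in list(g_exp.values()) + list(h_exp.values()):
            if isinstance(e, str) and e not in params:
                params[e] = Parameter(e, None, "kinetic_order")
        production[v] = PowerLawTerm(
            +1, sym(a), {w: (sym(e) if isinstance(e, str) else e) for w, e in g_exp.items()}
        )
        degradation[v] = PowerLawTerm(
            -1, sym(b), {w: (sym(e) if isinstance(e, str) else e) for w, e in h_exp.items()}
        )
    initial = {"X0": 1.0, **{f"X{i}": 1.0 for i in range(1, 9)}}
    return SSystemModel(
        dependent=[f"X{i}" for i in range(1, 9)],
        independent=["X0"],
        production=production,
        degradation=degradation,
        parameters=params,
        initial=initial,
        metadata={"zoo": "iwata_structure", "structure_only": True},
    )


def _wrf_glucose_fragment() -> GMAModel:
    """One-equation GMA fragment of a fungal biomass model: glucose with a
    constant inflow, a delayed consumption term, and first-order loss.
    The inflow V_in_Gluc and delayed variable X11 are independent here;
    their placeholder values (1.0) are not part of the published fragment.
    """
    terms = {
        "X1": [
            PowerLawTerm(+1, sp.Integer(1), {"V_in_Gluc": 1}),
            PowerLawTerm(-1, exact(0.3), {"X11": 1}),
            PowerLawTerm(-1, exact(0.1), {"X1": 1}),
        ]
    }
    return GMAModel(
        dependent=["X1"],
        independent=["V_in_Gluc", "X11"],
        term_lists=terms,
        parameters={},
        initial={"X1": 1.0, "V_in_Gluc": 1.0, "X11": 1.0},
        metadata={"zoo": "wrf_glucose_fragment"},
    )


_BUILDERS = {
    "linear_pathway": _linear_pathway,
    "bistable": _bistable,
    "bistable_recast": _bistable_recast,
    "goodwin": _goodwin,
    "roessler": _roessler,
    "roessler_hyper": _roessler_hyper,
    "cascade": _cascade,
    "iwata_structure": _iwata_structure,
    "wrf_glucose_fragment": _wrf_glucose_fragment,
}


def zoo_names() -> list[str]:
    return sorted(_BUILDERS)


def zoo(name: str, **kwargs):
    """Build a zoo model by name.

    ``goodwin`` accepts ``n_value`` (Hill exponent, default 4).
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValidationError(
            f"unknown zoo model {name!r}; available: {', '.join(zoo_names())}"
        ) from None
    return builder(**kwargs)
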