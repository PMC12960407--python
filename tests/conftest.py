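"""Shared fixtures: zoo models, the Hill-form Goodwin reference, and small
hand-built models used across the suite."""

from __future__ import annotations

import numpy as np
import pytest
import sympy as sp

import canonred as cr
from canonred.expressions import exact, sym
from canonred.model_core import GeneralODEModel, LVModel, Parameter


@pytest.fixture
def linear_pathway():
    return cr.zoo("linear_pathway")


@pytest.fixture
def bistable():
    return cr.zoo("bistable")


@pytest.fixture
def cascade():
    return cr.zoo("cascade")


def goodwin_hill(n: float) -> GeneralODEModel:
    """Four-variable Goodwin cascade in its original Hill form (exactly
    equivalent to the recast zoo model on the constraint manifold)."""
    X1, X2, X3, X4 = (sym(v) for v in ["X1", "X2", "X3", "X4"])
    nn = sym("n")
    rhs = {
        "X1": 50 / (X4**nn + 1) - exact(0.1) * X1,
        "X2": exact(0.4) * X1 - X2,
        "X3": X2 - exact(0.1) * X3,
        "X4": X3 - 2 * X4,
    }
    gw = cr.zoo("goodwin", n_value=n)
    return GeneralODEModel(
        dependent=["X1", "X2", "X3", "X4"],
        independent=[],
        rhs=rhs,
        parameters={"n": Parameter("n", n, "kinetic_order")},
        initial={v: gw.initial[v] for v in ["X1", "X2", "X3", "X4"]},
    )


def three_species_lv() -> LVModel:
    """The worked 3-species LV example used for the parameter-update
    formulas."""
    a = [1.0, 0.5, 0.8]
    b = [[-1.0, 0.5, 0.2], [0.3, -1.0, 0.1], [0.2, 0.4, -1.0]]
    return LVModel(
        dependent=["X1", "X2", "X3"],
        growth=[sp.Rational(repr(x)) for x in a],
        interaction=[[sp.Rational(repr(x)) for x in row] for row in b],
        parameters={},
        initial={"X1": 1.0, "X2": 1.0, "X3": 1.0},
    )


#: printed steady states of the bistable system (low, middle/unstable, high)
BISTABLE_STATES = np.array(
    [
        [13.598, 7.3964, 4.9309, 1.3218],
        [19.849, 15.760, 10.507, 3.6241],
        [27.251, 29.705, 19.804, 8.4381],
    ]
)

#: printed Goodwin fixed points for n=4 and n=18 (X1..X4)
GOODWIN_N4 = np.array([1.989, 0.7956, 7.956, 3.978])
GOODWIN_N18 = np.array([0.71915, 0.28766, 2.8766, 1.4383])

#: printed linear-pathway steady state (carries ~0.3% numerical residual)
PATHWAY_PRINTED = np.array([2.826188, 0.1419327, 0.1240745, 0.04240996, 1.766654])


def random_positive_states(model, n, seed, lo=0.5, hi=3.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(n, len(model.dependent)))
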