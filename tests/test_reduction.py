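"""Nullcline solving, symbolic substitution, format preservation and
numeric collapse."""

import numpy as np
import pytest
import sympy as sp

import canonred as cr
from canonred.errors import (
    AlreadyDecoupled,
    CannotCollapse,
    CyclicDependency,
    NotReducible,
    NotSolvable,
)
from canonred.expressions import exact, sym
from canonred.model_core import Parameter, PowerLawTerm, SSystemModel
from canonred.reduction import NullclineSolution
from canonred.synthgen import GeneratorSpec, random_lv, random_ssystem

from conftest import three_species_lv


def _residual_at_random_states(model, sol, n=20, seed=0):
    """Oracle: the nullcline solution must zero its source equation."""
    rng = np.random.default_rng(seed)
    vals = {sym(p.name): p.value for p in model.parameters.values() if p.value is not None}
    f = model.rhs_exprs()[sol.variable].subs(vals)
    expr = f.subs(sym(sol.variable), sol.expr).subs(vals)
    others = sorted(expr.free_symbols - {sym(v) for v in model.independent}, key=str)
    indep = {sym(v): model.initial[v] for v in model.independent}
    worst = 0.0
    for _ in range(n):
        env = {s: rng.uniform(0.5, 2.0) for s in others}
        env.update(indep)
        worst = max(worst, abs(float(expr.subs(env).evalf())))
    return worst


class TestSSystemNullcline:
    def test_linear_pathway_x4(self, linear_pathway):
        sol = cr.solve_nullcline_ssystem(linear_pathway, "X4")
        b3, b4, X3 = sym("b3"), sym("b4"), sym("X3")
        expected = (b3 * X3 ** exact(0.8) / b4) ** exact(2.5)
        ratio = sp.powsimp(sp.powdenest(sol.expr / expected, force=True), force=True)
        assert sp.simplify(ratio) == 1
        assert sol.kind == "power_product"

    def test_iwata_structure_x3_symbolic(self):
        iw = cr.zoo("iwata_structure")
        sol = cr.solve_nullcline_ssystem(iw, "X3")
        b3, a3, g32, g33, h33, X2 = (
            sym(s) for s in ["beta3", "alpha3", "g32", "g33", "h33", "X2"]
        )
        expected = ((b3 / a3) * X2 ** (-g32)) ** (1 / (g33 - h33))
        diff = sp.simplify(sp.log(sol.expr) - sp.log(expected))
        # compare in log space at random positive bindings
        rng = np.random.default_rng(2)
        env = {s: rng.uniform(0.3, 2.0) for s in diff.free_symbols}
        assert abs(complex(diff.subs(env).evalf())) < 1e-10

    def test_linear_degradation(self):
        m = SSystemModel(
            dependent=["X1"],
            independent=[],
            production={"X1": PowerLawTerm(+1, sym("a"), {})},
            degradation={"X1": PowerLawTerm(-1, sym("b"), {"X1": 1})},
            parameters={"a": Parameter("a", 2.0, "rate_constant"),
                        "b": Parameter("b", 0.5, "rate_constant")},
            initial={"X1": 1.0},
        )
        sol = cr.solve_nullcline_ssystem(m, "X1")
        assert sp.simplify(sol.expr - sym("a") / sym("b")) == 0

    def test_equal_self_exponents_not_reducible(self):
        m = SSystemModel(
            dependent=["X1", "X2"],
            independent=[],
            production={
                "X1": PowerLawTerm(+1, sym("a"), {"X2": 1}),
                "X2": PowerLawTerm(+1, sym("a"), {"X2": 0.5, "X1": 1}),
            },
            degradation={
                "X1": PowerLawTerm(-1, sym("b"), {"X1": 1}),
                "X2": PowerLawTerm(-1, sym("b"), {"X2": 0.5}),
            },
            parameters={"a": Parameter("a", 1.0, "rate_constant"),
                        "b": Parameter("b", 1.0, "rate_constant")},
            initial={"X1": 1.0, "X2": 1.0},
        )
        with pytest.raises(NotReducible, match="g_kk equals h_kk"):
            cr.solve_nullcline_ssystem(m, "X2")

    def test_decoupled_variable_advisory(self):
        m = SSystemModel(
            dependent=["X1", "X2"],
            independent=[],
            production={
                "X1": PowerLawTerm(+1, sym("a"), {}),
                "X2": PowerLawTerm(+1, sym("a"), {"X1": 1}),
            },
            degradation={
                "X1": PowerLawTerm(-1, sym("b"), {"X1": 1}),
                "X2": PowerLawTerm(-1, sym("b"), {"X1": 0.5}),
            },
            parameters={"a": Parameter("a", 1.0, "rate_constant"),
                        "b": Parameter("b", 1.0, "rate_constant")},
            initial={"X1": 1.0, "X2": 1.0},
        )
        with pytest.raises(AlreadyDecoupled):
            cr.solve_nullcline_ssystem(m, "X2")

    def test_nullcline_identity_on_synthetic_models(self):
        for seed in range(5):
            m = random_ssystem(GeneratorSpec("ssystem", n=4, seed=seed))
            for k in m.dependent:
                sol = cr.solve_nullcline_ssystem(m, k)
                assert _residual_at_random_states(m, sol, n=20, seed=seed) < 1e-9


class TestLVNullcline:
    def test_logistic_carrying_capacity(self):
        from canonred.model_core import LVModel

        lv = LVModel(
            dependent=["X1"],
            growth=[sp.Integer(1)],
            interaction=[[sp.Integer(-1)]],
            parameters={},
            initial={"X1": 0.5},
        )
        sol = cr.solve_nullcline_lv(lv, "X1")
        assert sp.simplify(sol.expr - 1) == 0

    def test_three_species_row(self):
        lv = three_species_lv()
        sol = cr.solve_nullcline_lv(lv, "X3")
        expected = sp.Rational(4, 5) + sp.Rational(1, 5) * sym("X1") + sp.Rational(2, 5) * sym("X2")
        assert sp.expand(sol.expr - expected) == 0
        assert _residual_at_random_states(lv, sol, n=20, seed=1) < 1e-12

    def test_zero_diagonal_refused(self):
        from canonred.model_core import LVModel

        lv = LVModel(
            dependent=["X1", "X2"],
            growth=[sp.Integer(1), sp.Integer(1)],
            interaction=[[sp.Integer(0), sp.Integer(-1)], [sp.Integer(-1), sp.Integer(-1)]],
            parameters={},
            initial={"X1": 1.0, "X2": 1.0},
        )
        with pytest.raises(NotReducible, match="b_kk"):
            cr.solve_nullcline_lv(lv, "X1")


class TestReduceLV:
    def test_uncoupled_row_unchanged(self):
        m = random_lv(GeneratorSpec("lv", n=3, seed=4, sparsity=1.0))  # diagonal only
        red = cr.reduce_lv(m, "X3")
        np.testing.assert_allclose(red.growth_values(), m.growth_values()[:2])
        np.testing.assert_allclose(
            red.interaction_values(), m.interaction_values()[:2, :2]
        )

    def test_three_species_hand_arithmetic(self):
        red = cr.reduce_lv(three_species_lv(), "X3")
        # a~_1 = a_1 - a_3*b_13/b_33 = 1 - 0.8*0.2/(-1) = 1.16
        assert float(red.growth[0]) == pytest.approx(1.16)
        assert float(red.growth[1]) == pytest.approx(0.5 - 0.8 * 0.1 / (-1.0))
        # b~_12 = b_12 - b_13*b_32/b_33 = 0.5 - 0.2*0.4/(-1) = 0.58
        assert float(red.interaction[0][1]) == pytest.approx(0.58)
        assert float(red.interaction[0][0]) == pytest.approx(-1 - 0.2 * 0.2 / (-1.0))

    def test_fixed_point_projection_on_random_models(self):
        for seed in range(10):
            m = random_lv(GeneratorSpec("lv", n=4, seed=seed))
            fp = np.array(m.metadata["fixed_point"])
            red = cr.reduce_lv(m, "X2")
            x_red = np.linalg.solve(-red.interaction_values(), red.growth_values())
            proj = np.array([fp[m.dependent.index(v)] for v in red.dependent])
            np.testing.assert_allclose(x_red, proj, rtol=1e-10, atol=1e-12)


class TestGeneralNullcline:
    def test_wrf_glucose_affine(self):
        wrf = cr.zoo("wrf_glucose_fragment")
        sol = cr.solve_nullcline_general(wrf, "X1")
        expected = 10 * (sym("V_in_Gluc") - exact(0.3) * sym("X11"))
        assert sp.expand(sol.expr - expected) == 0
        assert sol.kind == "affine"

    def test_roessler_rational(self):
        ro = cr.zoo("roessler")
        sol = cr.solve_nullcline_general(ro, "X3")
        expected = exact(0.4) * sym("X1") / (exact(4.5) - sym("X1"))
        assert sp.simplify(sol.expr - expected) == 0
        assert sol.kind == "rational"
        assert _residual_at_random_states(ro, sol, n=20, seed=7) < 1e-10

    def test_incommensurate_powers_not_solvable(self):
        from canonred.model_core import GeneralODEModel

        x = sym("X1")
        m = GeneralODEModel(
            dependent=["X1"],
            independent=[],
            rhs={"X1": 2 * x ** exact(0.5) + 3 * x ** exact(0.37) + 1},
            parameters={},
            initial={"X1": 1.0},
        )
        with pytest.raises(NotSolvable):
            cr.solve_nullcline_general(m, "X1")

    def test_bistable_power_solve(self, bistable):
        sol = cr.solve_nullcline_general(bistable, "X4")
        # 3*X3 = 12*X4**0.75  ->  X4 = (X3/4)**(4/3)
        expected = (sym("X3") / 4) ** sp.Rational(4, 3)
        rng = np.random.default_rng(3)
        for _ in range(5):
            x3 = rng.uniform(0.5, 5)
            a = float(sol.expr.subs(sym("X3"), x3))
            b = float(expected.subs(sym("X3"), x3))
            assert a == pytest.approx(b, rel=1e-12)


class TestSubstitute:
    def test_pathway_exponent_cancellation_is_exact(self, linear_pathway):
        """Substituting the X4 nullcline into the X5 equation collapses
        symbolically to b3*X3**0.8 - b5*X5**0.6 (exponents 2.5*0.4 = 1)."""
        sol = cr.solve_nullcline_ssystem(linear_pathway, "X4")
        red = cr.substitute(linear_pathway, [sol])
        assert red.model.model_class == "ssystem"
        prod = red.model.production["X5"]
        assert prod.rate == sym("b3")
        assert prod.exponents == {"X3": sp.Rational(4, 5)}
        deg = red.model.degradation["X5"]
        assert deg.rate == sym("b5") and deg.exponents == {"X5": sp.Rational(3, 5)}

    def test_untouched_equations_unchanged(self, linear_pathway):
        sol = cr.solve_nullcline_ssystem(linear_pathway, "X4")
        red = cr.substitute(linear_pathway, [sol])
        for v in ["X1", "X2", "X3"]:
            assert red.model.production[v] == linear_pathway.production[v]
            assert red.model.degradation[v] == linear_pathway.degradation[v]

    def test_numeric_substitution_oracle(self, bistable):
        """Reduced RHS equals hand-substituted RHS at random states."""
        sol = cr.solve_nullcline_general(bistable, "X3")
        red = cr.substitute(bistable, [sol])
        rng = np.random.default_rng(9)
        vals = {}
        for _ in range(100):
            x = rng.uniform(1.0, 20.0, size=4)
            env = dict(zip(bistable.dependent, x))
            x3 = float(sol.expr.subs({sym("X2"): env["X2"]}))
            env["X3"] = x3
            expected = [
                float(bistable.rhs[v].subs({sym(k): w for k, w in env.items()}))
                for v in red.model.dependent
            ]
            got = cr.evaluate_rhs(red, [env[v] for v in red.model.dependent])
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_mutually_referential_solutions_rejected(self, bistable):
        s3 = NullclineSolution("X3", sym("X4") ** 2, "other")
        s4 = NullclineSolution("X4", sym("X3") / 2, "other")
        with pytest.raises(CyclicDependency):
            cr.substitute(bistable, [s3, s4])


class TestReduce:
    def test_pathway_triple_elimination_matches_printed_form(self, linear_pathway):
        red = cr.reduce(linear_pathway, ["X2", "X3", "X4"])
        assert red.model.model_class == "ssystem"
        assert red.model.dependent == ["X1", "X5"]
        # dX1 = a1*X0*X5**g - b1*X1 (unchanged), dX5 = b1*X1 - b5*X5**0.6
        p5, d5 = red.model.production["X5"], red.model.degradation["X5"]
        assert p5.rate == sym("b1") and p5.exponents == {"X1": sp.Integer(1)}
        assert d5.rate == sym("b5") and d5.exponents == {"X5": sp.Rational(3, 5)}
        assert red.model.production["X1"] == linear_pathway.production["X1"]

    def test_elimination_order_commutes(self, linear_pathway):
        r1 = cr.reduce(linear_pathway, ["X2", "X3", "X4"])
        r2 = cr.reduce(linear_pathway, ["X4", "X3", "X2"])
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.uniform(0.2, 5.0, size=2)
            a, b = cr.evaluate_rhs(r1, x), cr.evaluate_rhs(r2, x)
            np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-14)

    def test_empty_elimination_is_identity(self, linear_pathway):
        red = cr.reduce(linear_pathway, [])
        assert red.model is linear_pathway
        assert red.addons == {} and red.elimination_record == []

    def test_simultaneous_matches_sequential(self, linear_pathway, bistable):
        for model, elim in [
            (linear_pathway, ["X2", "X3", "X4"]),
            (bistable, ["X3", "X4"]),
        ]:
            seq = cr.reduce(model, elim)
            sim = cr.reduce(model, elim, simultaneous=True)
            rng = np.random.default_rng(6)
            for _ in range(20):
                x = rng.uniform(0.5, 5.0, size=len(seq.model.dependent))
                np.testing.assert_allclose(
                    cr.evaluate_rhs(seq, x), cr.evaluate_rhs(sim, x),
                    rtol=1e-9, atol=1e-12,
                )

    def test_addons_reference_only_retained_variables(self, linear_pathway):
        red = cr.reduce(linear_pathway, ["X2", "X3", "X4"])
        retained = set(red.model.dependent) | set(red.model.independent) | set(
            red.model.parameters
        )
        for s in red.addons.values():
            assert s.references() <= retained


class TestFormatPreservation:
    def test_single_elimination_keeps_ssystem_class(self):
        for seed in range(20):
            m = random_ssystem(GeneratorSpec("ssystem", n=4, seed=seed))
            red = cr.reduce(m, ["X2"])
            assert red.model.model_class == "ssystem"
            red.check_partition()

    def test_steady_state_preserved_under_reduction(self):
        for seed in range(20):
            m = random_ssystem(GeneratorSpec("ssystem", n=4, seed=100 + seed,
                                             require_stable=True))
            fp = np.array(m.metadata["fixed_point"])
            red = cr.reduce(m, ["X3"])
            ss = cr.steady_state_analytic_ssystem(red.model)
            proj = np.array([fp[m.dependent.index(v)] for v in red.model.dependent])
            np.testing.assert_allclose(ss.state, proj, rtol=1e-8)


class TestCollapseNumeric:
    def test_power_of_quotient_value(self, linear_pathway):
        red = cr.substitute(
            linear_pathway, [cr.solve_nullcline_ssystem(linear_pathway, "X4")]
        )
        col = cr.collapse_numeric(red)
        # the X4 add-on (b3*X3**0.8/b4)**2.5 with b3=3, b4=2 -> 1.5**2.5 * X3**2
        expr = col.addons["X4"].expr
        x3 = 1.7
        got = float(expr.subs(sym("X3"), x3))
        assert got == pytest.approx(1.5**2.5 * x3**2, rel=1e-12)

    def test_collapsed_pathway_matches_printed_constants(self, linear_pathway):
        red = cr.reduce(linear_pathway, ["X2", "X3", "X4"])
        col = cr.collapse_numeric(red)
        p1 = col.model.production["X1"]
        assert float(p1.rate) == pytest.approx(1.0)
        d1 = col.model.degradation["X1"]
        assert float(d1.rate) == pytest.approx(0.2)
        assert any("no longer possible" in w for w in col.warnings)

    def test_collapse_is_numerically_idempotent(self, cascade):
        red = cr.reduce(cascade, ["X2"])
        c1 = cr.collapse_numeric(red)
        c2 = cr.collapse_numeric(
            cr.ReducedModel(c1.model, c1.addons, c1.elimination_record, red.parent)
        )
        x = np.array([1.0, 5.0, 10.0, 0.1])
        np.testing.assert_allclose(
            cr.evaluate_rhs(c1, x), cr.evaluate_rhs(c2, x), rtol=1e-12
        )

    def test_structure_only_model_refused(self):
        iw = cr.zoo("iwata_structure")
        red = cr.substitute(iw, [cr.solve_nullcline_ssystem(iw, "X3")])
        with pytest.raises(CannotCollapse):
            cr.collapse_numeric(red)
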