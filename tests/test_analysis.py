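"""Steady-state search, stability classification, oscillation detection,
trajectory comparison and reduction ranking."""

import numpy as np
import pytest
import sympy as sp

import canonred as cr
from canonred import PerturbationEvent as E
from canonred.analysis import SteadyState
from canonred.errors import NoUniqueSteadyState, ValidationError
from canonred.expressions import sym
from canonred.model_core import LVModel, Parameter, PowerLawTerm, SSystemModel
from canonred.synthgen import GeneratorSpec, random_ssystem

from conftest import BISTABLE_STATES, GOODWIN_N4, GOODWIN_N18, goodwin_hill


def _one_dim_ssystem(alpha, beta, h=1.0):
    return SSystemModel(
        dependent=["X1"],
        independent=[],
        production={"X1": PowerLawTerm(+1, sym("a"), {})},
        degradation={"X1": PowerLawTerm(-1, sym("b"), {"X1": h})},
        parameters={"a": Parameter("a", alpha, "rate_constant"),
                    "b": Parameter("b", beta, "rate_constant")},
        initial={"X1": 1.0},
    )


class TestAnalyticSteadyState:
    def test_one_dimensional(self):
        ss = cr.steady_state_analytic_ssystem(_one_dim_ssystem(2.0, 0.5))
        assert ss.state[0] == pytest.approx(4.0)
        assert ss.classification == "stable"

    def test_linear_pathway_exact_fixed_point(self, linear_pathway):
        """Flux balance along the chain gives X5 = 2.5**0.625 exactly; the
        printed state carries ~0.3% numerical residual against this."""
        ss = cr.steady_state_analytic_ssystem(linear_pathway)
        assert ss["X5"] == pytest.approx(2.5**0.625, rel=1e-10)
        assert ss["X1"] == pytest.approx(5.0 / 2.5**0.625, rel=1e-10)
        assert ss.residual < 1e-10

    def test_agrees_with_multistart_newton(self):
        for seed in range(5):
            m = random_ssystem(GeneratorSpec("ssystem", n=4, seed=seed,
                                             require_stable=True))
            analytic = cr.steady_state_analytic_ssystem(m)
            found = cr.find_steady_states(m, n_starts=20, seed=seed)
            assert len(found) >= 1
            best = min(found, key=lambda s: np.max(np.abs(s.state - analytic.state)))
            np.testing.assert_allclose(best.state, analytic.state, rtol=1e-8)

    def test_synthetic_prescribed_point_recovered(self):
        m = random_ssystem(GeneratorSpec("ssystem", n=5, seed=77))
        fp = np.array(m.metadata["fixed_point"])
        ss = cr.steady_state_analytic_ssystem(m)
        np.testing.assert_allclose(ss.state, fp, rtol=1e-10)

    def test_singular_exponent_matrix_rejected(self):
        # two identical equations: (g - h) is singular
        term_p = PowerLawTerm(+1, sym("a"), {"X2": 1})
        term_d = PowerLawTerm(-1, sym("b"), {"X1": 1})
        m = SSystemModel(
            dependent=["X1", "X2"],
            independent=[],
            production={"X1": term_p, "X2": term_p},
            degradation={"X1": term_d, "X2": term_d},
            parameters={"a": Parameter("a", 1.0, "rate_constant"),
                        "b": Parameter("b", 1.0, "rate_constant")},
            initial={"X1": 1.0, "X2": 1.0},
        )
        with pytest.raises(NoUniqueSteadyState):
            cr.steady_state_analytic_ssystem(m)


class TestFindSteadyStates:
    def test_logistic_single_state(self):
        lv = LVModel(
            dependent=["X1", "X2"],
            growth=[sp.Integer(1), sp.Integer(1)],
            interaction=[[sp.Integer(-1), sp.Integer(0)], [sp.Integer(0), sp.Integer(-1)]],
            parameters={},
            initial={"X1": 0.5, "X2": 0.5},
        )
        states = cr.find_steady_states(lv, n_starts=20, seed=0)
        interior = [s for s in states if np.all(s.state > 1e-6)]
        assert len(interior) == 1
        np.testing.assert_allclose(interior[0].state, [1.0, 1.0], rtol=1e-8)

    def test_bistable_three_positive_states(self, bistable):
        states = cr.find_steady_states(bistable, n_starts=60, seed=1)
        assert len(states) == 3
        for found, printed in zip(states, BISTABLE_STATES):
            np.testing.assert_allclose(found.state, printed, rtol=5e-4)
        assert [s.classification for s in states] == ["stable", "unstable", "stable"]

    def test_goodwin_unique_positive_state(self):
        gw = cr.zoo("goodwin")  # n = 4
        states = cr.find_steady_states(gw, n_starts=30, seed=2)
        assert len(states) == 1
        np.testing.assert_allclose(states[0].state[:4], GOODWIN_N4, rtol=5e-4)
        # the auxiliary is lifted through its constraint
        assert states[0]["X5"] == pytest.approx(states[0]["X4"] ** 4 + 1, rel=1e-10)

    def test_deterministic_given_seed(self, bistable):
        a = cr.find_steady_states(bistable, n_starts=30, seed=5)
        b = cr.find_steady_states(bistable, n_starts=30, seed=5)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.state, t.state)


class TestClassifyStability:
    def test_one_dimensional_eigenvalue(self):
        ss = cr.classify_stability(_one_dim_ssystem(1.0, 1.0), [1.0])
        assert ss.classification == "stable"
        assert ss.eigenvalues[0].real == pytest.approx(-1.0)

    def test_bistable_middle_state_unstable(self, bistable):
        states = cr.find_steady_states(bistable, n_starts=60, seed=1)
        mid = cr.classify_stability(bistable, states[1].state)
        assert mid.classification == "unstable"

    def test_goodwin_stability_switches_with_hill_exponent(self):
        s4 = cr.find_steady_states(cr.zoo("goodwin", n_value=4.0), n_starts=20, seed=3)[0]
        s18 = cr.find_steady_states(cr.zoo("goodwin", n_value=18.0), n_starts=20, seed=3)[0]
        assert s4.classification == "stable"
        assert s18.classification == "unstable"
        np.testing.assert_allclose(s18.state[:4], GOODWIN_N18, rtol=5e-4)

    def test_non_fixed_point_rejected(self, bistable):
        with pytest.raises(ValidationError, match="not a fixed point"):
            cr.classify_stability(bistable, [1.0, 1.0, 1.0, 1.0])


class TestDetectOscillation:
    def test_constant_series_converged(self, cascade):
        traj = cr.simulate(cascade, span=(0, 50))
        assert cr.detect_oscillation(traj, "X3").classification == "converged"

    def test_goodwin_damped_at_moderate_hill_exponent(self):
        gw = cr.zoo("goodwin", n_value=4.0)
        traj = cr.simulate(gw, span=(0, 150), schedule=[E(20, "reset_state", "X1", 5.0)])
        rep = cr.detect_oscillation(traj, "X1", transient_fraction=0.2)
        assert rep.classification == "damped_oscillation"
        assert rep.amplitude_trend < 0.99

    def test_goodwin_sustained_at_steep_hill_exponent(self):
        traj = cr.simulate(goodwin_hill(18.0), span=(0, 400),
                           schedule=[E(20, "reset_state", "X1", 5.0)])
        rep = cr.detect_oscillation(traj, "X1")
        assert rep.classification == "sustained_oscillation"
        assert rep.period == pytest.approx(19.2, rel=0.05)

    def test_divergent_series_flagged(self):
        ro = cr.zoo("roessler")
        red = cr.reduce(ro, ["X2"])
        traj = cr.simulate(red, x0=np.array([0.01, 0.0]), span=(0, 300))
        assert cr.detect_oscillation(traj, "X1").classification == "divergent"


class TestCompareTrajectories:
    def _steady(self, model, traj):
        return SteadyState(
            variables=list(traj.variables),
            state=traj.terminal_state(),
            residual=0.0,
            eigenvalues=np.array([]),
            classification="stable",
        )

    def test_identical_trajectories_score_zero(self, cascade):
        traj = cr.simulate(cascade, span=(0, 20))
        rep = cr.compare_trajectories(traj, traj, self._steady(cascade, traj))
        assert all(v == 0.0 for v in rep.rmse.values())
        assert rep.steady_state_match

    def test_resting_system_normalizes_to_one(self, cascade):
        traj = cr.simulate(cascade, span=(0, 20))
        rep = cr.compare_trajectories(traj, traj, self._steady(cascade, traj))
        for z in rep.z_original.values():
            np.testing.assert_allclose(z, 1.0, rtol=1e-6)

    def test_disjoint_variables_rejected(self, cascade):
        traj = cr.simulate(cascade, span=(0, 5))
        other = cr.Trajectory(t=traj.t, series={"Q1": traj.series["X1"]})
        with pytest.raises(ValidationError, match="share no variables"):
            cr.compare_trajectories(traj, other, self._steady(cascade, traj))

    def test_full_vs_reduced_pathway_matches_steady_state(self, linear_pathway):
        sched = [
            E(5, "set_independent", "X0", 4.0),
            E(6, "set_independent", "X0", 1.0),
            E(40, "set_parameter", "b5", 0.8),
        ]
        full = cr.simulate(linear_pathway, span=(0, 200), schedule=sched)
        red = cr.reduce(linear_pathway, ["X2", "X3", "X4"])
        x0 = np.array([linear_pathway.initial[v] for v in red.model.dependent])
        rtraj = cr.simulate(red, x0=x0, span=(0, 200), schedule=sched)
        steady = self._steady(linear_pathway, full)
        rep = cr.compare_trajectories(full, rtraj, steady)
        assert rep.steady_state_match


class TestRankReductions:
    SCENARIO = {
        "span": (0, 120),
        "schedule": [
            E(5, "set_independent", "X0", 4.0),
            E(6, "set_independent", "X0", 1.0),
            E(40, "set_parameter", "b5", 0.8),
        ],
    }

    def test_single_candidate_ranks_first(self, linear_pathway):
        entries = cr.rank_reductions(linear_pathway, [("X4",)], self.SCENARIO, ["X5"])
        assert len(entries) == 1 and entries[0].candidate == ("X4",)
        assert entries[0].feasible

    def test_smaller_elimination_scores_better(self, linear_pathway):
        """Removing only X4 perturbs the X5 response less than removing all
        three intermediates."""
        entries = cr.rank_reductions(
            linear_pathway, [("X2", "X3", "X4"), ("X4",)], self.SCENARIO, ["X5"]
        )
        assert entries[0].candidate == ("X4",)
        assert entries[0].score < entries[1].score

    def test_matches_bruteforce_recomputation(self, linear_pathway):
        """Oracle: an independent loop over candidates reproduces scores and
        ordering."""
        candidates = [("X4",), ("X3", "X4")]
        entries = cr.rank_reductions(linear_pathway, candidates, self.SCENARIO, ["X5"])
        base = cr.simulate(linear_pathway, span=self.SCENARIO["span"],
                           schedule=self.SCENARIO["schedule"])
        ref = base.terminal_state(["X5"])[0]
        brute = {}
        for cand in candidates:
            red = cr.reduce(linear_pathway, list(cand))
            x0 = np.array([linear_pathway.initial[v] for v in red.model.dependent])
            traj = cr.simulate(red, x0=x0, span=self.SCENARIO["span"],
                               schedule=self.SCENARIO["schedule"])
            z0 = base.series["X5"] / ref
            z1 = np.interp(base.t, traj.t, traj.series["X5"]) / ref
            brute[cand] = float(np.sqrt(np.mean((z0 - z1) ** 2)))
        for e in entries:
            assert e.score == pytest.approx(brute[e.candidate], rel=1e-12)
        assert [e.candidate for e in entries] == sorted(brute, key=brute.get)

    def test_infeasible_candidate_recorded(self):
        lv = LVModel(
            dependent=["X1", "X2"],
            growth=[sp.Integer(1), sp.Integer(1)],
            interaction=[[sp.Integer(0), sp.Integer(-1)], [sp.Integer(-1), sp.Integer(-1)]],
            parameters={},
            initial={"X1": 0.5, "X2": 0.5},
        )
        entries = cr.rank_reductions(
            lv, [("X1",)], {"span": (0, 10), "schedule": []}, ["X2"]
        )
        assert len(entries) == 1
        assert not entries[0].feasible and entries[0].score == float("inf")
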