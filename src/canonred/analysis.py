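"""Steady states, stability, oscillation classification, trajectory
comparison and reduction ranking.

Steady states of S-systems are found analytically: equating production and
degradation and taking logarithms turns the fixed-point condition into a
linear system in log-concentrations.  Arbitrary models use seeded multistart
Newton iterations (log-parameterized on the positive orthant, so iterates
can never leave the domain of fractional kinetic orders).

Models carrying recast auxiliary constraints (``A = K**n + X**n``) are
analyzed on the constraint manifold: the auxiliary is substituted out, the
core system is solved, and the auxiliary components are lifted back through
the constraint.  Off-manifold fixed points of the recast equations form
degenerate families and are not steady states of the underlying model.

Stability is read off the Jacobian eigenvalues with a +-1e-9 threshold on
the real parts; anything inside the band is reported as marginal rather
than silently classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import sympy as sp
from scipy.signal import find_peaks

from .errors import NotReducible, NoUniqueSteadyState, ValidationError
from .expressions import sym
from .model_core import SSystemModel
from .reduction import ReducedModel, reduce

__all__ = [
    "SteadyState",
    "ComparisonReport",
    "OscillationReport",
    "steady_state_analytic_ssystem",
    "find_steady_states",
    "classify_stability",
    "detect_oscillation",
    "compare_trajectories",
    "rank_reductions",
]

#: eigenvalue real parts inside this band are classified "marginal"
STABILITY_THRESHOLD = 1e-9


@dataclass
class SteadyState:
    """A fixed point with residual, Jacobian spectrum and stability class."""

    variables: list[str]
    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    classification: str  # stable | unstable | marginal

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=complex)

    def __getitem__(self, name: str) -> float:
        return float(self.state[self.variables.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {v: float(x) for v, x in zip(self.variables, self.state)}


@dataclass
class ComparisonReport:
    """Original-vs-reduced trajectory comparison on steady-state-normalized
    series Z_i = X_i / X_i_steadystate."""

    variables: list[str]
    t: np.ndarray
    z_original: dict[str, np.ndarray]
    z_reduced: dict[str, np.ndarray]
    rmse: dict[str, float]
    max_deviation: float
    steady_state_match: bool


@dataclass
class OscillationReport:
    classification: str  # converged | damped_oscillation | sustained_oscillation | divergent
    period: float | None = None
    amplitude_trend: float | None = None
    note: str = ""


# ---------------------------------------------------------------------------
# Effective (constraint-substituted) systems
# ---------------------------------------------------------------------------


def _strip(model):
    return model.model if isinstance(model, ReducedModel) else model


def _effective_system(model):
    """Return (core variable names, core RHS exprs, lift map aux->expr)."""
    model = _strip(model)
    aux = dict(model.aux_constraints)
    core = [v for v in model.dependent if v not in aux]
    rhs = model.rhs_exprs()
    if not aux:
        return core, [rhs[v] for v in core], {}
    submap = {sym(a): c for a, c in aux.items()}
    core_rhs = [sp.simplify(rhs[v].subs(submap)) for v in core]
    return core, core_rhs, aux


def _numeric_system(model, core, core_rhs):
    model = _strip(model)
    args = [sym(v) for v in core]
    tail_syms = [sym(v) for v in model.independent] + [sym(p) for p in model.parameters]
    f = sp.lambdify(args + tail_syms, core_rhs, modules="numpy")
    jac = sp.lambdify(
        args + tail_syms, sp.Matrix(core_rhs).jacobian(args), modules="numpy"
    )
    tail = model._tail_args()

    def fun(x):
        return np.asarray(f(*x, *tail), dtype=float)

    def jfun(x):
        return np.asarray(jac(*x, *tail), dtype=float)

    return fun, jfun


def _lift(model, core, state_core):
    """Append auxiliary components through their constraints."""
    model = _strip(model)
    aux = model.aux_constraints
    if not aux:
        return list(core), np.asarray(state_core, dtype=float)
    env = {v: float(x) for v, x in zip(core, state_core)}
    env.update({v: float(model.initial[v]) for v in model.independent})
    env.update({p.name: p.value for p in model.parameters.values()})
    names = list(core)
    vals = list(np.asarray(state_core, dtype=float))
    for a, c in aux.items():
        names.append(a)
        vals.append(float(sp.sympify(c).subs({sym(k): v for k, v in env.items()})))
    order = [v for v in model.dependent if v in names]
    lut = dict(zip(names, vals))
    return order, np.array([lut[v] for v in order])


def _classify_eigenvalues(eigs) -> str:
    mx = float(np.max(np.real(eigs)))
    if mx < -STABILITY_THRESHOLD:
        return "stable"
    if mx > STABILITY_THRESHOLD:
        return "unstable"
    return "marginal"


def _steady_state_at(model, core, core_rhs, x_core) -> SteadyState:
    fun, jfun = _numeric_system(model, core, core_rhs)
    res = fun(x_core)
    eigs = np.linalg.eigvals(jfun(x_core))
    names, full = _lift(model, core, x_core)
    return SteadyState(
        variables=names,
        state=full,
        residual=float(np.linalg.norm(res)),
        eigenvalues=eigs,
        classification=_classify_eigenvalues(eigs),
    )


# ---------------------------------------------------------------------------
# Analytic S-system steady state
# ---------------------------------------------------------------------------


def steady_state_analytic_ssystem(model: SSystemModel) -> SteadyState:
    """Solve the S-system fixed point as a linear system in log space.

    alpha_i prod X_j**g_ij = beta_i prod X_j**h_ij  becomes
    sum_j (g_ij - h_ij) y_j = log(beta_i/alpha_i) - sum_indep (g_ij - h_ij) y_j
    with y = log X.  Requires the dependent exponent-difference matrix to be
    nonsingular, otherwise there is no unique positive steady state.
    """
    model = _strip(model)
    if not isinstance(model, SSystemModel):
        raise ValidationError("analytic steady states require an S-system")
    vals = {**model.parameter_values()}
    dep = model.dependent
    n = len(dep)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i, v in enumerate(dep):
        prod, deg = model.production[v], model.degradation[v]
        for j, w in enumerate(dep):
            A[i, j] = float(sp.sympify(prod.exponent(w) - deg.exponent(w)).subs(vals))
        alpha = float(sp.sympify(prod.rate).subs(vals))
        beta = float(sp.sympify(deg.rate).subs(vals))
        rhs = np.log(beta / alpha)
        for w in model.independent:
            e = float(sp.sympify(prod.exponent(w) - deg.exponent(w)).subs(vals))
            rhs -= e * np.log(float(model.initial[w]))
        b[i] = rhs
    if abs(np.linalg.det(A)) < 1e-14 * max(1.0, np.linalg.norm(A)):
        raise NoUniqueSteadyState(
            "dependent exponent-difference matrix (g - h) is singular"
        )
    y = np.linalg.solve(A, b)
    x = np.exp(y)
    rhs_exprs = [model.rhs_exprs()[v] for v in dep]
    return _steady_state_at(model, dep, rhs_exprs, x)


# ---------------------------------------------------------------------------
# Multistart search
# ---------------------------------------------------------------------------


def find_steady_states(
    model,
    n_starts: int = 100,
    seed: int = 0,
    box=None,
    residual_tol: float = 1e-8,
    dedup_tol: float = 1e-6,
) -> list[SteadyState]:
    """Seeded multistart Newton search for fixed points.

    Positive-orthant models use log-uniform starts over [1e-2, 1e2]**n and
    solve in log coordinates; general models use uniform starts over ``box``
    (default [-30, 30]**n).  Results are deduplicated at relative tolerance
    ``dedup_tol``, sorted by first component, and carry stability labels.
    """
    if n_starts < 1:
        raise ValidationError("n_starts must be at least 1")
    stripped = _strip(model)
    core, core_rhs, _aux = _effective_system(stripped)
    fun, jfun = _numeric_system(stripped, core, core_rhs)
    m = len(core)
    rng = np.random.default_rng(seed)
    positive = stripped.requires_positive

    roots: list[np.ndarray] = []
    with np.errstate(all="ignore"):
        roots = _multistart_roots(
            fun, m, rng, positive, box, n_starts, residual_tol, dedup_tol
        )

    roots.sort(key=lambda r: r[0])
    out = [_steady_state_at(stripped, core, core_rhs, r) for r in roots]
    if not out:
        import warnings

        warnings.warn("multistart search found no steady states", stacklevel=2)
    return out


def _multistart_roots(fun, m, rng, positive, box, n_starts, residual_tol, dedup_tol):
    roots: list[np.ndarray] = []
    for _ in range(n_starts):
        if positive:
            y0 = rng.uniform(np.log(1e-2), np.log(1e2), size=m)

            def flog(y):
                return fun(np.exp(y))

            try:
                sol = scipy.optimize.root(flog, y0, method="hybr")
            except (FloatingPointError, ValueError):
                continue
            x = np.exp(sol.x)
        else:
            lo, hi = box if box is not None else (-30.0, 30.0)
            x0 = rng.uniform(lo, hi, size=m)
            try:
                sol = scipy.optimize.root(fun, x0, method="hybr")
            except (FloatingPointError, ValueError):
                continue
            x = sol.x
        if not sol.success:
            continue
        if not np.all(np.isfinite(x)):
            continue
        scale = 1.0 + float(np.max(np.abs(x)))
        if np.linalg.norm(fun(x)) > residual_tol * scale:
            continue
        if positive and np.any(x <= 0):
            continue
        if any(
            np.allclose(x, r, rtol=dedup_tol, atol=dedup_tol * 1e-3) for r in roots
        ):
            continue
        roots.append(x)
    return roots


def classify_stability(model, state) -> SteadyState:
    """Eigenvalue-based stability classification at a fixed point.

    ``state`` is ordered like the model's dependent variables (auxiliary
    components may be included or omitted; they are recomputed through their
    constraints).  Raises if the state is not actually a fixed point.
    """
    stripped = _strip(model)
    core, core_rhs, _aux = _effective_system(stripped)
    state = np.asarray(state, dtype=float)
    if state.shape == (len(stripped.dependent),):
        lut = dict(zip(stripped.dependent, state))
        x_core = np.array([lut[v] for v in core])
    elif state.shape == (len(core),):
        x_core = state
    else:
        raise ValidationError(
            f"state must have {len(stripped.dependent)} (full) or {len(core)} "
            f"(core) components, got {state.shape}"
        )
    fun, _ = _numeric_system(stripped, core, core_rhs)
    res = np.linalg.norm(fun(x_core))
    scale = 1.0 + float(np.max(np.abs(x_core)))
    if res > 1e-6 * scale:
        raise ValidationError(
            f"state is not a fixed point (residual {res:.3e} above 1e-6*scale)"
        )
    return _steady_state_at(stripped, core, core_rhs, x_core)


# ---------------------------------------------------------------------------
# Oscillation detection
# ---------------------------------------------------------------------------


def detect_oscillation(
    traj,
    variable: str,
    transient_fraction: float = 0.5,
    sustained_band: float = 0.01,
) -> OscillationReport:
    """Classify the tail of a trajectory variable.

    Peak detection runs on the post-transient part of the series (the last
    ``1 - transient_fraction`` of the time span).  Successive peak-to-trough
    amplitudes within ``+-sustained_band`` over the last four periods are
    classified as a sustained oscillation; monotonically shrinking
    amplitudes as damped; non-finite or unbounded series as divergent;
    anything else as converged.
    """
    x = np.asarray(traj.series[variable], dtype=float)
    t = traj.t
    if traj.diverged or not np.all(np.isfinite(x)):
        return OscillationReport(
            "divergent", note=traj.metadata.get("diagnostic", "non-finite values")
        )
    scale = float(np.max(x) - np.min(x))
    level = float(np.max(np.abs(x)))
    start = int(len(x) * transient_fraction)
    xt, tt = x[start:], t[start:]
    if scale <= 1e-12 * max(level, 1.0):
        return OscillationReport("converged", note="constant series")

    prominence = 1e-6 * scale
    peaks, _ = find_peaks(xt, prominence=prominence)
    troughs, _ = find_peaks(-xt, prominence=prominence)
    n_extrema = len(peaks) + len(troughs)

    if n_extrema < 5:
        # too few extrema: classify by the terminal trend
        tail_level = np.abs(xt[-1])
        early_level = np.max(np.abs(x[: max(start, 1)]))
        if tail_level > 100.0 * max(early_level, 1.0):
            return OscillationReport("divergent", note="monotone unbounded growth")
        return OscillationReport("converged", note=f"{n_extrema} extrema in the tail")

    # peak-to-trough amplitudes around each detected peak
    amplitudes = []
    times = []
    for p in peaks:
        left = troughs[troughs < p]
        right = troughs[troughs > p]
        lo_candidates = []
        if left.size:
            lo_candidates.append(xt[left[-1]])
        if right.size:
            lo_candidates.append(xt[right[0]])
        if not lo_candidates:
            continue
        amplitudes.append(xt[p] - float(np.mean(lo_candidates)))
        times.append(tt[p])
    if len(amplitudes) < 2:
        return OscillationReport("converged", note="too few full swings")
    amplitudes = np.asarray(amplitudes)
    times = np.asarray(times)
    m = min(5, len(amplitudes))  # last four periods
    a = amplitudes[-m:]
    ratios = a[1:] / a[:-1]
    trend = float(np.mean(ratios))
    period = float(np.mean(np.diff(times[-m:])))

    if np.all(np.abs(ratios - 1.0) <= sustained_band):
        return OscillationReport("sustained_oscillation", period=period, amplitude_trend=trend)
    if trend < 1.0 - sustained_band:
        return OscillationReport("damped_oscillation", period=period, amplitude_trend=trend)
    if trend > 1.0 + sustained_band and np.abs(xt[-1]) > 100.0 * level:
        return OscillationReport("divergent", amplitude_trend=trend, note="growing oscillation")
    return OscillationReport("converged", amplitude_trend=trend, note="mixed amplitude trend")


# ---------------------------------------------------------------------------
# Trajectory comparison and reduction ranking
# ---------------------------------------------------------------------------


def compare_trajectories(original, reduced_traj, steady: SteadyState) -> ComparisonReport:
    """Compare two trajectories on steady-state-normalized series.

    The reduced trajectory is interpolated onto the original's grid; shared
    variables (retained ODEs plus algebraic add-ons) are compared by
    relative RMSE of Z_i = X_i/X_i_steadystate.
    """
    shared = [v for v in original.variables if v in reduced_traj.series]
    if not shared:
        raise ValidationError(
            "trajectories share no variables: "
            f"{original.variables} vs {reduced_traj.variables}"
        )
    t = original.t
    z_o, z_r, rmse = {}, {}, {}
    max_dev = 0.0
    for v in shared:
        ref = steady[v]
        if ref == 0:
            raise ValidationError(f"steady-state normalization of {v!r} divides by zero")
        zo = original.series[v] / ref
        zr = np.interp(t, reduced_traj.t, reduced_traj.series[v]) / ref
        z_o[v], z_r[v] = zo, zr
        rmse[v] = float(np.sqrt(np.mean((zo - zr) ** 2)))
        max_dev = max(max_dev, float(np.max(np.abs(zo - zr))))
    term_o = np.array([original.series[v][-1] for v in shared])
    term_r = np.array([np.interp(t[-1], reduced_traj.t, reduced_traj.series[v]) for v in shared])
    match = bool(
        np.all(np.abs(term_o - term_r) <= 1e-4 * (np.abs(term_o) + 1e-12))
    )
    return ComparisonReport(
        variables=shared,
        t=t,
        z_original=z_o,
        z_reduced=z_r,
        rmse=rmse,
        max_deviation=max_dev,
        steady_state_match=match,
    )


@dataclass
class RankEntry:
    candidate: tuple[str, ...]
    score: float
    feasible: bool = True
    note: str = ""


def rank_reductions(model, candidates, scenario, focus) -> list[RankEntry]:
    """Rank candidate elimination sets by simulation mismatch.

    For each candidate the model is reduced, both models are simulated under
    the scenario (``{"span": ..., "schedule": [...], "x0": ..., "options":
    ...}``), and the score is the mean relative RMSE over the ``focus``
    variables (normalized by the original run's terminal state).  Candidates
    that cannot be reduced are recorded as infeasible with infinite score,
    never silently dropped.
    """
    from .dynamics import simulate  # local import to avoid a cycle

    focus = list(focus)
    span = scenario["span"]
    schedule = scenario.get("schedule", [])
    x0 = scenario.get("x0")
    options = scenario.get("options")

    base = simulate(model, x0=x0, span=span, schedule=schedule, options=options)
    steady = SteadyState(
        variables=list(base.variables),
        state=base.terminal_state(),
        residual=np.nan,
        eigenvalues=np.array([]),
        classification="marginal",
    )

    entries: list[RankEntry] = []
    for cand in candidates:
        cand_t = tuple(cand)
        missing = [v for v in focus if v in cand_t]
        if missing:
            entries.append(
                RankEntry(cand_t, float("inf"), False, f"focus variables {missing} eliminated")
            )
            continue
        try:
            red = reduce(model, list(cand_t))
        except NotReducible as err:
            entries.append(RankEntry(cand_t, float("inf"), False, str(err)))
            continue
        x0_red = (
            None
            if x0 is None
            else np.array(
                [x0[model.dependent.index(v)] for v in red.model.dependent]
            )
        )
        traj = simulate(red, x0=x0_red, span=span, schedule=schedule, options=options)
        if traj.diverged:
            entries.append(RankEntry(cand_t, float("inf"), False, "simulation diverged"))
            continue
        report = compare_trajectories(base, traj, steady)
        score = float(np.mean([report.rmse[v] for v in focus]))
        entries.append(RankEntry(cand_t, score))
    entries.sort(key=lambda e: (e.score, e.candidate))
    return entries
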