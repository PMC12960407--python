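"""ODE integration under timed perturbation schedules.

Simulations are piecewise: the time span is split at every event time, the
integrator restarts at each breakpoint with the mutation applied (parameter
change, independent-variable change, discontinuous state reset, or parameter
scaling), and the pieces are concatenated on a strictly increasing grid
whose value at an event time is the post-event state.

Reduced models integrate only their retained ODEs; algebraic add-ons are
evaluated on the output grid afterwards, never integrated.

Defaults: LSODA (stiff-capable) with rtol 1e-8 / atol 1e-10.  A divergence
guard terminates integration when any state magnitude exceeds 1e12 and marks
the trajectory as divergent with the last reachable time -- expected
behaviour for some chaotic-model reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .errors import DomainError, ValidationError
from .expressions import sym
from .model_core import GMAModel, GeneralODEModel, LVModel, SSystemModel
from .reduction import ReducedModel

__all__ = ["PerturbationEvent", "Trajectory", "TimeScale", "simulate", "apply_time_scale"]

_EVENT_KINDS = {"set_parameter", "set_independent", "reset_state", "scale_parameter"}

#: states beyond this magnitude terminate integration as divergent
#: (recast auxiliaries A = K**n + X**n with steep n legitimately reach ~1e13)
_DIVERGENCE_BOUND = 1e15


@dataclass
class PerturbationEvent:
    """A timed mutation of the running simulation."""

    time: float
    kind: str
    target: str
    value: float

    def __post_init__(self):
        if self.kind not in _EVENT_KINDS:
            raise ValidationError(
                f"unknown event kind {self.kind!r}; expected one of {sorted(_EVENT_KINDS)}"
            )


@dataclass
class TimeScale:
    """Artificial time-scaling factor SF > 0.

    Multiplying every retained right-hand side by SF < 1 slows the reduced
    dynamics down, partially restoring the time delays lost by eliminating
    intermediate variables.  Steady states are unaffected.
    """

    SF: float

    def __post_init__(self):
        if not self.SF > 0:
            raise ValidationError(f"time-scale factor must be positive, got {self.SF}")


@dataclass
class Trajectory:
    """Time grid plus per-variable series (including add-on series for
    reduced models)."""

    t: np.ndarray
    series: dict[str, np.ndarray]
    schedule: list[PerturbationEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("trajectory time grid must be strictly increasing")

    def variable(self, name: str) -> np.ndarray:
        return self.series[name]

    @property
    def variables(self) -> list[str]:
        return list(self.series)

    @property
    def diverged(self) -> bool:
        return bool(self.metadata.get("diverged", False))

    def terminal_state(self, names=None) -> np.ndarray:
        names = names or self.variables
        return np.array([self.series[v][-1] for v in names])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, **self.series})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_schedule(model, schedule, span):
    t0, t1 = span
    events = sorted(schedule, key=lambda e: e.time)
    params = set(model.parameters)
    for e in events:
        if not (t0 <= e.time <= t1):
            raise ValidationError(
                f"event at t={e.time} lies outside the simulation span {span}"
            )
        if e.kind in ("set_parameter", "scale_parameter"):
            if e.target not in params:
                raise ValidationError(f"event targets unknown parameter {e.target!r}")
        elif e.kind == "set_independent":
            if e.target not in model.independent:
                raise ValidationError(
                    f"event targets unknown independent variable {e.target!r}"
                )
        elif e.kind == "reset_state":
            if e.target not in model.dependent:
                raise ValidationError(
                    f"event targets unknown (or eliminated) state variable {e.target!r}"
                )
    return events


def simulate(model, x0=None, span=(0.0, 100.0), schedule=None, options=None) -> Trajectory:
    """Integrate a model (or reduced model) under a perturbation schedule.

    Parameters
    ----------
    model : canonical model or ReducedModel
    x0 : initial state over the model's dependent variables (defaults to the
        model's declared initial values)
    span : (t0, t1)
    schedule : list of PerturbationEvent
    options : dict with any of rtol, atol, method, points_per_unit, max_points
    """
    reduced = model if isinstance(model, ReducedModel) else None
    core = model.model if reduced is not None else model

    options = dict(options or {})
    rtol = float(options.pop("rtol", 1e-8))
    atol = float(options.pop("atol", 1e-10))
    method = options.pop("method", "LSODA")
    points_per_unit = float(options.pop("points_per_unit", 10.0))
    max_points = int(options.pop("max_points", 20001))
    if options:
        raise ValidationError(f"unknown simulate options {sorted(options)}")

    t0, t1 = float(span[0]), float(span[1])
    if not t1 > t0:
        raise ValidationError(f"empty simulation span {span}")
    schedule = _validate_schedule(core, schedule or [], (t0, t1))

    x = np.asarray(x0 if x0 is not None else core.initial_state(), dtype=float)
    if x.shape != (core.n,):
        raise ValidationError(f"x0 has shape {x.shape}, expected ({core.n},)")

    breakpoints = [t0] + [e.time for e in schedule if t0 < e.time < t1] + [t1]
    # merge events at identical times
    breakpoints = sorted(set(breakpoints))
    events_at = {}
    for e in schedule:
        events_at.setdefault(e.time, []).append(e)

    overrides: dict[str, float] = {}
    for e in events_at.get(t0, []):
        x, overrides = _apply_event(core, e, x, overrides)

    n_total = min(max_points, max(int(points_per_unit * (t1 - t0)), 200))

    def guard(t, y):
        return _DIVERGENCE_BOUND - np.max(np.abs(y))

    guard.terminal = True
    guard.direction = -1

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    seg_overrides: list[tuple[int, dict]] = []  # (start index into grid, overrides)
    meta: dict = {"method": method, "rtol": rtol, "atol": atol}
    diverged = False
    grid_len = 0

    for si in range(len(breakpoints) - 1):
        ta, tb = breakpoints[si], breakpoints[si + 1]
        n_seg = max(int(round(n_total * (tb - ta) / (t1 - t0))), 20)
        t_eval = np.linspace(ta, tb, n_seg)
        rhs = core.rhs_function(overrides)
        try:
            sol = solve_ivp(
                rhs, (ta, tb), x, method=method, t_eval=t_eval,
                rtol=rtol, atol=atol, events=[guard], dense_output=False,
            )
        except DomainError as err:
            diverged = True
            meta["diagnostic"] = f"{err}; integration stopped in segment starting t={ta:.6g}"
            break
        last = si == len(breakpoints) - 2
        keep = slice(None) if last or sol.status != 0 else slice(None, -1)
        seg_t, seg_y = sol.t[keep], sol.y[:, keep]
        if seg_t.size:
            ts.append(seg_t)
            ys.append(seg_y)
            seg_overrides.append((grid_len, dict(overrides)))
            grid_len += seg_t.size
        if sol.status == 1:  # divergence guard fired
            diverged = True
            meta["diagnostic"] = (
                f"state magnitude exceeded {_DIVERGENCE_BOUND:g}; "
                f"last reachable time t={sol.t_events[0][0]:.6g}"
            )
            break
        if sol.status != 0:
            diverged = True
            meta["diagnostic"] = (
                f"integration failed ({sol.message.strip()}); "
                f"last reachable time t={sol.t[-1] if sol.t.size else ta:.6g}"
            )
            break
        x = sol.y[:, -1]
        if not last:
            for e in events_at.get(tb, []):
                x, overrides = _apply_event(core, e, x, overrides)

    meta["diverged"] = diverged
    if not ts:
        raise ValidationError("integration produced no output points")
    t_grid = np.concatenate(ts)
    y_grid = np.concatenate(ys, axis=1)
    # enforce strict monotonicity (guard against duplicated breakpoints)
    keep_idx = np.concatenate([[True], np.diff(t_grid) > 0])
    t_grid, y_grid = t_grid[keep_idx], y_grid[:, keep_idx]

    series = {v: y_grid[i] for i, v in enumerate(core.dependent)}

    if reduced is not None and reduced.addons:
        addon_series = _evaluate_addons(reduced, core, t_grid, y_grid, seg_overrides, keep_idx)
        series.update(addon_series)

    return Trajectory(t=t_grid, series=series, schedule=schedule, metadata=meta)


def _apply_event(model, event, x, overrides):
    overrides = dict(overrides)
    x = x.copy()
    if event.kind == "reset_state":
        x[model.dependent.index(event.target)] = event.value
    elif event.kind == "set_parameter":
        overrides[event.target] = float(event.value)
    elif event.kind == "scale_parameter":
        base = overrides.get(event.target)
        if base is None:
            base = model.parameters[event.target].value
            if base is None:
                raise ValidationError(
                    f"cannot scale unbound parameter {event.target!r}"
                )
        overrides[event.target] = float(base) * event.value
    elif event.kind == "set_independent":
        overrides[event.target] = float(event.value)
    return x, overrides


def _evaluate_addons(reduced, core, t_grid, y_grid, seg_overrides, keep_idx):
    """Evaluate eliminated variables as algebraic functions of the retained
    state, per segment so that parameter events take effect."""
    args = (
        [sym(v) for v in core.dependent]
        + [sym(v) for v in core.independent]
        + [sym(p) for p in core.parameters]
    )
    fns = {
        name: sp.lambdify(args, s.expr, modules="numpy")
        for name, s in reduced.addons.items()
    }
    # map original segment start indices through the dedup mask
    old_to_new = np.cumsum(keep_idx) - 1
    out = {name: np.empty_like(t_grid) for name in fns}
    bounds = [old_to_new[start] for start, _ in seg_overrides] + [t_grid.size]
    for si, (_, ov) in enumerate(seg_overrides):
        lo, hi = bounds[si], bounds[si + 1]
        if hi <= lo:
            continue
        tail = core._tail_args(ov)
        cols = [y_grid[i, lo:hi] for i in range(core.n)]
        for name, f in fns.items():
            vals = f(*cols, *tail)
            out[name][lo:hi] = np.broadcast_to(vals, (hi - lo,))
    return out


def apply_time_scale(model, ts: TimeScale):
    """Multiply every retained ODE right-hand side by SF.

    Algebraic add-ons are untouched; steady states are invariant because the
    zeros of the RHS do not move under positive scaling.
    """
    if isinstance(ts, (int, float)):
        ts = TimeScale(float(ts))
    if isinstance(model, ReducedModel):
        return ReducedModel(
            apply_time_scale(model.model, ts),
            dict(model.addons),
            list(model.elimination_record),
            model.parent,
            list(model.warnings),
        )
    sf = sp.Rational(repr(float(ts.SF)))
    if sf == 1:
        return model
    if isinstance(model, SSystemModel):
        scale = lambda t: type(t)(t.sign, sf * t.rate, dict(t.exponents))  # noqa: E731
        return model.with_updates(
            production={v: scale(t) for v, t in model.production.items()},
            degradation={v: scale(t) for v, t in model.degradation.items()},
        )
    if isinstance(model, GMAModel):
        return model.with_updates(
            term_lists={
                v: [type(t)(t.sign, sf * t.rate, dict(t.exponents)) for t in ts_]
                for v, ts_ in model.term_lists.items()
            }
        )
    if isinstance(model, LVModel):
        return model.with_updates(
            growth=[sf * g for g in model.growth],
            interaction=[[sf * b for b in row] for row in model.interaction],
        )
    if isinstance(model, GeneralODEModel):
        return model.with_updates(rhs={v: sf * e for v, e in model.rhs.items()})
    raise ValidationError(f"cannot time-scale model of class {model.model_class!r}")
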