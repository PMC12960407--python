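"""Seeded generators of random canonical models with known fixed points.

Every generated model is constructed *around* a prescribed positive fixed
point: exponents and degradation constants are drawn first, then the
production constants are set so the prescribed point zeroes every equation
exactly.  With ``require_stable`` the draw is rejected (and retried) until
the Jacobian at the fixed point has all eigenvalue real parts below
-1e-9.  The random stream is a named, seeded generator; the same seed
reproduces the same model field-by-field.

Defaults mirror common pathway-model heuristics: off-diagonal kinetic
orders in [-1, 1] (about 0.5 for substrates, -1 for inhibitors), diagonal
degradation orders in [0.1, 1], production not autoregulated.  Because
h_kk > 0 = g_kk by construction, every variable of a generated S-system is
admissible for nullcline elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .errors import GenerationFailed, ValidationError
from .expressions import sym
from .model_core import LVModel, Parameter, PowerLawTerm, SSystemModel

__all__ = ["GeneratorSpec", "random_ssystem", "random_lv"]


@dataclass
class GeneratorSpec:
    """Specification for one random canonical model."""

    model_class: str  # "ssystem" | "lv"
    n: int
    seed: int
    kinetic_order_range: tuple[float, float] = (-1.0, 1.0)
    diagonal_range: tuple[float, float] = (0.1, 1.0)
    rate_range: tuple[float, float] = (0.5, 2.0)
    fixed_point: np.ndarray | None = None
    fixed_point_range: tuple[float, float] = (0.1, 10.0)
    sparsity: float = 0.5
    require_stable: bool = False
    max_retries: int = 200
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_class not in ("ssystem", "lv"):
            raise ValidationError(f"unknown generator class {self.model_class!r}")
        if self.n < 2:
            raise ValidationError("generated models need n >= 2")
        if not (0.0 <= self.sparsity <= 1.0):
            raise ValidationError("sparsity must lie in [0, 1]")
        if self.fixed_point is not None:
            self.fixed_point = np.asarray(self.fixed_point, dtype=float)
            if self.fixed_point.shape != (self.n,) or np.any(self.fixed_point <= 0):
                raise ValidationError(
                    "prescribed fixed point must be a positive vector of length n"
                )


def _draw_fixed_point(spec: GeneratorSpec, rng) -> np.ndarray:
    if spec.fixed_point is not None:
        return spec.fixed_point
    lo, hi = spec.fixed_point_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n))


def _stable(eigs) -> bool:
    return float(np.max(np.real(eigs))) < -1e-9


def random_ssystem(spec: GeneratorSpec) -> SSystemModel:
    """Random S-system with a prescribed (exact) positive fixed point."""
    if spec.model_class != "ssystem":
        raise ValidationError("spec.model_class must be 'ssystem'")
    rng = np.random.default_rng(spec.seed)
    names = [f"X{i+1}" for i in range(spec.n)]
    lo, hi = spec.kinetic_order_range
    for attempt in range(1, spec.max_retries + 1):
        xstar = _draw_fixed_point(spec, rng)
        g = np.zeros((spec.n, spec.n))
        h = np.zeros((spec.n, spec.n))
        for i in range(spec.n):
            h[i, i] = rng.uniform(*spec.diagonal_range)
            for j in range(spec.n):
                if j != i and rng.uniform() > spec.sparsity:
                    g[i, j] = rng.uniform(lo, hi)
        beta = rng.uniform(*spec.rate_range, size=spec.n)
        # alpha_i so that the prescribed point zeroes equation i exactly
        alpha = beta * np.prod(xstar**h, axis=1) / np.prod(xstar**g, axis=1)
        # Jacobian of an S-system at x*: J_ij = (alpha_i prod x**g) g_ij / x_j - ...
        flux = beta * np.prod(xstar**h, axis=1)  # = production flux at x*
        J = (flux[:, None] * (g - h)) / xstar[None, :]
        if spec.require_stable and not _stable(np.linalg.eigvals(J)):
            continue
        params: dict[str, Parameter] = {}
        production, degradation = {}, {}
        for i, v in enumerate(names):
            a, b = f"alpha{i+1}", f"beta{i+1}"
            params[a] = Parameter(a, float(alpha[i]), "rate_constant")
            params[b] = Parameter(b, float(beta[i]), "rate_constant")
            production[v] = PowerLawTerm(
                +1,
                sym(a),
                {
                    names[j]: sp.Float(g[i, j], 15)
                    for j in range(spec.n)
                    if g[i, j] != 0
                },
            )
            degradation[v] = PowerLawTerm(-1, sym(b), {v: sp.Float(h[i, i], 15)})
        return SSystemModel(
            dependent=names,
            independent=[],
            production=production,
            degradation=degradation,
            parameters=params,
            initial={v: float(xstar[i]) for i, v in enumerate(names)},
            metadata={
                "generator": "random_ssystem",
                "seed": spec.seed,
                "fixed_point": [float(x) for x in xstar],
            },
        )
    raise GenerationFailed(spec.max_retries, "no stable S-system found")


def random_lv(spec: GeneratorSpec) -> LVModel:
    """Random LV model with strictly negative self-interactions and a
    prescribed interior fixed point (a = -B x*, exactly)."""
    if spec.model_class != "lv":
        raise ValidationError("spec.model_class must be 'lv'")
    rng = np.random.default_rng(spec.seed)
    names = [f"X{i+1}" for i in range(spec.n)]
    for attempt in range(1, spec.max_retries + 1):
        xstar = _draw_fixed_point(spec, rng)
        B = np.zeros((spec.n, spec.n))
        for i in range(spec.n):
            B[i, i] = -rng.uniform(0.5, 1.5)
            for j in range(spec.n):
                if j != i and rng.uniform() > spec.sparsity:
                    B[i, j] = rng.uniform(-0.5, 0.5)
        a = -B @ xstar
        # Jacobian at the interior fixed point: J = diag(x*) B
        J = xstar[:, None] * B
        if spec.require_stable and not _stable(np.linalg.eigvals(J)):
            continue
        params: dict[str, Parameter] = {}
        growth, interaction = [], []
        for i in range(spec.n):
            gname = f"a{i+1}"
            params[gname] = Parameter(gname, float(a[i]), "lv_growth")
            growth.append(sym(gname))
            row = []
            for j in range(spec.n):
                if B[i, j] == 0:
                    row.append(sp.Integer(0))
                else:
                    bname = f"b{i+1}{j+1}"
                    params[bname] = Parameter(bname, float(B[i, j]), "lv_interaction")
                    row.append(sym(bname))
            interaction.append(row)
        return LVModel(
            dependent=names,
            growth=growth,
            interaction=interaction,
            parameters=params,
            initial={v: float(xstar[i]) for i, v in enumerate(names)},
            metadata={
                "generator": "random_lv",
                "seed": spec.seed,
                "fixed_point": [float(x) for x in xstar],
            },
        )
    raise GenerationFailed(spec.max_retries, "no stable LV model found")
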