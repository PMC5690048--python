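"""Penalized quadratic fluence-map optimization.

The objective is the classic penalized sum of piecewise squared dose
deviations over all constrained VOIs,

    F(w) = sum_V (1/n_V) [ p_V^max * sum_{i in V} phi_i {d_i - d_V^max}_+^2
                         + p_V^min * sum_{i in V} phi_i {d_V^min - d_i}_+^2 ]

with d = D w, w >= 0, and {x}_+ = max(x, 0).  The per-voxel factor phi_i
multiplies both deviation terms; with phi identically 1 the modified
objective reduces exactly to the conventional one.  Minimization uses
bound-constrained limited-memory BFGS with the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt
from scipy import sparse

from .dose import DoseInfluence
from .grid import StructureSet

__all__ = [
    "VoiConstraint",
    "ConstraintSet",
    "FluencePlan",
    "objective",
    "gradient",
    "optimize",
]


@dataclass(frozen=True)
class VoiConstraint:
    """Reference doses (Gy) and penalties for one VOI; absent entries are
    inactive.  d_min = d_max is legitimate (a strict prescription)."""

    d_max: float | None = None
    p_max: float = 0.0
    d_min: float | None = None
    p_min: float = 0.0

    def __post_init__(self) -> None:
        if self.p_max < 0 or self.p_min < 0:
            raise ValueError("penalties must be non-negative")


class ConstraintSet(dict):
    """Mapping VOI name -> :class:`VoiConstraint`."""

    @classmethod
    def from_dict(cls, spec: dict) -> "ConstraintSet":
        out = cls()
        for name, c in spec.items():
            if isinstance(c, VoiConstraint):
                out[name] = c
            else:
                out[name] = VoiConstraint(
                    d_max=c.get("d_max"),
                    p_max=float(c.get("p_max", 0.0)),
                    d_min=c.get("d_min"),
                    p_min=float(c.get("p_min", 0.0)),
                )
        return out

    def validate(self, structures: StructureSet) -> None:
        for name in self:
            if name not in structures:
                raise KeyError(
                    f"constraint references unknown VOI {name!r}; "
                    f"known: {[s.name for s in structures.structures]}"
                )


@dataclass
class FluencePlan:
    """Non-negative beamlet weights plus optimizer provenance."""

    w: np.ndarray
    provenance: str = ""
    objective_value: float = np.nan
    objective_history: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("beamlet weights must be non-negative")


def _voi_terms(structures: StructureSet, constraints: ConstraintSet):
    """Flat voxel indices and constraint parameters per constrained VOI."""
    terms = []
    for name, c in constraints.items():
        s = structures[name]
        idx = np.flatnonzero(s.mask.ravel())
        if idx.size == 0:
            raise ValueError(f"VOI {name!r} has zero voxels (1/n_V undefined)")
        terms.append((name, idx, c))
    return terms


def _deviation(d, idx, c, phi):
    """Weighted piecewise residual r_i and its dose-derivative g_i on a VOI:
    value contribution = sum phi * r2, gradient factor = 2 * phi * g."""
    dv = d[idx]
    p = phi[idx] if phi is not None else 1.0
    r2 = np.zeros_like(dv)
    g = np.zeros_like(dv)
    if c.d_max is not None and c.p_max > 0:
        over = np.maximum(dv - c.d_max, 0.0)
        r2 += c.p_max * over * over
        g += c.p_max * over
    if c.d_min is not None and c.p_min > 0:
        under = np.maximum(c.d_min - dv, 0.0)
        r2 += c.p_min * under * under
        g -= c.p_min * under
    return p * r2, p * g


def objective(
    w: np.ndarray,
    dij: DoseInfluence,
    structures: StructureSet,
    constraints: ConstraintSet,
    phi: np.ndarray | None = None,
) -> float:
    """Evaluate the (phi-modified) penalized quadratic objective at ``w``."""
    d = dij.dose(np.asarray(w, dtype=float))
    phi_flat = None if phi is None else np.asarray(phi, dtype=float).ravel()
    total = 0.0
    for _, idx, c in _voi_terms(structures, constraints):
        r2, _ = _deviation(d, idx, c, phi_flat)
        total += r2.sum() / idx.size
    return float(total)


def gradient(
    w: np.ndarray,
    dij: DoseInfluence,
    structures: StructureSet,
    constraints: ConstraintSet,
    phi: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic gradient of :func:`objective` with respect to the beamlet
    weights: dF/dw_j = sum_V (2/n_V) sum_{i in V} phi_i [p_max {d_i-d_max}_+
    - p_min {d_min-d_i}_+] D_ij."""
    d = dij.dose(np.asarray(w, dtype=float))
    phi_flat = None if phi is None else np.asarray(phi, dtype=float).ravel()
    res = np.zeros(dij.n_voxels)
    for _, idx, c in _voi_terms(structures, constraints):
        _, g = _deviation(d, idx, c, phi_flat)
        res[idx] += 2.0 * g / idx.size
    return np.asarray(dij.matrix.T @ res).ravel()


def default_start(dij: DoseInfluence, structures: StructureSet) -> np.ndarray:
    """Uniform weights scaled so the mean dose over all target voxels
    equals the voxel-averaged prescription."""
    tmask = np.zeros(structures.grid.shape, dtype=bool)
    dsum = 0.0
    for t in structures.targets:
        tmask |= t.mask
        dsum += t.dpres * t.n_voxels
    idx = np.flatnonzero(tmask.ravel())
    dpres_mean = sum(
        t.dpres * (t.mask & tmask).sum() for t in structures.targets
    ) / idx.size
    ones = np.ones(dij.n_beamlets)
    mean_unit = float((dij.matrix[idx] @ ones).mean())
    scale = dpres_mean / mean_unit if mean_unit > 0 else 1.0
    return np.full(dij.n_beamlets, scale)


def optimize(
    w0: np.ndarray | None,
    dij: DoseInfluence,
    structures: StructureSet,
    constraints: ConstraintSet,
    phi: np.ndarray | None = None,
    options: dict | None = None,
) -> FluencePlan:
    """Minimize the objective over the non-negative orthant with L-BFGS-B.

    ``options`` may set ``max_iter`` (default 500), ``gtol`` (projected
    gradient tolerance, default 1e-7), ``ftol`` (default 1e-12) and
    ``history_size`` (default 20).  Returns the plan together with the
    objective trace over accepted iterations (non-increasing).
    """
    constraints.validate(structures)
    opts = dict(options or {})
    max_iter = int(opts.pop("max_iter", 500))
    gtol = float(opts.pop("gtol", 1e-7))
    ftol = float(opts.pop("ftol", 1e-12))
    m = int(opts.pop("history_size", 20))
    if opts:
        raise ValueError(f"unknown optimizer options: {sorted(opts)}")

    if w0 is None:
        w0 = default_start(dij, structures)
    w0 = np.asarray(w0, dtype=float)
    if np.any(w0 < 0):
        raise ValueError("initial weights must be non-negative")

    phi_flat = None if phi is None else np.asarray(phi, dtype=float).ravel()
    terms = _voi_terms(structures, constraints)
    D = dij.matrix
    subs = [(D[idx], idx, c) for _, idx, c in terms]

    def fun(w):
        d = D @ w
        total = 0.0
        res = np.zeros(D.shape[0])
        for Dv, idx, c in subs:
            r2, g = _deviation(d, idx, c, phi_flat)
            total += r2.sum() / idx.size
            res[idx] += 2.0 * g / idx.size
        return total, np.asarray(D.T @ res).ravel()

    f0 = fun(w0)[0]
    if not np.isfinite(f0):
        raise ValueError(f"objective is not finite at the start point (F={f0})")

    history = [f0]
    result = sciopt.minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=sciopt.Bounds(0.0, np.inf),
        callback=lambda xk: history.append(fun(xk)[0]),
        options={"maxiter": max_iter, "gtol": gtol, "ftol": ftol, "maxcor": m},
    )
    w_star = np.maximum(result.x, 0.0)
    f_star = fun(w_star)[0]
    if f_star > f0:  # never accept an ascent over the start point
        w_star, f_star = w0, f0
    return FluencePlan(
        w=w_star,
        provenance=f"L-BFGS-B maxiter={max_iter} gtol={gtol}",
        objective_value=f_star,
        objective_history=history,
        n_iterations=int(result.nit),
        converged=bool(result.success),
    )


def as_dose_cube(dij: DoseInfluence, w: np.ndarray, shape) -> np.ndarray:
    """Dose distribution D @ w reshaped onto the voxel grid."""
    return dij.dose(w).reshape(shape)
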