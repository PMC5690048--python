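"""Dose-driven voxel-wise penalty adaptation with penumbra suppression.

The naive heuristic raises the penalty scale phi of a normal-tissue voxel
according to how far its dose exceeds the tolerated level, relative to a
threshold dose d_T:

    phi_O(d) = [ {d - d_max}_+^2 / (d_T - d_max)^2 ]^alpha

so phi_O(d_T) = 1 and hot voxels (d > d_T) get quadratically growing
penalties.  Applied blindly, this also penalizes the penumbra shoulder
right outside the target, where high dose is physically unavoidable, and
the reoptimizer responds by pushing the penumbra inward — losing coverage.

The physical variant therefore suppresses the scaling near targets.  From
the erfc penumbra model, a dose level d at a target border is acceptable
out to the distance

    delta_P(d) = sqrt(2) * sigma_p * (erfc^-1(2 d / d_pres) + c)

(the inverse of the penumbra profile; c is the 95% coverage shift).  A
suppression factor S in [0, 1] is 1 (full suppression, phi = 1) for
voxels within delta_P, decays quadratically over a release margin
Delta_delta, and is 0 beyond it; doses at or above the prescription use an
exponential correction that shortens the allowed region.  The final scale
is the interpolation

    phi_S = phi_O - (phi_O - 1) * S.

With several prescription levels, each voxel uses the group for which it
is most "inside" the allowed region, i.e. the smallest delta - delta_P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcinv

from .distance import DistanceMap
from .dose import COVERAGE_SHIFT, SQRT2
from .fluence import ConstraintSet, VoiConstraint
from .grid import StructureSet

__all__ = [
    "AdaptationParams",
    "phi_naive",
    "delta_p",
    "suppression",
    "phi_suppressed",
    "compute_penalty_scale",
]


@dataclass(frozen=True)
class AdaptationParams:
    """Tunables of the penalty-adaptation heuristic.

    alpha : scaling power of the naive heuristic (1 = match the local
        objective at the threshold dose).
    d_T : Gy, dose above which normal tissue counts as a hot-spot; must
        exceed the adapted VOI's d_max so the normalizer is positive.
    delta_delta : mm, release margin over which suppression fades out.
    sigma_p : mm, penumbra width of the beam model.
    clamp_low : keep phi >= 1 (adaptation only ever *raises* penalties);
        the unclamped literal heuristic is available for comparison.
    n_runs : number of adaptation + reoptimization cycles.
    mode : "physical" (suppressed phi_S) or "naive" (raw phi_O).
    """

    alpha: float = 1.0
    d_T: float = 35.0
    delta_delta: float = 12.0
    sigma_p: float = 3.2
    clamp_low: bool = True
    n_runs: int = 2
    mode: str = "physical"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.delta_delta <= 0:
            raise ValueError("delta_delta must be positive")
        if self.sigma_p <= 0:
            raise ValueError("sigma_p must be positive")
        if self.mode not in ("physical", "naive"):
            raise ValueError(f"unknown adaptation mode {self.mode!r}")
        if self.n_runs < 0:
            raise ValueError("n_runs must be >= 0")


def phi_naive(d, voi_constraint: VoiConstraint, params: AdaptationParams):
    """Naive dose-driven penalty scale phi_O for the adapted VOI.

    Uses the VOI's overdose term: phi_O = ({d - d_max}_+ / (d_T - d_max))
    ^(2*alpha), clamped to >= 1 unless ``clamp_low`` is off.
    """
    d_max = voi_constraint.d_max
    if d_max is None:
        raise ValueError("adapted VOI needs a d_max constraint")
    if params.d_T <= d_max:
        raise ValueError(
            f"threshold d_T={params.d_T} Gy must exceed the adapted VOI's "
            f"d_max={d_max} Gy"
        )
    d = np.asarray(d, dtype=float)
    over = np.maximum(d - d_max, 0.0)
    phi = (over / (params.d_T - d_max)) ** (2.0 * params.alpha)
    if params.clamp_low:
        phi = np.maximum(phi, 1.0)
    return phi if phi.ndim else float(phi)


def delta_p(d, dpres: float, sigma_p: float = 3.2, cap: float = 1e6):
    """Allowed penumbra distance (mm) for dose level ``d``: how far from
    the target border the penumbra model still explains a dose d.

    Inverts the erfc profile; zero for d in the 95%..100% prescription
    band (where the inversion would go negative), and capped at ``cap``
    for vanishing doses where the inverse erfc diverges.  Only meaningful
    for d < dpres; higher doses are handled by the suppression branch.
    """
    if dpres <= 0:
        raise ValueError("dpres must be positive")
    d = np.asarray(d, dtype=float)
    ratio = np.clip(2.0 * d / dpres, 0.0, 2.0)
    with np.errstate(over="ignore"):
        out = SQRT2 * sigma_p * (erfcinv(np.maximum(ratio, 1e-300)) + COVERAGE_SHIFT)
    out = np.where(ratio < 1e-12, cap, out)
    out = np.minimum(np.maximum(out, 0.0), cap)
    return out if out.ndim else float(out)


def suppression(d, delta, dpres: float, params: AdaptationParams, cap: float = 1e6):
    """Suppression factor S(d, delta) in [0, 1].

    Below the prescription, S = 1 inside the allowed distance delta_P(d),
    fades quadratically over the release margin Delta_delta, and is 0
    beyond.  At or above the prescription (where the inversion is
    undefined) the allowed region is shortened by an exponential factor:
    S = {1 - (delta/Delta_delta)^2 * exp[5 (d/dpres - 1)]}_+ .
    """
    d = np.asarray(d, dtype=float)
    delta = np.asarray(delta, dtype=float)
    d, delta = np.broadcast_arrays(d, delta)
    dd = params.delta_delta

    dp = delta_p(d, dpres, params.sigma_p, cap=cap)
    excess = delta - dp
    s_low = np.where(
        excess <= 0.0,
        1.0,
        np.where(excess < dd, 1.0 - (excess / dd) ** 2, 0.0),
    )
    with np.errstate(over="ignore"):
        s_high = 1.0 - (delta / dd) ** 2 * np.exp(5.0 * (d / dpres - 1.0))
    s = np.where(d < dpres, s_low, np.clip(s_high, 0.0, 1.0))
    return s if s.ndim else float(s)


def phi_suppressed(phi_o, s):
    """Interpolate between no scaling (S = 1 -> phi = 1) and the naive
    scale (S = 0 -> phi = phi_O): phi_S = phi_O - (phi_O - 1) S."""
    phi_o = np.asarray(phi_o, dtype=float)
    s = np.asarray(s, dtype=float)
    out = phi_o - (phi_o - 1.0) * s
    return out if out.ndim else float(out)


def compute_penalty_scale(
    dose: np.ndarray,
    structures: StructureSet,
    distance_maps: dict[float, DistanceMap],
    params: AdaptationParams,
    constraints: ConstraintSet,
    region: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel penalty scale from the latest dose distribution.

    Inside the adaptation region (normal tissue by default) each voxel
    gets phi_O from its dose and — in physical mode — the suppression of
    the prescription group with the smallest delta - delta_P, ties going
    to the lowest prescription.  Everywhere else phi = 1.
    """
    if not distance_maps:
        raise ValueError("no prescription groups / distance maps supplied")
    if region is None:
        region = structures.adaptation_region()
    body_name = structures.body.name
    if body_name not in constraints:
        raise KeyError(f"no constraint entry for adapted VOI {body_name!r}")

    dose = np.asarray(dose, dtype=float).reshape(structures.grid.shape)
    phi = np.ones(structures.grid.shape)
    idx = region
    d = dose[idx]
    phi_o = phi_naive(d, constraints[body_name], params)

    if params.mode == "naive":
        phi[idx] = phi_o
        return phi

    cap = structures.grid.diameter()
    groups = sorted(distance_maps)  # ascending dpres -> ties pick lowest
    best_excess = None
    best_s = None
    for dpres in groups:
        delta = distance_maps[dpres].delta[idx]
        dp = delta_p(d, dpres, params.sigma_p, cap=cap)
        excess = delta - dp
        s = suppression(d, delta, dpres, params, cap=cap)
        if best_excess is None:
            best_excess, best_s = excess, s
        else:
            take = excess < best_excess  # strict: ties keep lower dpres
            best_excess = np.where(take, excess, best_excess)
            best_s = np.where(take, s, best_s)

    phi[idx] = phi_suppressed(phi_o, best_s)
    return phi
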