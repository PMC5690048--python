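"""Toy photon dose engine with analytic erfc penumbra.

The engine produces a sparse dose-influence matrix D (voxels x beamlets)
for parallel coplanar beams on a phantom.  Each beamlet deposits

    d(voxel) = exp(-mu * depth) * slit(lateral offset)

where ``depth`` is the path length inside the body upstream of the voxel
and ``slit`` is the lateral profile of a finite bixel: the convolution of
a rectangle of the bixel width with a Gaussian penumbra kernel of width
sigma_p, i.e. a difference of error functions.  This keeps the lateral
falloff — the physics the penalty-suppression heuristic reasons about —
quantitatively right while making no claim to depth-dose realism (single
exponential, no buildup, sigma_p constant with depth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import erf, erfc, erfinv

from .grid import StructureSet

__all__ = [
    "COVERAGE_SHIFT",
    "BeamSetup",
    "DoseInfluence",
    "penumbra_profile",
    "slit_profile",
    "compute_dij",
]

#: Lateral shift (in units of sqrt(2)*sigma_p) placing the target border on
#: the 95% level of the penumbra: solves (1/2)*erfc(-c) = 0.95, i.e.
#: c = erfinv(0.9) ~= 1.16309.
COVERAGE_SHIFT = float(erfinv(0.9))

SQRT2 = np.sqrt(2.0)


def penumbra_profile(delta, dpres: float, sigma_p: float = 3.2):
    """Idealized penumbra dose at lateral distance ``delta`` (mm) from a
    target border.

    dP(delta) = (1/2) * dpres * erfc(delta / (sqrt(2)*sigma_p) - c) with the
    coverage shift c chosen so dP(0) = 0.95*dpres: the border itself still
    receives 95% of the prescription.  Monotone non-increasing in delta,
    tending to dpres far inside and 0 far outside.
    """
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    if dpres <= 0:
        raise ValueError("dpres must be positive")
    delta = np.asarray(delta, dtype=float)
    out = 0.5 * dpres * erfc(delta / (SQRT2 * sigma_p) - COVERAGE_SHIFT)
    return out if out.ndim else float(out)


def slit_profile(delta, bixel_width: float = 5.0, sigma_p: float = 3.2):
    """Lateral profile of a single bixel: rectangle (width b) convolved
    with a Gaussian of std sigma_p, normalized to unit open-field value."""
    delta = np.asarray(delta, dtype=float)
    s = SQRT2 * sigma_p
    out = 0.5 * (erf((delta + bixel_width / 2) / s) - erf((delta - bixel_width / 2) / s))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BeamSetup:
    """Parallel coplanar beam arrangement.

    Angles follow the gantry convention: 0 deg enters from +y travelling
    toward -y, increasing clockwise when looking along +z.
    """

    gantry_angles: tuple[float, ...] = (0.0, 50.0, 100.0, 155.0, 200.0, 260.0, 310.0)
    bixel_width: float = 5.0  # mm
    sigma_p: float = 3.2  # mm, lateral penumbra width
    attenuation_mu: float = 0.005  # per mm
    dose_scale: float = 1.0  # Gy per unit weight on the central axis at depth 0

    def __post_init__(self) -> None:
        if self.bixel_width <= 0 or self.sigma_p <= 0:
            raise ValueError("bixel_width and sigma_p must be positive")
        if any(not (0.0 <= a < 360.0) for a in self.gantry_angles):
            raise ValueError("gantry angles must lie in [0, 360)")
        object.__setattr__(self, "gantry_angles", tuple(float(a) for a in self.gantry_angles))


@dataclass
class DoseInfluence:
    """Sparse mapping from beamlet weights to voxel doses, d = D @ w."""

    matrix: sparse.csr_matrix
    beamlet_index: list[dict] = field(default_factory=list)
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    def dose(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_beamlets,):
            raise ValueError(f"expected {self.n_beamlets} weights, got {w.shape}")
        return self.matrix @ w


def _body_depth(points: np.ndarray, inside, direction: np.ndarray,
                step: float, n_steps: int) -> np.ndarray:
    """Path length (mm) inside the body upstream of each point, by marching
    against the propagation direction in uniform steps."""
    depth = np.zeros(len(points))
    for m in range(1, n_steps + 1):
        depth += step * inside(points - (m * step) * direction)
    return depth


def compute_dij(
    structures: StructureSet,
    beams: BeamSetup,
    truncation: float = 1e-4,
) -> DoseInfluence:
    """Build the dose-influence matrix for ``beams`` on a phantom.

    Bixels tile the lateral extent of the body for every beam, anchored at
    the grid center so the layout is independent of the body mask's exact
    bounding box.  Entries below ``truncation`` times the per-beamlet
    maximum are dropped (sparsity approximation, not a model change).
    Beamlets that deposit nothing inside the body are kept as zero columns,
    flagged ``missed_body`` in the beamlet index, with a warning.
    """
    grid = structures.grid
    body = structures.body.mask
    pos = grid.voxel_centers()
    body_flat = body.ravel()
    body_idx = np.flatnonzero(body_flat)
    pts = pos[body_idx]

    # nearest-voxel body lookup for the depth march
    lo = np.array(grid.origin) - 0.5 * np.array(grid.spacing)
    sp = np.array(grid.spacing)
    shp = np.array(grid.shape)

    def inside(p: np.ndarray) -> np.ndarray:
        ijk = np.floor((p - lo) / sp).astype(int)
        ok = np.all((ijk >= 0) & (ijk < shp), axis=1)
        out = np.zeros(len(p), dtype=bool)
        if ok.any():
            q = ijk[ok]
            out[ok] = body[q[:, 0], q[:, 1], q[:, 2]]
        return out

    step = 0.5 * min(grid.spacing)
    n_steps = int(np.ceil(grid.diameter() / step))
    center = np.array(grid.origin) + 0.5 * sp * (shp - 1)

    b = beams.bixel_width
    cutoff = b / 2 + 6.0 * beams.sigma_p  # lateral reach worth evaluating

    cols: list[sparse.csc_matrix] = []
    beamlet_index: list[dict] = []
    for beam_no, ang in enumerate(beams.gantry_angles):
        th = np.deg2rad(ang)
        u = np.array([np.sin(th), -np.cos(th), 0.0])  # propagation
        v = np.array([np.cos(th), np.sin(th), 0.0])  # lateral
        depth = _body_depth(pts, inside, u, step, n_steps)
        att = beams.dose_scale * np.exp(-beams.attenuation_mu * depth)

        t = (pts - center) @ v
        k_lo = int(np.floor((t.min() - b / 2) / b))
        k_hi = int(np.ceil((t.max() + b / 2) / b))
        for k in range(k_lo, k_hi + 1):
            delta = t - k * b
            near = np.abs(delta) <= cutoff
            vals = np.zeros(len(pts))
            vals[near] = att[near] * slit_profile(delta[near], b, beams.sigma_p)
            vmax = vals.max(initial=0.0)
            if vmax > 0:
                vals[vals < truncation * vmax] = 0.0
            nz = np.flatnonzero(vals)
            col = sparse.csc_matrix(
                (vals[nz], (body_idx[nz], np.zeros(len(nz), dtype=int))),
                shape=(grid.n_voxels, 1),
            )
            missed = len(nz) == 0
            if missed:
                warnings.warn(
                    f"beamlet (beam {beam_no}, bixel {k}) misses the body; "
                    "zero column retained",
                    stacklevel=2,
                )
            cols.append(col)
            beamlet_index.append(
                {
                    "beam": beam_no,
                    "gantry_deg": float(ang),
                    "bixel": k,
                    "lateral_mm": float(k * b),
                    "missed_body": missed,
                }
            )

    matrix = sparse.hstack(cols, format="csr")
    return DoseInfluence(matrix=matrix, beamlet_index=beamlet_index, grid_shape=grid.shape)
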