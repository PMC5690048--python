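"""Voxel grids and segmented structure sets.

All geometry lives on a regular 3D voxel lattice; planar (2D) and linear
(1D) cases are represented with singleton trailing axes so that every
downstream algorithm has a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "Structure", "StructureSet", "GeometryError"]


class GeometryError(ValueError):
    """Raised when structure geometry is inconsistent (e.g. target outside body)."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z); trailing axes may be 1.
    spacing : tuple of float
        Voxel size in mm along each axis; must be positive.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def is_isotropic(self) -> bool:
        sx, sy, sz = self.spacing
        active = [s for s, n in zip(self.spacing, self.shape) if n > 1] or [sx]
        return max(active) - min(active) < 1e-9 * max(active)

    def voxel_centers(self) -> np.ndarray:
        """Physical (mm) coordinates of all voxel centers, shape (n_voxels, 3)."""
        axes = [
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def diameter(self) -> float:
        """Length (mm) of the grid's space diagonal — an upper bound on any
        in-grid distance."""
        ext = [self.spacing[k] * self.shape[k] for k in range(3)]
        return float(np.sqrt(sum(e * e for e in ext)))


@dataclass
class Structure:
    """A segmented volume of interest (VOI).

    ``dpres`` is the prescribed dose in Gy and is required for (and only
    for) targets, where it anchors the penumbra model and prescription
    grouping.  ``adapt`` marks whether voxel-wise penalty adaptation is
    allowed inside this structure.
    """

    name: str
    mask: np.ndarray
    role: str  # "target" | "oar" | "body"
    dpres: float | None = None
    adapt: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.role not in ("target", "oar", "body"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "target":
            if self.dpres is None or self.dpres <= 0:
                raise ValueError(f"target {self.name!r} needs dpres > 0")
        elif self.dpres is not None:
            raise ValueError(f"non-target {self.name!r} must not carry a prescription")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class StructureSet:
    """An ordered collection of structures on a common grid.

    Exactly one structure has role ``body``; every other mask must be a
    subset of the body.  Targets are grouped by their prescribed dose for
    distance-transform bookkeeping: each prescription level owns the union
    of its targets.
    """

    grid: VoxelGrid
    structures: list[Structure] = field(default_factory=list)

    def __post_init__(self) -> None:
        bodies = [s for s in self.structures if s.role == "body"]
        if len(bodies) != 1:
            raise GeometryError(f"need exactly one body structure, got {len(bodies)}")
        if not self.targets:
            raise GeometryError("structure set has no target")
        body = bodies[0].mask
        for s in self.structures:
            if s.mask.shape != self.grid.shape:
                raise GeometryError(
                    f"mask shape {s.mask.shape} of {s.name!r} != grid {self.grid.shape}"
                )
            if s.role != "body" and np.any(s.mask & ~body):
                raise GeometryError(f"structure {s.name!r} extends outside the body")
        # overlapping targets with *different* prescriptions make the
        # per-group distance selection ill-defined; same-dose overlap
        # (CTV inside PTV) is fine.
        tg = self.targets
        for i, a in enumerate(tg):
            for b in tg[i + 1:]:
                if a.dpres != b.dpres and np.any(a.mask & b.mask):
                    raise GeometryError(
                        f"targets {a.name!r} and {b.name!r} overlap but have "
                        f"different prescriptions ({a.dpres} vs {b.dpres} Gy)"
                    )

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.structures)

    @property
    def body(self) -> Structure:
        return next(s for s in self.structures if s.role == "body")

    @property
    def targets(self) -> list[Structure]:
        return [s for s in self.structures if s.role == "target"]

    @property
    def oars(self) -> list[Structure]:
        return [s for s in self.structures if s.role == "oar"]

    @property
    def prescription_groups(self) -> dict[float, list[str]]:
        """Targets grouped by prescribed dose, keyed by dpres in Gy."""
        groups: dict[float, list[str]] = {}
        for t in self.targets:
            groups.setdefault(float(t.dpres), []).append(t.name)
        return dict(sorted(groups.items()))

    def group_mask(self, dpres: float) -> np.ndarray:
        """Union mask of all targets sharing prescription ``dpres``."""
        names = self.prescription_groups[float(dpres)]
        out = np.zeros(self.grid.shape, dtype=bool)
        for n in names:
            out |= self[n].mask
        return out

    def adaptation_region(self) -> np.ndarray:
        """Normal tissue where penalties may be adapted: body minus all
        targets and OARs (overridable per structure via ``adapt``)."""
        region = self.body.mask.copy()
        for s in self.structures:
            if s.role in ("target", "oar") and not s.adapt:
                region &= ~s.mask
        return region
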