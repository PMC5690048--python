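"""Synthetic planning phantoms.

The phantoms are deliberately simple geometries that nevertheless produce
the planning situations voxel-wise penalty adaptation is meant to handle:
hot-spots in the normal tissue where beams overlap, penumbra trade-offs at
target borders, and multiple prescription levels.  2D phantoms are 3D
grids with nz = 1; the 1D penumbra demonstration uses ny = nz = 1.
"""

from __future__ import annotations

import numpy as np

from .grid import GeometryError, Structure, StructureSet, VoxelGrid

__all__ = [
    "make_phantom_2d",
    "make_phantom_two_targets",
    "make_1d_penumbra_case",
    "FIG1_CONSTRAINTS",
]


def _ellipse(
    grid: VoxelGrid,
    center_mm: tuple[float, float],
    semi_axes_mm: tuple[float, float],
) -> np.ndarray:
    pos = grid.voxel_centers().reshape(*grid.shape, 3)
    dx = (pos[..., 0] - center_mm[0]) / semi_axes_mm[0]
    dy = (pos[..., 1] - center_mm[1]) / semi_axes_mm[1]
    return dx * dx + dy * dy <= 1.0


def _disc(grid: VoxelGrid, center_mm: tuple[float, float], radius_mm: float) -> np.ndarray:
    return _ellipse(grid, center_mm, (radius_mm, radius_mm))


def make_phantom_2d(
    size: int = 128,
    spacing_mm: float = 2.5,
    body_radius_mm: float | None = None,
    target_radius_mm: float | tuple[float, float] = (28.0, 12.0),
    target_dpres: float = 70.0,
    inner_target_radius_mm: float | tuple[float, float] | None = (22.0, 8.0),
    target_offset_mm: tuple[float, float] = (0.0, -8.0),
    oar_spec: list[dict] | None = None,
    seed: int = 0,
) -> StructureSet:
    """Prostate-like 2D phantom: a body disc containing an elliptical (or
    circular) PTV, optionally with a concentric inner CTV at the same
    prescription, and adjacent OAR discs.

    The default target is elongated (semi-axes 28 x 12 mm): beams looking
    along its short axis project wide fluence corridors whose overlaps
    create high-dose regions in the normal tissue well away from the
    target — the hot-spot situation penalty adaptation is meant to clean
    up — while the penumbra at the long flanks exercises the coverage
    trade-off.  ``target_radius_mm`` accepts a scalar (circle) or a
    semi-axes pair.

    ``oar_spec`` entries are dicts with keys ``name``, ``angle_deg``
    (direction from the target center), ``gap_mm`` (edge-to-edge distance
    to the target along that direction; 0 means abutting) and
    ``radius_mm``.  The ``seed`` jitters OAR placement angles by up to
    ±3° so distinct seeds give distinct (but topologically identical)
    cases; geometry is otherwise deterministic.
    """
    grid = VoxelGrid((size, size, 1), (spacing_mm, spacing_mm, spacing_mm))
    extent = size * spacing_mm
    if body_radius_mm is None:
        body_radius_mm = 0.45 * extent
    center = (extent / 2.0, extent / 2.0)
    tcen = (center[0] + target_offset_mm[0], center[1] + target_offset_mm[1])
    axes = (
        (float(target_radius_mm), float(target_radius_mm))
        if np.isscalar(target_radius_mm)
        else tuple(target_radius_mm)
    )

    # the target must clear the body edge by two release margins so the
    # suppression band never runs off the phantom
    clearance = 24.0
    margin = np.hypot(*target_offset_mm) + max(axes)
    if margin + clearance > body_radius_mm:
        raise GeometryError(
            f"target (semi-axes {axes} mm at offset {target_offset_mm}) "
            f"does not fit inside body radius {body_radius_mm} mm with "
            f"{clearance} mm clearance"
        )

    body = _disc(grid, center, body_radius_mm)
    ptv = _ellipse(grid, tcen, axes)
    structures = [
        Structure("body", body, "body"),
        Structure("ptv", ptv, "target", dpres=target_dpres),
    ]
    if inner_target_radius_mm is not None:
        in_axes = (
            (float(inner_target_radius_mm), float(inner_target_radius_mm))
            if np.isscalar(inner_target_radius_mm)
            else tuple(inner_target_radius_mm)
        )
        ctv = _ellipse(grid, tcen, in_axes)
        structures.insert(1, Structure("ctv", ctv, "target", dpres=target_dpres))

    rng = np.random.default_rng(seed)
    taken = ptv.copy()
    for spec in oar_spec or []:
        ang = np.deg2rad(spec["angle_deg"] + rng.uniform(-3.0, 3.0))
        r_oar = spec["radius_mm"]
        # edge-to-edge placement along the chosen direction
        ca, sa = np.cos(ang), np.sin(ang)
        t_edge = 1.0 / np.sqrt((ca / axes[0]) ** 2 + (sa / axes[1]) ** 2)
        dist = t_edge + spec["gap_mm"] + r_oar
        ocen = (tcen[0] + dist * ca, tcen[1] + dist * sa)
        oar = _disc(grid, ocen, r_oar) & body & ~taken
        structures.append(Structure(spec["name"], oar, "oar"))
        taken |= oar
    return StructureSet(grid, structures)


def make_prostate_case(seed: int = 0, size: int = 128) -> StructureSet:
    """The default prostate-like study phantom: elongated PTV + concentric
    CTV with rectum-like (posterior, near-abutting) and bladder-like
    (anterior) OARs."""
    return make_phantom_2d(
        size=size,
        oar_spec=[
            {"name": "rectum", "angle_deg": 270, "gap_mm": 2.0, "radius_mm": 9.0},
            {"name": "bladder", "angle_deg": 90, "gap_mm": 4.0, "radius_mm": 13.0},
        ],
        seed=seed,
    )


def make_phantom_two_targets(
    dpres_a: float = 70.0,
    dpres_b: float = 46.0,
    size: int = 64,
    spacing_mm: float = 2.5,
    target_radius_mm: float = 10.0,
    separation_mm: float = 50.0,
    oar_spec: list[dict] | None = None,
    seed: int = 0,
) -> StructureSet:
    """Head-and-neck-like phantom with two laterally separated targets.

    Distinct prescriptions yield two prescription groups (the situation
    that exercises per-group distance selection); equal prescriptions
    collapse into one group holding both targets.
    """
    grid = VoxelGrid((size, size, 1), (spacing_mm, spacing_mm, spacing_mm))
    extent = size * spacing_mm
    center = (extent / 2.0, extent / 2.0)
    body = _disc(grid, center, 0.45 * extent)
    half = separation_mm / 2.0
    if half + target_radius_mm + 2 * spacing_mm > 0.45 * extent:
        raise GeometryError("targets do not fit inside the body")
    cen_a = (center[0] - half, center[1])
    cen_b = (center[0] + half, center[1])
    mask_a = _disc(grid, cen_a, target_radius_mm)
    mask_b = _disc(grid, cen_b, target_radius_mm)
    suffix_a = f"{dpres_a:g}".replace(".", "p")
    suffix_b = f"{dpres_b:g}".replace(".", "p")
    if suffix_a == suffix_b:
        suffix_a, suffix_b = suffix_a + "a", suffix_b + "b"
    structures = [
        Structure("body", body, "body"),
        Structure(f"ptv{suffix_a}", mask_a, "target", dpres=dpres_a),
        Structure(f"ptv{suffix_b}", mask_b, "target", dpres=dpres_b),
    ]
    rng = np.random.default_rng(seed)
    for spec in oar_spec or []:
        ang = np.deg2rad(spec["angle_deg"] + rng.uniform(-3.0, 3.0))
        dist = spec.get("dist_mm", 0.3 * extent)
        ocen = (center[0] + dist * np.cos(ang), center[1] + dist * np.sin(ang))
        oar = _disc(grid, ocen, spec["radius_mm"]) & body & ~mask_a & ~mask_b
        structures.append(Structure(spec["name"], oar, "oar"))
    return StructureSet(grid, structures)


#: Fixture constraint set for the 1D penumbra demonstration: a flat unit
#: prescription in the target against a weakly penalized zero-dose wish in
#: the normal tissue (pmax = 1 vs pmin = 500).
FIG1_CONSTRAINTS = {
    "target": {"d_min": 1.0, "p_min": 500.0},
    "body": {"d_max": 0.0, "p_max": 1.0},
}


def make_1d_penumbra_case(
    n: int = 160,
    spacing_mm: float = 1.0,
    target_len_mm: float = 40.0,
) -> tuple[StructureSet, dict]:
    """1D inverse-planning demonstration of the penumbra/coverage trade-off.

    A central target interval (length well above 4·sigma_p so both penumbra
    flanks are resolvable) inside a 1D body, together with the fixture
    constraint set (normal-tissue p_max = 1, target p_min = 500).
    Returns ``(structures, constraints)``.
    """
    grid = VoxelGrid((n, 1, 1), (spacing_mm, spacing_mm, spacing_mm))
    body = np.ones(grid.shape, dtype=bool)
    x = grid.voxel_centers().reshape(*grid.shape, 3)[..., 0]
    mid = (n - 1) * spacing_mm / 2.0
    target = np.abs(x - mid) <= target_len_mm / 2.0
    structures = StructureSet(
        grid,
        [
            Structure("body", body, "body"),
            Structure("target", target, "target", dpres=1.0),
        ],
    )
    return structures, {k: dict(v) for k, v in FIG1_CONSTRAINTS.items()}
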