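"""Artifact I/O: structures as NIfTI + JSON sidecar, dose-influence
matrices as Matrix Market + JSON sidecar, configs as YAML, reports as
JSON/CSV.

Structures are stored in a single integer volume using one bit per
structure, so overlapping VOIs (a CTV inside its PTV) survive the round
trip; the sidecar maps bits to names, roles and prescriptions.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy import io as scio
from scipy import sparse

from .dose import DoseInfluence
from .grid import Structure, StructureSet, VoxelGrid

__all__ = [
    "write_structures",
    "read_structures",
    "write_dij",
    "read_dij",
    "write_volume",
    "write_report",
    "write_dvh_csv",
    "load_config",
    "save_config",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def write_volume(path, data: np.ndarray, grid: VoxelGrid) -> None:
    """Write a scalar voxel cube (dose, penalty scale, distance) as NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(grid))
    nib.save(img, str(path))


def write_structures(prefix, structures: StructureSet) -> tuple[Path, Path]:
    """Write a structure set as ``<prefix>.nii.gz`` (bit-packed labels)
    plus ``<prefix>.json`` (bit -> name/role/dpres/adapt and the grid)."""
    prefix = Path(prefix)
    if len(structures.structures) > 32:
        raise ValueError("bit-packed label volume supports at most 32 structures")
    labels = np.zeros(structures.grid.shape, dtype=np.uint32)
    entries = []
    for bit, s in enumerate(structures.structures):
        labels |= s.mask.astype(np.uint32) << bit
        entries.append(
            {"bit": bit, "name": s.name, "role": s.role, "dpres": s.dpres, "adapt": s.adapt}
        )
    nii = prefix.with_suffix(".nii.gz")
    img = nib.Nifti1Image(labels, _affine(structures.grid))
    nib.save(img, str(nii))
    sidecar = prefix.with_suffix(".json")
    meta = {
        "grid": {
            "shape": list(structures.grid.shape),
            "spacing": list(structures.grid.spacing),
            "origin": list(structures.grid.origin),
        },
        "structures": entries,
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return nii, sidecar


def read_structures(prefix) -> StructureSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    img = nib.load(str(prefix.with_suffix(".nii.gz")))
    labels = np.asarray(img.dataobj).astype(np.uint32)
    g = meta["grid"]
    grid = VoxelGrid(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
    if labels.shape != grid.shape:
        raise ValueError(
            f"label volume shape {labels.shape} does not match sidecar grid {grid.shape}"
        )
    structures = [
        Structure(
            e["name"],
            (labels >> e["bit"]) & 1 > 0,
            e["role"],
            dpres=e["dpres"],
            adapt=e["adapt"],
        )
        for e in meta["structures"]
    ]
    return StructureSet(grid, structures)


def write_dij(prefix, dij: DoseInfluence) -> tuple[Path, Path]:
    """Write a dose-influence matrix as ``<prefix>.mtx`` plus a JSON
    sidecar with the beamlet index and grid shape."""
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx")
    scio.mmwrite(str(mtx), sparse.coo_matrix(dij.matrix), precision=17)
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"grid_shape": list(dij.grid_shape or ()), "beamlet_index": dij.beamlet_index},
            indent=2,
            sort_keys=True,
        )
    )
    return mtx, sidecar


def read_dij(prefix) -> DoseInfluence:
    prefix = Path(prefix)
    matrix = sparse.csr_matrix(scio.mmread(str(prefix.with_suffix(".mtx"))))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    shape = tuple(meta.get("grid_shape") or ()) or None
    return DoseInfluence(matrix=matrix, beamlet_index=meta["beamlet_index"], grid_shape=shape)


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def write_dvh_csv(path, curves: dict[str, tuple[np.ndarray, np.ndarray]]) -> None:
    """Write DVH curves as CSV: first column dose (Gy), one column of
    volume-% per VOI, resampled onto a common threshold axis."""
    names = sorted(curves)
    top = max(float(t[-1]) for t, _ in curves.values())
    step = min(float(t[1] - t[0]) for t, _ in curves.values())
    axis = np.arange(0.0, top + step, step)
    cols = []
    for n in names:
        t, v = curves[n]
        vv = np.interp(axis, t, v, left=100.0, right=0.0)
        cols.append(vv)
    with open(path, "w") as fh:
        fh.write("dose_gy," + ",".join(names) + "\n")
        for i, x in enumerate(axis):
            fh.write(f"{x:.6g}," + ",".join(f"{c[i]:.6g}" for c in cols) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
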