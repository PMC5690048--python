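"""Plan-quality metrics: DVHs, coverage, conformity, dose-volume points,
and the convergence measure of successive penalty-scale distributions.

Conformity is reported as the conformation number (van't Riet):
CN = (V_T,95 / V_T) * (V_T,95 / V_95) — the product of target coverage and
the selectivity of the 95% isodose.  The alternative literal product
CO * V_95 / V_T is available behind a flag for comparison; it is not a
number in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlanReport",
    "dvh",
    "coverage",
    "conformity",
    "dose_volume_point",
    "dose_stats",
    "penalty_msd",
]


def _require_mask(mask: np.ndarray, what: str = "mask") -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"{what} is empty")
    return mask


def dvh(dose: np.ndarray, mask: np.ndarray, bin_width: float = 0.1):
    """Cumulative dose-volume histogram.

    Returns ``(thresholds_gy, volume_pct)`` where ``volume_pct[k]`` is the
    percentage of masked voxels with dose >= ``thresholds_gy[k]``;
    thresholds run from 0 to just past the maximum dose in steps of
    ``bin_width``.  The curve starts at 100% and is non-increasing.
    """
    mask = _require_mask(mask)
    d = np.asarray(dose, dtype=float)[mask]
    top = max(float(d.max()), 0.0) + bin_width
    thresholds = np.arange(0.0, top + bin_width, bin_width)
    volume = (d[None, :] >= thresholds[:, None]).mean(axis=1) * 100.0
    return thresholds, volume


def coverage(dose: np.ndarray, target_mask: np.ndarray, dpres: float) -> float:
    """Target coverage CO in %: fraction of target voxels receiving at
    least 95% of the prescription (voxels exactly at the threshold count
    as covered)."""
    mask = _require_mask(target_mask, "target mask")
    d = np.asarray(dose, dtype=float)[mask]
    return float((d >= 0.95 * dpres).mean() * 100.0)


def conformity(
    dose: np.ndarray,
    target_mask: np.ndarray,
    dpres: float,
    eval_region: np.ndarray | None = None,
    literal: bool = False,
) -> float:
    """Conformation number CN = (V_T,95/V_T) * (V_T,95/V_95) in [0, 1].

    ``eval_region`` restricts where the 95% isodose volume V_95 is counted
    (defaults to the whole grid).  With ``literal=True`` the unnormalized
    product (V_T,95/V_T) * (V_95/V_T) is returned instead.
    """
    mask = _require_mask(target_mask, "target mask")
    d = np.asarray(dose, dtype=float)
    region = np.ones_like(mask) if eval_region is None else np.asarray(eval_region, bool)
    hot = (d >= 0.95 * dpres) & region
    v95 = int(hot.sum())
    vt = int(mask.sum())
    vt95 = int((hot & mask).sum())
    if literal:
        return (vt95 / vt) * (v95 / vt)
    if v95 == 0:
        warnings.warn("95% isodose volume is empty; conformity defined as 0", stacklevel=2)
        return 0.0
    return (vt95 / vt) * (vt95 / v95)


def dose_volume_point(dose: np.ndarray, mask: np.ndarray, x_gy: float) -> float:
    """VxGy: percentage of the masked volume receiving at least ``x_gy``."""
    mask = _require_mask(mask)
    d = np.asarray(dose, dtype=float)[mask]
    return float((d >= x_gy).mean() * 100.0)


def dose_stats(dose: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """(Dmean, Dmax) in Gy over the masked voxels."""
    mask = _require_mask(mask)
    d = np.asarray(dose, dtype=float)[mask]
    return float(d.mean()), float(d.max())


def penalty_msd(phi_a: np.ndarray, phi_b: np.ndarray, region_mask: np.ndarray) -> float:
    """Mean squared deviation between two penalty-scale distributions over
    a region — the stability measure of successive adaptation runs."""
    region = _require_mask(region_mask, "region mask")
    a = np.asarray(phi_a, dtype=float)
    b = np.asarray(phi_b, dtype=float)
    if a.shape != b.shape or a.shape != region.shape:
        raise ValueError("shape mismatch between penalty cubes and region")
    diff = a[region] - b[region]
    return float(np.mean(diff * diff))


@dataclass
class PlanReport:
    """Aggregated evaluation of one adaptive planning sequence."""

    dvhs: dict[str, dict] = field(default_factory=dict)  # run label -> VOI -> curve
    metrics: list[dict] = field(default_factory=list)  # one entry per run
    msd_sequence: list[float] = field(default_factory=list)
    hotspot_counts: list[int] = field(default_factory=list)
    # in-memory only (not serialized): penalty cube per adaptation run
    phi_cubes: list[np.ndarray] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "msd_sequence": self.msd_sequence,
            "hotspot_counts": self.hotspot_counts,
            "dvhs": self.dvhs,
        }


def evaluate_run(dose: np.ndarray, structures) -> dict:
    """Per-VOI metric block for one dose distribution: CO/CN for targets,
    Dmean/Dmax for every structure, standard VxGy points for OARs."""
    out: dict[str, dict] = {}
    for s in structures.structures:
        d_mean, d_max = dose_stats(dose, s.mask)
        block: dict = {"Dmean": round(d_mean, 6), "Dmax": round(d_max, 6)}
        if s.role == "target":
            block["CO"] = round(coverage(dose, s.mask, s.dpres), 6)
            block["CI"] = round(conformity(dose, s.mask, s.dpres), 6)
        elif s.role == "oar":
            for x in (10.0, 20.0, 30.0, 40.0, 50.0):
                block[f"V{x:g}Gy"] = round(dose_volume_point(dose, s.mask, x), 6)
        out[s.name] = block
    return out
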