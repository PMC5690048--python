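"""End-to-end adaptive planning sequence.

One case runs as: conventional optimization with phi = 1, then ``n_runs``
cycles of (penalty adaptation from the latest dose -> reoptimization of
the modified objective, warm-started from the previous weights).  The
target-border distance maps are computed once — geometry does not change
between runs.  Per run the pipeline records plan metrics, the hot-spot
count (normal-tissue voxels above the threshold dose d_T) and the mean
squared deviation between successive penalty-scale cubes (run 1 compares
against the all-ones initialization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .adaptation import AdaptationParams, compute_penalty_scale
from .distance import group_distance_maps
from .dose import BeamSetup, DoseInfluence, compute_dij
from .evaluation import PlanReport, dvh, evaluate_run, penalty_msd
from .fluence import ConstraintSet, FluencePlan, optimize
from .grid import StructureSet
from .phantoms import make_1d_penumbra_case, make_phantom_two_targets, make_prostate_case

__all__ = ["RunConfig", "run_adaptive_plan", "build_case"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one planning sequence."""

    constraints: ConstraintSet
    params: AdaptationParams = field(default_factory=AdaptationParams)
    optimizer_options: dict = field(default_factory=dict)
    output_dir: Path | None = None
    seed: int = 0
    dvh_bin_width: float = 0.5

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        params = AdaptationParams(**cfg.get("adaptation", {}))
        out = cfg.get("output_dir")
        return cls(
            constraints=ConstraintSet.from_dict(cfg["constraints"]),
            params=params,
            optimizer_options=dict(cfg.get("optimizer", {})),
            output_dir=Path(out) if out else None,
            seed=int(cfg.get("seed", 0)),
            dvh_bin_width=float(cfg.get("dvh_bin_width", 0.5)),
        )


def build_case(kind: str, seed: int = 0, **kwargs):
    """Construct a named phantom; returns ``(structures, extra)`` where
    ``extra`` holds fixture constraints for cases that ship them."""
    if kind == "prostate2d":
        return make_prostate_case(seed=seed, **kwargs), None
    if kind == "two-targets":
        return make_phantom_two_targets(seed=seed, **kwargs), None
    if kind == "penumbra1d":
        structures, constraints = make_1d_penumbra_case(**kwargs)
        return structures, constraints
    raise ValueError(f"unknown phantom kind {kind!r}")


def _validate(config: RunConfig, structures: StructureSet) -> None:
    config.constraints.validate(structures)
    body = structures.body.name
    if body not in config.constraints:
        raise ValueError(f"adapted VOI {body!r} has no constraint entry")
    d_max = config.constraints[body].d_max
    if d_max is None or config.params.d_T <= d_max:
        raise ValueError(
            f"infeasible configuration: threshold d_T={config.params.d_T} Gy "
            f"must exceed the adapted VOI's d_max ({d_max} Gy)"
        )


def run_adaptive_plan(
    structures: StructureSet,
    dij: DoseInfluence,
    config: RunConfig,
) -> tuple[PlanReport, list[FluencePlan]]:
    """Run the full sequence and return the report plus per-run plans.

    With ``n_runs = 0`` only the conventional plan is produced and the MSD
    sequence is empty.  Deterministic: the same inputs produce the same
    report, byte for byte once serialized.
    """
    _validate(config, structures)
    grid = structures.grid
    params = config.params
    region = structures.adaptation_region()

    plans: list[FluencePlan] = []
    report = PlanReport()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def record(run_label: str, dose_cube: np.ndarray) -> None:
        report.metrics.append({"run": run_label, "voi": evaluate_run(dose_cube, structures)})
        report.hotspot_counts.append(int((dose_cube[region] > params.d_T).sum()))
        curves = {
            s.name: dvh(dose_cube, s.mask, config.dvh_bin_width)
            for s in structures.structures
        }
        report.dvhs[run_label] = {
            n: {"dose_gy": t.tolist(), "volume_pct": v.tolist()} for n, (t, v) in curves.items()
        }
        if outdir:
            vio.write_volume(outdir / f"dose_{run_label}.nii.gz", dose_cube, grid)
            vio.write_dvh_csv(outdir / f"dvh_{run_label}.csv", curves)

    # conventional plan, phi = 1
    plan = optimize(None, dij, structures, config.constraints,
                    phi=None, options=config.optimizer_options)
    plan.provenance = "initial " + plan.provenance
    plans.append(plan)
    dose_cube = dij.dose(plan.w).reshape(grid.shape)
    record("run0", dose_cube)

    if params.n_runs > 0:
        distance_maps = group_distance_maps(structures)
        phi_prev = np.ones(grid.shape)
        for k in range(1, params.n_runs + 1):
            phi = compute_penalty_scale(
                dose_cube, structures, distance_maps, params, config.constraints,
                region=region,
            )
            report.msd_sequence.append(penalty_msd(phi, phi_prev, region))
            report.phi_cubes.append(phi)
            plan = optimize(plans[-1].w, dij, structures, config.constraints,
                            phi=phi, options=config.optimizer_options)
            plan.provenance = f"adaptation run {k} ({params.mode}) " + plan.provenance
            plans.append(plan)
            dose_cube = dij.dose(plan.w).reshape(grid.shape)
            record(f"run{k}", dose_cube)
            if outdir:
                vio.write_volume(outdir / f"phi_run{k}.nii.gz", phi, grid)
            phi_prev = phi

    if outdir:
        vio.write_report(outdir / "report.json", report.to_dict())
    return report, plans


def plan_case(
    kind: str,
    config: RunConfig,
    beams: BeamSetup | None = None,
    **phantom_kwargs,
) -> tuple[PlanReport, list[FluencePlan]]:
    """Convenience wrapper: phantom -> dose engine -> adaptive planning."""
    structures, _ = build_case(kind, seed=config.seed, **phantom_kwargs)
    dij = compute_dij(structures, beams or BeamSetup())
    return run_adaptive_plan(structures, dij, config)
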