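# Methods

## Model and planning sequence

The optimization problem is the standard penalized quadratic formulation
of IMRT inverse planning. For each constrained VOI `V` with reference
doses `d_V^max`, `d_V^min` (Gy) and penalties `p_V^max`, `p_V^min`
(unitless, ≥ 0), the objective over non-negative beamlet weights `w` is

    F(w) = Σ_V (1/n_V) [ p_V^max Σ_{i∈V} {d_i − d_V^max}₊²
                       + p_V^min Σ_{i∈V} {d_V^min − d_i}₊² ],    d = D w.

`{x}₊` contributes nothing (value or gradient) at `x = 0` exactly; a
voxel belonging to several VOIs contributes to each VOI's sum
independently (the literal formula; a CTV inside its PTV is counted in
both). `d_min = d_max` is a legitimate strict prescription. VOIs with
zero voxels are rejected (the `1/n_V` normalization would be undefined).

The adaptive sequence is:

1. optimize `F` with unit penalty scale → initial plan `w₀*`, dose `d₀`;
2. for `k = 1 … n_runs`: compute the per-voxel penalty scale `φ_k` from
   `d_{k−1}`, reoptimize the modified objective `F̃` (same form with
   `φ_i` inside the sums), warm-starting from `w_{k−1}*`.

`φ` is recomputed from the latest dose each run (non-accumulating), so
the mean squared deviation (MSD) between successive `φ` cubes measures
stabilization of the adaptation; run 1 is compared against the all-ones
initialization. Warm starts make the reoptimizations cheap and the
run-to-run MSD meaningful. Target-border distance maps are computed once
per case, since geometry does not change between runs.

## Penalty adaptation

Naive scale, for a normal-tissue voxel with dose `d` inside the adapted
VOI (whose overdose constraint is `d^max`):

    φ_O(d) = [ {d − d^max}₊² / (d_T − d^max)² ]^α.

`d_T` (Gy) is the dose above which normal tissue counts as undesirably
overdosed; it must exceed `d^max` so the normalizer is positive.
`φ_O(d_T) = 1` by construction. The literal formula maps doses below
`d_T` to values below 1, which would *weaken* the baseline penalties; by
default `φ_O` is clamped to ≥ 1 (adaptation only ever raises penalties),
with the unclamped form behind a flag (`clamp_low=False`) for
comparison. Defaults: `α = 1`, `d_T = 35 Gy`, matching the values found
adequate for prostate-level prescriptions; both are exposed.

Penumbra model and suppression. The lateral falloff of a photon beam at
a target border is modelled as

    d_P(δ) = ½ d_pres erfc( δ/(√2 σ_P) − c ),

with `σ_P = 3.2 mm` (constant with depth and field size here) and the
shift `c` fixed by the coverage condition `d_P(0) = 0.95 d_pres`, i.e.
`c = erf⁻¹(0.9) = 1.1630871537…` (we use the exact value; the rounded
1.16309 differs by ~10⁻⁵ mm in the resulting distances). Inverting the
profile gives the allowed penumbra distance

    δ_P(d) = √2 σ_P ( erfc⁻¹(2 d/d_pres) + c ),

clamped to 0 for `d` in the `[0.95, 1)·d_pres` band (where the inversion
would go negative) and capped at the grid diameter for vanishing doses
(where `erfc⁻¹` diverges; `φ_O = 1` there anyway, so the cap has no
behavioral effect). The suppression factor is

    S(d, δ) = 1                          δ ≤ δ_P(d)         (d < d_pres)
            = 1 − ((δ − δ_P)/Δδ)²        δ_P < δ < δ_P + Δδ
            = 0                          δ ≥ δ_P + Δδ
    S(d, δ) = {1 − (δ/Δδ)² e^{5(d/d_pres − 1)}}₊            (d ≥ d_pres)

The high-dose branch continues the quadratic falloff while exponentially
shortening the allowed region (the inversion is undefined there); the
two branches join continuously at `d = d_pres` and at the band edges.
`Δδ` (default 12 mm) is the release margin accounting for finite bixel
size and beam number; it is global (one value for all prescription
groups). Final scale: `φ_S = φ_O − (φ_O − 1) S ∈ [1, φ_O]`, with
`φ_S` continuous and non-decreasing in dose at fixed distance.

Multi-prescription cases: targets are grouped by prescribed dose; each
group gets its own border-distance map, and a voxel uses the group with
the smallest `δ − δ_P(d)` (most "inside" the allowed region). Exact ties
go to the lowest prescription — deterministic and documented; targets
overlapping with *different* prescriptions are rejected at construction
because this selection would be ill-defined for shared voxels.

The adaptation region defaults to body minus all targets minus all OARs;
per-structure `adapt` flags can override it. `φ = 1` everywhere else.

## Distance transform

Distances to target borders use a two-pass (forward/backward) Chamfer
relaxation with integer weights 3 (face), 4 (edge), 5 (corner) — the
best integer approximation to the Euclidean metric on an isotropic
lattice — divided by 3 and scaled by the voxel spacing, so a face step
costs exactly one spacing in mm. The border is the set of mask voxels
with a face neighbor outside the mask; singleton axes are ignored so
planar grids get an in-plane rim, and distances are measured between
voxel centers (computed on both sides of the border, unsigned; only
normal-tissue values are consumed). Worst-case deviation from the exact
Euclidean distance is ≈ 10% for this weight set; the test suite checks
≤ 13% against an exhaustive oracle. Anisotropic grids fall back to the
exact Euclidean transform (the integer weights are only calibrated for
isotropic lattices); the Chamfer path raises a pointer to it.

## Dose engine

The toy engine builds a sparse dose-influence matrix for parallel
coplanar beams: per beamlet,

    dose(voxel) = exp(−μ · depth) × ½[erf((δ + b/2)/(√2 σ_P)) − erf((δ − b/2)/(√2 σ_P))],

with `depth` the upstream path length inside the body (marched in steps
of half the minimum voxel spacing), `δ` the lateral offset from the
bixel axis, `b = 5 mm` the bixel width and `μ = 0.005 /mm`. Entries
below 10⁻⁴ of the per-beamlet maximum are dropped; tightening this
threshold changes reference doses by well under 0.5% (sparsity is an
approximation, not a model change). Deliberate simplifications: single
exponential depth dose (no buildup), `σ_P` constant with depth, parallel
(not divergent) geometry, no heterogeneity or magnetic-field effects.
The adaptation logic depends on the lateral penumbra, which this model
reproduces quantitatively; depth-dose realism is out of scope.

## Optimization

Bound-constrained L-BFGS-B (scipy) on `w ≥ 0` with the analytic
gradient. Defaults: max 500 iterations, projected-gradient tolerance
1e-7, ftol 1e-12, history size 20 — these reach visually converged
phantom plans in about a second and are exposed as optimizer options.
Initialization: uniform weights scaled so the mean target dose equals
the voxel-averaged prescription (deterministic, prescription-aware). The
objective trace over accepted iterations is recorded and non-increasing;
if the solver ever returned an ascent over the start point, the start
point would be kept (relevant only at pathological starts).

## Synthetic study conditions

No clinical dose-influence data ship with the package; the phantoms are
designed to reproduce the *situations* the algorithm targets, not any
patient geometry.

- **prostate2d** (default study case): 128² grid at 2.5 mm, body disc of
  radius 144 mm, elongated PTV (semi-axes 28 × 12 mm) with concentric
  CTV (22 × 8 mm) at the same 70 Gy prescription, rectum-like and
  bladder-like OAR discs; seven coplanar beams at the standard prostate
  angles. The elongated target makes beams that look along its short
  axis project wide fluence corridors; their overlaps produce
  normal-tissue voxels above `d_T` up to ~40 mm from the target border —
  genuine hot-spots outside the suppression reach — while the long
  flanks exercise the penumbra/coverage trade-off. The class-solution
  constraint set (`configs/prostate_class_solution.yaml`) uses the
  prostate-style values: CTV 78/78 Gy, PTV 70/70 Gy, bladder/rectum
  15 Gy max, body 25 Gy max with a strong penalty. The phantom's CTV
  carries `dpres = 70 Gy` (one prescription group with the PTV — the
  grouping requires overlapping targets to share a prescription) while
  the constraint set prescribes 78 Gy to it; prescription and reference
  doses are distinct concepts.
- **two-targets**: two separated discs at 70 and 46 Gy — two
  prescription groups, exercising the per-group distance selection
  (`configs/hn_class_solution.yaml`).
- **penumbra1d**: a 1D body with a central 40 mm target (> 4 σ_P, so
  both penumbra flanks are resolvable) and the demonstration constraint
  set p_max = 1 (normal tissue) vs p_min = 500 (target).

What passing tests do and do not show: on these phantoms the sequence
eradicates hot-spots in both modes, the physical mode loses at most a
fraction of a coverage point where the naive mode loses ~11, and the
penalty cube stabilizes within one or two runs (MSD drops > 30× from
run 1 to run 2). Absolute metric levels are *not* comparable to clinical
3D results: with a 2D desk-scale grid the `1/n_V` normalization weighs
the body contour orders of magnitude more heavily per voxel than at
clinical voxel counts (~10⁶–10⁷), so initial coverage sits near 78%
rather than the ~95% typical of clinical plans, and hot-spot populations
are smaller. The directional claims — suppression preserves coverage,
adaptation removes hot voxels, the scale distribution converges — are
exactly what the tests assert.

## Numerical choices and degenerate inputs

- Threshold comparisons in evaluation use ≥ (a voxel exactly at
  `0.95 d_pres` counts as covered); fixed and documented.
- Conformity is the van't Riet conformation number
  `CN = (V_T,95/V_T)·(V_T,95/V_95) ∈ [0, 1]`; the unnormalized literal
  product `CO·V_95/V_T` is available behind `literal=True`. An empty
  95% isodose yields CN = 0 with a warning.
- MSD is evaluated over the adaptation region (φ is 1 elsewhere by
  construction).
- Beamlets whose slit misses the body entirely are kept as zero columns,
  flagged, with a warning — column indexing stays aligned with the
  beam/bixel layout.
- Determinism: phantoms, dose engine, optimizer and pipeline are fully
  deterministic given the configuration (the phantom seed only jitters
  OAR placement); two runs of the same config produce byte-identical
  serialized reports.

## Known limitations

Parallel-beam toy dosimetry (no divergence, buildup, scatter,
heterogeneities); adaptation restricted to the normal tissue (no OAR- or
target-interior adaptation); no fluence-map sequencing into deliverable
apertures; no multicriteria or biological objectives; 2D study phantoms
(the code paths are 3D, but the shipped cases use nz = 1).
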