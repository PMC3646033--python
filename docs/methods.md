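# Methods

This note documents the models, numerical choices and limitations of
`retrack`: what the synthetic phantom emulates, how tracking and
re-seeding are parameterized, and what the evaluation does and does not
show about real clinical data.

## Diffusion model and tensor estimation

Each voxel carries a symmetric 3×3 diffusion tensor `D` (mm²/s), stored as
six coefficients in lower-triangular order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).
The single-shell signal model is Stejskal–Tanner,
`S_k = S0 · exp(−b g_kᵀ D g_k)`; at least six non-collinear directions
plus one b=0 volume determine the tensor. Estimation is ordinary least
squares on `log(S_k/S0)` — the simplest estimator consistent with clinical
practice; a one-pass weighted variant (weights = predicted signals) is
available behind `weighted=True`. Signals ≤ 0 are floored to a tiny
epsilon before the log. Negative fitted eigenvalues are clamped to zero
and the affected voxels flagged. On noiseless synthetic data the fit is
exact to machine precision (the suite asserts ≤ 1e−8 relative error).

FA is computed from tensor invariants (`tr D`, `tr D²`) rather than an
eigendecomposition, which makes the per-step cost of tracking low; a
relative cancellation guard returns exactly 0 for exactly isotropic
tensors. Continuous tensors for tracking come from component-wise
trilinear interpolation of the six coefficients — interpolating
coefficients rather than eigenvectors avoids sign-flip artifacts.

Coordinates everywhere: voxel indices are 0-based, voxels isotropic, and
world mm coordinates are voxel-center based (the grid origin is the world
position of the center of voxel (0,0,0)). Streamline points are world mm.

## TEND tracking

Tensor deflection bends the incoming direction with the full tensor:

    v_out ∝ f·e₁ + (1−f)·((1−g)·v_in + g·D̂·v_in),   D̂ = D/λ₁.

Defaults are f = 0, g = 1 (pure deflection `D·v_in`), for which the λ₁
normalization cancels under the final unit normalization and is skipped.
The output is sign-aligned with `v_in` (no backtracking). Integration is
fixed-step Euler (1 mm, i.e. half a voxel), bidirectional from every seed
with initial directions ±e₁; the two half-tracks are concatenated with the
seed appearing once. RK4 is available behind `integrator="rk4"` and agrees
with Euler on straight fields. Termination: interpolated FA < 0.15,
turning angle > 45° per step, leaving the voxel-center hull, or 600 steps
per half-track. All values are configurable (`TrackingParams`) and echoed
into every run's provenance JSON; the defaults are standard
clinical-practice settings.

Propagation is vectorized: all seeds of a region advance in lockstep,
with interpolation, deflection and the stopping tests computed for the
whole active batch per step. A full 33-region repeated run on the 64³
phantom takes a few seconds on one CPU.

## Centerline and seed-region generation

Streamlines of the initial bundle are orientation-aligned against the
longest streamline (flipped when their endpoints match the reference
better in reverse), resampled to n = 129 equally spaced arc-length points,
and averaged point-wise. n = 129 is chosen so that every evaluated seed
count {2, 3, 5, 9, 17, 33, 65, 129} (all 2^k + 1) is an exact equally
spaced subset of centerline indices, endpoints included.

At each selected index a plane perpendicular to the local centerline
direction (segment to the next point; previous segment at the last index;
nearest distinct neighbor if consecutive points coincide) is erected with
a deterministic in-plane basis (cross product with the coordinate axis of
smallest normal component). 36 rays at 10° spacing, sampled every 0.5 mm
up to 30 mm, find the first sample outside the rasterized initial tract
mask (nearest-voxel lookup); rays still inside at the cap are truncated
and flagged. A closed periodic cubic spline through the 36 polar boundary
points (128 samples) is the region contour; scaling moves every boundary
point outwards along its ray by the SCALING offset (mm) and refits the
spline. Seed points are a regular 1 mm in-plane grid (half the voxel size
— coverage vs. cost) clipped by point-in-polygon against the spline, plus
always the plane origin. A robustness detail: when point-wise averaging
under noise pushes an end-plane origin's nearest voxel just outside the
voxelized mask, the origin is nudged along the centerline toward the
interior by up to one voxel before erroring.

## Accumulation and FBM

Each region's tracking result (filtered with the original seed and
include ROIs as *alternative* includes, i.e. a streamline is kept when it
touches at least one of them — the alternative use captures fibers near
the borders that reach only one end) is rasterized to a binary mask:
segments super-sampled at ≤ voxel_size/4, every touched voxel set, each
region contributing at most 1 per voxel. The count mask is the element-wise
sum over the n regions (values 0..n); the initial two-ROI result does not
itself contribute to the count — n generated regions define the FBM
denominator. FBM thresholding keeps voxels with count ≥ ceil(fbm/100 · n),
so "90 % or more" includes ties; masks are nested as FBM rises.

## The synthetic phantom

The phantom emulates a segment of the left corticospinal tract: a
quarter-circle arc (bend radius 30 mm) swept by a 6 mm-radius disk in a
64³ grid of 2 mm isotropic voxels (geometry also available as a straight
tube for symmetry tests). Deep tube voxels carry a prolate tensor with
eigenvalues (1.7, 0.3, 0.3)·10⁻³ mm²/s (FA ≈ 0.80) whose principal axis is
the local arc tangent; the background is isotropic with the same mean
diffusivity (0.767·10⁻³ mm²/s). Within one voxel of the tube surface the
tensor blends linearly toward the background (weight 1 at depth ≥ one
voxel, 0 at the surface), and the tube ends flat with the same one-voxel
taper — this partial-volume shell reproduces the anisotropy loss at tract
borders that makes plain streamline tracking underestimate bundles. The
whole geometry is shifted off the voxel-center lattice by a third of a
voxel so no voxel center lies exactly on a boundary plane (the voxelized
volume would otherwise be tie-dependent); the voxelized bundle volume
matches π r² L to a fraction of a percent.

Signals use S0 = 1000 and one b = 1000 s/mm² shell over 30 embedded
quasi-uniform directions (antipodally symmetric electrostatic repulsion,
checked in as a text table for bit-reproducibility) plus one b=0 volume.
Noise is complex Gaussian: `|S + n_r + i·n_i|` with i.i.d. N(0, σ)
components (Rician magnitude). σ is chosen per level so that the measured
SNR — mean noise-free b0 signal inside the bundle divided by σ, the
estimator is a package choice — equals the target: level 0 noise-free,
level 1 ≈ 65, level 2 ≈ 32.

The ground-truth bundle mask contains the voxels whose centers lie inside
the tube. The seed and include ROIs are the first in-bundle voxel layer at
either tube end with radius `tube_radius − voxel_size` (4 mm at defaults):
manual ROIs outline the clearly visible, high-FA core of a structure
conservatively, and this choice reproduces the documented underestimation
mechanism — the two-ROI baseline recovers essentially the core cylinder,
while the scaled re-seeded regions reach the partial-volume border. The
cap radius is configurable (`roi_radius`).

What the phantom does **not** model: crossing/kissing/fanning fiber
populations, anatomical surroundings (CSF, gray matter), eddy-current or
motion artifacts, field inhomogeneity, or the specific anatomical phantom
geometry used in clinical evaluations. Passing tests therefore demonstrate
the method's mechanics and its directional behavior (re-seeding with
outward scaling beats the two-ROI baseline; robustness to Rician noise at
clinical SNRs), not absolute DSC levels on real brains.

## Evaluation

DSC = 2|A∩B|/(|A|+|B|); two empty masks score 1 with a warning (the
formula is 0/0 there). The sweep grid is the full factorial NOISE {0,1,2}
× SEEDS {2,3,5,9,17,33,65,129} × SCALING {0..5} mm × FBM {10..100 %} =
1440 parameterizations; repeated tracking is cached per (noise, seeds,
scaling) so the ten FBM rows of a triple share one count mask. Group
summaries report mean/std/min/max DSC in percent with the sample standard
deviation (n−1). Inferential statistics are intentionally out of scope;
the CSV output (`noise,seeds,scaling,fbm,dsc`) is designed for external
stats packages.

The default test suite and the acceptance script use a reduced sweep
(SEEDS {5, 33} × SCALING {0, 2} × all FBM at all three noise levels, 120
records, one 64³ phantom per level) — problem sizes chosen so a complete
run takes well under a minute on one CPU while still containing the
preferred band (SCALING ≥ 1, SEEDS > 2, FBM 30–50) and its contrasts.

## Known limitations

- Single-tensor model only; no HARDI/Q-ball or multi-fiber handling.
- Axis-aligned isotropic NIfTI geometry only; oblique affines are rejected.
- Whole-brain baselines on the phantom reduce to near-identical masks
  (original and variant seed volumes both cover every trackable voxel of
  the single bundle); the distinction is meaningful only on data with
  more than one structure.
- Deterministic tie-breaks (eigenvector sign, in-plane basis) are fixed
  conventions, not physically meaningful.
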