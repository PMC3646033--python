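"""Binary fiber masks, visitation-count accumulation and the repeated
tracking pipeline.

A tracking result becomes a binary mask (a voxel scores 1 if any
streamline crosses or touches it).  Repeated tracking from n generated
seed regions produces n binary masks whose element-wise sum is the count
mask with values 0..n; thresholding the count mask at a fiber-bundle-
membership (FBM) percentage yields the final segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from math import ceil

import numpy as np

from .centerline import (
    Centerline,
    SeedPlan,
    compute_centerline,
    plane_at,
    scale_contour,
    seed_points_in_contour,
    select_plane_indices,
    trace_contour,
)
from .grid import Grid
from .tensor import TensorField
from .tracking import (
    StreamlineBundle,
    TrackingParams,
    filter_by_include,
    propagate_bundle,
    seeds_from_mask,
)


@dataclass
class BinaryMask:
    data: np.ndarray  # {0,1}
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("binary mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * self.grid.voxel_size**3


@dataclass
class CountMask:
    data: np.ndarray  # 0..n_regions
    n_regions: int
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(np.int32)
        if self.data.shape != self.grid.shape:
            raise ValueError("count mask shape does not match grid")
        if self.data.min() < 0 or self.data.max() > self.n_regions:
            raise ValueError("count values must lie in [0, n_regions]")


@dataclass
class RepeatedResult:
    """Everything one repeated-tracking run produces."""

    count_mask: CountMask
    per_region_masks: list[BinaryMask]
    centerline: Centerline
    seed_plan: SeedPlan
    params: TrackingParams
    initial_mask: BinaryMask
    region_seed_points: list[np.ndarray] = dc_field(default_factory=list)

    def seed_volume(self) -> "BinaryMask":
        """Union of the rasterized calculated seed regions (the seed volume
        of the whole-brain-tractography variant baseline)."""
        pts = np.vstack(self.region_seed_points)
        return rasterize_points(pts, self.count_mask.grid)


# --------------------------------------------------------------------------

def streamlines_to_mask(bundle: StreamlineBundle, grid: Grid) -> BinaryMask:
    """Rasterize streamlines: segments are super-sampled at ≤ voxel_size/4
    and every voxel containing a sample is set."""
    out = np.zeros(grid.shape, dtype=np.uint8)
    shape = np.asarray(grid.shape)
    for s in bundle:
        s = np.asarray(s, dtype=float)
        if s.shape[0] == 1:
            pts = s
        else:
            p0, p1 = s[:-1], s[1:]
            seglen = np.linalg.norm(p1 - p0, axis=1)
            n_sub = max(1, int(np.ceil(seglen.max() / (grid.voxel_size / 4.0))))
            t = np.linspace(0.0, 1.0, n_sub, endpoint=False)
            pts = (p0[:, None, :] + t[None, :, None] * (p1 - p0)[:, None, :]).reshape(-1, 3)
            pts = np.vstack([pts, s[-1]])
        idx = grid.nearest_voxel(pts)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return BinaryMask(out, grid)


def accumulate(masks: list[BinaryMask]) -> CountMask:
    """Element-wise integer sum of per-region binary masks."""
    if not masks:
        raise ValueError("no masks to accumulate")
    grid = masks[0].grid
    for m in masks[1:]:
        if not m.grid.same_as(grid):
            raise ValueError("masks are on different grids")
    total = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        total += m.data
    return CountMask(total, len(masks), grid)


def fbm_threshold(cm: CountMask, fbm_percent: int) -> BinaryMask:
    """Voxels covered by at least ``fbm_percent`` % of the reconstructions.

    A voxel is kept iff its count ≥ ceil(fbm/100 · n_regions), so ties at
    exact multiples are included ("90 % or more").
    """
    if not 0 < fbm_percent <= 100:
        raise ValueError("fbm_percent must be in (0, 100]")
    thr = ceil(fbm_percent / 100.0 * cm.n_regions)
    return BinaryMask((cm.data >= thr).astype(np.uint8), cm.grid)


# --------------------------------------------------------------------------
# pipeline stages

def _track_two_roi(field: TensorField, seed_roi: np.ndarray, include_roi: np.ndarray,
                   tparams: TrackingParams, seed_density: int = 1) -> StreamlineBundle:
    seeds = seeds_from_mask(seed_roi, field.grid, seed_density)
    bundle = propagate_bundle(field, seeds, tparams, provenance="two-roi")
    return filter_by_include(bundle, [include_roi], field.grid, mode="ALL")


def run_two_roi(field: TensorField, seed_roi, include_roi,
                tparams: TrackingParams = TrackingParams(),
                seed_density: int = 1) -> BinaryMask:
    """Classic two-ROI baseline: seed in the first ROI, keep streamlines
    reaching the second, rasterize."""
    bundle = _track_two_roi(field, np.asarray(seed_roi), np.asarray(include_roi),
                            tparams, seed_density)
    return streamlines_to_mask(bundle, field.grid)


def rasterize_points(points, grid: Grid) -> BinaryMask:
    """Mark the voxel nearest to every point (used for seed-region export)."""
    out = np.zeros(grid.shape, dtype=np.uint8)
    idx = grid.nearest_voxel(np.atleast_2d(points))
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    idx = idx[ok]
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return BinaryMask(out, grid)


def _plane_origin_inside(mask, grid, origin) -> bool:
    idx = grid.nearest_voxel(origin)
    if not grid.contains_index(idx):
        return False
    return mask[tuple(idx)] > 0


def run_repeated_tracking(
    field: TensorField,
    seed_roi,
    include_roi,
    plan: SeedPlan,
    tparams: TrackingParams = TrackingParams(),
    *,
    n_centerline: int = 129,
    seed_spacing_mm: float = 1.0,
    n_rays: int = 36,
    ray_step_mm: float = 0.5,
    max_radius_mm: float = 30.0,
    seed_density: int = 1,
) -> RepeatedResult:
    """Full repeated-tracking pipeline for one seed plan.

    1. initial two-ROI tracking and fiber mask;
    2. centerline (``n_centerline`` samples) of the initial bundle;
    3. ``plan.n_seeds`` planes at equally spaced centerline indices, each
       with a ray-cast contour scaled outwards by ``plan.scaling_mm`` and
       filled with a regular seed grid;
    4. tracking from every generated region, filtered with the initial
       seed and include ROIs as *alternative* includes (ANY), one binary
       mask per region;
    5. accumulation into the count mask (denominator = n regions; the
       initial result itself does not contribute).
    """
    seed_roi = np.asarray(seed_roi)
    include_roi = np.asarray(include_roi)
    grid = field.grid

    initial = _track_two_roi(field, seed_roi, include_roi, tparams, seed_density)
    if len(initial) == 0:
        raise RuntimeError("initial reconstruction empty")
    initial_mask = streamlines_to_mask(initial, grid)

    cl = compute_centerline(initial, n_centerline)
    indices = select_plane_indices(n_centerline, plan.n_seeds)

    region_masks: list[BinaryMask] = []
    region_seeds: list[np.ndarray] = []
    for count, i in enumerate(indices):
        frame = plane_at(cl, int(i))
        # averaging can push an end plane's origin just outside the voxelized
        # mask; nudge along the centerline toward the interior (≤ 1 voxel)
        if not _plane_origin_inside(initial_mask.data, grid, frame.origin):
            j = int(i)
            towards = 1 if j < n_centerline - 1 else -1
            target = cl.points[j + towards]
            step_v = target - frame.origin
            nstep = np.linalg.norm(step_v)
            fixed = False
            if nstep > 0:
                step_v = step_v / nstep * (grid.voxel_size / 4.0)
                origin = frame.origin.copy()
                for _ in range(4):
                    origin = origin + step_v
                    if _plane_origin_inside(initial_mask.data, grid, origin):
                        frame = type(frame)(origin, frame.normal, frame.u, frame.v)
                        fixed = True
                        break
            if not fixed:
                raise ValueError("plane origin lies outside the tract mask")
        ctr = trace_contour(frame, initial_mask.data, grid, n_rays=n_rays,
                            ray_step_mm=ray_step_mm, max_radius_mm=max_radius_mm)
        if plan.scaling_mm > 0:
            ctr = scale_contour(ctr, plan.scaling_mm)
        seeds = seed_points_in_contour(ctr, seed_spacing_mm)
        region_seeds.append(seeds)
        bundle = propagate_bundle(field, seeds, tparams, provenance=f"region-{count}")
        bundle = filter_by_include(bundle, [seed_roi, include_roi], grid, mode="ANY")
        region_masks.append(streamlines_to_mask(bundle, grid))

    count_mask = accumulate(region_masks)
    return RepeatedResult(count_mask, region_masks, cl, plan, tparams, initial_mask,
                          region_seeds)


def run_whole_brain(field: TensorField, seed_volume: BinaryMask, roi_a, roi_b,
                    tparams: TrackingParams = TrackingParams()) -> BinaryMask:
    """Whole-volume seeding baseline, restricted by both ROIs combined (AND)."""
    if seed_volume.data.sum() == 0:
        raise ValueError("empty seed volume")
    seeds = seeds_from_mask(seed_volume.data, field.grid, 1)
    bundle = propagate_bundle(field, seeds, tparams, provenance="whole-brain")
    bundle = filter_by_include(bundle, [np.asarray(roi_a), np.asarray(roi_b)],
                               field.grid, mode="ALL")
    return streamlines_to_mask(bundle, field.grid)


def brain_mask_from_fa(field: TensorField, fa_threshold: float) -> BinaryMask:
    """FA-suprathreshold mask used as the 'whole brain' seed volume."""
    return BinaryMask((field.fa_map() >= fa_threshold).astype(np.uint8), field.grid)
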