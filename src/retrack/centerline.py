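"""Bundle centerline extraction and planar seed-region generation.

The centerline of a streamline bundle is the point-wise average of all
streamlines after orientation alignment and arc-length resampling to a
common number of samples.  At selected centerline points a plane
perpendicular to the local direction is erected; rays cast in that plane
find the tract-mask boundary, a closed periodic spline through the
boundary points defines the seed-region contour (optionally moved
outwards by a scaling offset in mm), and a regular in-plane point grid
clipped by the contour yields the seed points for re-tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.interpolate import CubicSpline

from .grid import Grid
from .tracking import StreamlineBundle


@dataclass
class Centerline:
    points: np.ndarray  # (n, 3) world mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("centerline contains non-finite coordinates")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class PlaneFrame:
    """Orthonormal right-handed frame {u, v, normal} anchored at ``origin``."""

    origin: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def to_world(self, uv) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return self.origin + uv[:, :1] * self.u + uv[:, 1:2] * self.v


@dataclass
class Contour:
    """Ray-cast boundary of a tract cross-section with its spline outline."""

    plane: PlaneFrame
    ray_angles: np.ndarray          # (R,) radians, equally spaced
    radii: np.ndarray               # (R,) mm, one per ray
    spline_samples: np.ndarray      # (M, 2) closed in-plane polyline, first == last
    truncated: np.ndarray | None = None  # rays that hit max_radius while inside


@dataclass(frozen=True)
class SeedPlan:
    """Number of generated seed regions and their outward scaling offset."""

    n_seeds: int
    scaling_mm: float

    def __post_init__(self):
        if self.n_seeds < 2:
            raise ValueError("n_seeds must be >= 2")
        if self.scaling_mm < 0:
            raise ValueError("scaling_mm must be >= 0")


# --------------------------------------------------------------------------

def resample_streamline(s, n: int) -> np.ndarray:
    """n points equally spaced by arc length along a polyline, endpoints kept."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points to resample")
    if n < 2:
        raise ValueError("n must be >= 2")
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return np.repeat(s[:1], n, axis=0)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, arc, s[:, k])
    return out


def compute_centerline(bundle: StreamlineBundle, n: int) -> Centerline:
    """Point-wise average of orientation-aligned, resampled streamlines.

    Each streamline is flipped when its endpoints match the reference
    streamline (the longest one) better in reversed order; single-point
    streamlines are ignored.
    """
    lines = [np.asarray(s, dtype=float) for s in bundle if len(s) >= 2]
    if not lines:
        raise ValueError("bundle has no streamlines with >= 2 points")
    ref = max(lines, key=lambda s: s.shape[0])
    acc = np.zeros((n, 3))
    for s in lines:
        d_fwd = np.linalg.norm(s[0] - ref[0]) + np.linalg.norm(s[-1] - ref[-1])
        d_rev = np.linalg.norm(s[0] - ref[-1]) + np.linalg.norm(s[-1] - ref[0])
        if d_rev < d_fwd:
            s = s[::-1]
        acc += resample_streamline(s, n)
    return Centerline(acc / len(lines))


def _frame_from_normal(origin, normal) -> PlaneFrame:
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # deterministic in-plane basis: cross with the axis of smallest |component|
    ax = int(np.argmin(np.abs(normal)))
    e = np.zeros(3)
    e[ax] = 1.0
    u = np.cross(e, normal)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return PlaneFrame(np.asarray(origin, dtype=float), normal, u, v)


def plane_at(c: Centerline, i: int) -> PlaneFrame:
    """Plane through centerline point i, perpendicular to the local direction.

    The direction comes from the segment to the next point (the previous
    one for the last index); coincident consecutive points fall back to
    the nearest distinct neighbor.
    """
    if not 0 <= i < c.n:
        raise IndexError(f"index {i} out of range for centerline of {c.n} points")
    pts = c.points
    direction = None
    for j in range(i + 1, c.n):  # forward neighbors
        d = pts[j] - pts[i]
        if np.linalg.norm(d) > 1e-12:
            direction = d
            break
    if direction is None:
        for j in range(i - 1, -1, -1):
            d = pts[i] - pts[j]
            if np.linalg.norm(d) > 1e-12:
                direction = d
                break
    if direction is None:
        raise ValueError("all centerline points coincide; no direction defined")
    return _frame_from_normal(pts[i], direction)


def select_plane_indices(n_centerline: int, n_seeds: int) -> np.ndarray:
    """n_seeds indices equally spaced over [0, n_centerline-1], endpoints in."""
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    if n_seeds > n_centerline:
        raise ValueError(f"n_seeds={n_seeds} exceeds centerline length {n_centerline}")
    idx = np.rint(np.linspace(0, n_centerline - 1, n_seeds)).astype(int)
    assert np.all(np.diff(idx) >= 1)
    return idx


def _mask_lookup(mask, grid: Grid, pts) -> np.ndarray:
    """Nearest-voxel membership; points outside the grid count as outside."""
    idx = grid.nearest_voxel(pts)
    ok = grid.contains_index(idx)
    idc = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    inside = mask[idc[..., 0], idc[..., 1], idc[..., 2]] > 0
    return inside & ok


def _fit_closed_spline(angles, radii, n_samples: int = 128) -> np.ndarray:
    """Closed periodic cubic spline through polar contour points.

    Returns (n_samples + 1, 2) in-plane points with first == last.
    """
    ang_ext = np.concatenate([angles, [angles[0] + 2 * np.pi]])
    rad_ext = np.concatenate([radii, [radii[0]]])
    cs = CubicSpline(ang_ext, rad_ext, bc_type="periodic")
    a = np.linspace(angles[0], angles[0] + 2 * np.pi, n_samples + 1)
    r = cs(a)
    return np.stack([r * np.cos(a), r * np.sin(a)], axis=1)


def trace_contour(plane: PlaneFrame, tract_mask, grid: Grid, n_rays: int = 36,
                  ray_step_mm: float = 0.5, max_radius_mm: float = 30.0,
                  n_spline_samples: int = 128) -> Contour:
    """Ray-cast the tract-mask boundary in the plane and spline the outline.

    Each of ``n_rays`` equally spaced rays is sampled every ``ray_step_mm``;
    its radius is the distance to the first sample outside the mask
    (nearest-voxel lookup).  Rays still inside at ``max_radius_mm`` are
    truncated there and flagged.
    """
    if not _mask_lookup(tract_mask, grid, plane.origin[None, :])[0]:
        raise ValueError("plane origin lies outside the tract mask")
    angles = 2 * np.pi * np.arange(n_rays) / n_rays
    dirs = np.cos(angles)[:, None] * plane.u + np.sin(angles)[:, None] * plane.v
    ts = ray_step_mm * np.arange(1, int(np.ceil(max_radius_mm / ray_step_mm)) + 1)
    pts = plane.origin + dirs[:, None, :] * ts[None, :, None]  # (R, T, 3)
    inside = _mask_lookup(tract_mask, grid, pts.reshape(-1, 3)).reshape(len(angles), len(ts))
    first_out = np.argmax(~inside, axis=1)  # 0 if all inside -> handled below
    all_inside = inside.all(axis=1)
    radii = ts[first_out]
    radii[all_inside] = max_radius_mm
    spline = _fit_closed_spline(angles, radii, n_spline_samples)
    return Contour(plane, angles, radii, spline, truncated=all_inside)


def scale_contour(ctr: Contour, scaling_mm: float) -> Contour:
    """Move every contour point outwards along its ray and refit the spline."""
    if scaling_mm < 0:
        raise ValueError("scaling_mm must be >= 0")
    radii = ctr.radii + scaling_mm
    spline = _fit_closed_spline(ctr.ray_angles, radii, ctr.spline_samples.shape[0] - 1)
    return Contour(ctr.plane, ctr.ray_angles, radii, spline, truncated=ctr.truncated)


def seed_points_in_contour(ctr: Contour, spacing_mm: float = 1.0) -> np.ndarray:
    """Regular in-plane grid clipped by the contour, mapped to world mm.

    Always includes the plane origin, so a degenerate contour still yields
    one seed.
    """
    poly = ctr.spline_samples
    lo = poly.min(axis=0)
    hi = poly.max(axis=0)
    us = np.arange(lo[0], hi[0] + spacing_mm / 2, spacing_mm)
    vs = np.arange(lo[1], hi[1] + spacing_mm / 2, spacing_mm)
    if us.size and vs.size:
        uu, vv = np.meshgrid(us, vs, indexing="ij")
        cand = np.stack([uu.ravel(), vv.ravel()], axis=1)
        keep = MplPath(poly).contains_points(cand)
        uv = cand[keep]
    else:
        uv = np.empty((0, 2))
    uv = np.vstack([[0.0, 0.0], uv])  # plane origin first
    return ctr.plane.to_world(uv)
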