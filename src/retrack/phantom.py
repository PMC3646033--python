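"""Synthetic tensor phantom: a curved fiber bundle in isotropic background.

The phantom emulates a segment of the left corticospinal tract: a circular
arc (default a quarter circle) swept by a disk, embedded in an isotropic
medium.  Voxels deep inside the tube carry a prolate tensor whose principal
axis is the local arc tangent; a one-voxel shell at the tube surface blends
linearly toward the background tensor, emulating the partial-volume
anisotropy loss at tract borders.  DWI signals are synthesized from the
Stejskal–Tanner relation and degraded with complex Gaussian noise to reach
target SNRs of about 65 (level 1) and 32 (level 2); level 0 is noise-free.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .grid import Grid
from .tensor import TensorField, design_matrix, fit_tensor_loglinear

#: noise level -> target magnitude SNR (mean noise-free b0 over bundle / sigma)
SNR_BY_LEVEL = {0: math.inf, 1: 65.0, 2: 32.0}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic bundle phantom.

    Defaults give a quarter-circle tube of 30 mm bend radius and 6 mm
    cross-sectional radius in a 64³ grid of 2 mm voxels, with eigenvalues
    typical of coherent white matter (FA ≈ 0.80) over a background with
    the same mean diffusivity.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    arc_radius: float = 30.0
    tube_radius: float = 6.0
    bundle_eigenvalues: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)
    background_diffusivity: float = 0.766_67e-3
    s0: float = 1000.0
    noise_level: int = 0
    rng_seed: int = 0
    geometry: str = "arc"  # "arc" (quarter circle) or "straight"
    roi_radius: float | None = None  # default: tube_radius - voxel_size

    def __post_init__(self):
        ev = self.bundle_eigenvalues
        if not (ev[0] >= ev[1] >= ev[2] > 0):
            raise ValueError("bundle eigenvalues must be descending and positive")
        if self.noise_level not in SNR_BY_LEVEL:
            raise ValueError(f"noise_level must be in {sorted(SNR_BY_LEVEL)}")
        if self.geometry not in ("arc", "straight"):
            raise ValueError("geometry must be 'arc' or 'straight'")
        if self.tube_radius <= 0 or self.arc_radius <= 0:
            raise ValueError("radii must be positive")

    @property
    def effective_roi_radius(self) -> float:
        return self.tube_radius - self.voxel_size if self.roi_radius is None else self.roi_radius

    @property
    def snr(self) -> float:
        return SNR_BY_LEVEL[self.noise_level]


@dataclass(frozen=True)
class GradientScheme:
    """One-shell diffusion gradient scheme including a b=0 entry."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (K, 3); zero row for b=0 entries

    def __post_init__(self):
        object.__setattr__(self, "bvals", np.asarray(self.bvals, dtype=float))
        object.__setattr__(self, "bvecs", np.asarray(self.bvecs, dtype=float))
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ValueError("bvals and bvecs length mismatch")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        dwi = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if dwi.sum() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-encoding directions must be unit length")
        if dwi.sum() < 6:
            raise ValueError("at least 6 diffusion-weighted directions required")
        B = design_matrix(self.bvals[dwi], self.bvecs[dwi])
        if np.linalg.matrix_rank(B) < 6:
            raise ValueError("gradient directions are collinear (rank < 6)")

    @classmethod
    def default30(cls, b_value: float = 1000.0) -> "GradientScheme":
        """b=0 plus 30 embedded quasi-uniform directions at one shell."""
        ref = importlib.resources.files("retrack").joinpath("data/directions30.txt")
        with importlib.resources.as_file(ref) as path:
            dirs = np.loadtxt(path)
        bvals = np.concatenate([[0.0], np.full(len(dirs), float(b_value))])
        bvecs = np.vstack([np.zeros(3), dirs])
        return cls(bvals, bvecs)

    @property
    def n_entries(self) -> int:
        return len(self.bvals)


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal volume on an isotropic grid."""

    signals: np.ndarray  # (x, y, z, K)
    scheme: GradientScheme
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.signals.shape[-1] != self.scheme.n_entries:
            raise ValueError("4th dimension does not match gradient scheme length")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")

    @property
    def grid(self) -> Grid:
        return Grid(self.signals.shape[:3], self.voxel_size, self.origin)


@dataclass
class GroundTruth:
    """Bundle mask plus the two end-cap ROIs (seed = peduncle analogue)."""

    bundle_mask: "np.ndarray"
    seed_roi: "np.ndarray"
    include_roi: "np.ndarray"
    grid: Grid


# --------------------------------------------------------------------------
# analytic centerline helpers (shared with tests as the geometric oracle)

def arc_parameters(cfg: PhantomConfig):
    """Center of the arc circle (arc lies in the y = cy plane, x–z).

    The center is shifted off the voxel-center lattice by a third of a
    voxel so that no voxel center falls exactly on a tube boundary plane
    (which would make the voxelized volume tie-dependent).
    """
    extent = np.asarray(cfg.grid_shape) * cfg.voxel_size
    off = cfg.voxel_size / 3.0
    cx = extent[0] / 2 - cfg.arc_radius / 2 + off
    cy = extent[1] / 2
    cz = extent[2] / 2 - cfg.arc_radius / 2 + off
    return np.array([cx, cy, cz])


def analytic_centerline(cfg: PhantomConfig, n: int = 200) -> np.ndarray:
    """n points on the tube's central curve, in world mm."""
    if cfg.geometry == "arc":
        c = arc_parameters(cfg)
        th = np.linspace(0, np.pi / 2, n)
        return np.stack(
            [c[0] + cfg.arc_radius * np.cos(th),
             np.full(n, c[1]),
             c[2] + cfg.arc_radius * np.sin(th)], axis=1)
    extent = np.asarray(cfg.grid_shape) * cfg.voxel_size
    length = cfg.arc_radius * np.pi / 2
    off = cfg.voxel_size / 3.0  # keep boundary planes off the voxel-center lattice
    x = np.linspace(extent[0] / 2 - length / 2, extent[0] / 2 + length / 2, n) + off
    return np.stack([x, np.full(n, extent[1] / 2), np.full(n, extent[2] / 2)], axis=1)


def _distance_and_tangent(cfg: PhantomConfig, pts: np.ndarray):
    """Per point: radial distance to the (clamped) central curve, the local
    tangent there, and the arc-length overshoot beyond the tube ends (0
    inside the span), so the tube can end with flat caps."""
    if cfg.geometry == "arc":
        c = arc_parameters(cfg)
        dx = pts[..., 0] - c[0]
        dz = pts[..., 2] - c[2]
        th_raw = np.arctan2(dz, dx)
        th = np.clip(th_raw, 0.0, np.pi / 2)
        near = np.stack(
            [c[0] + cfg.arc_radius * np.cos(th),
             np.full(th.shape, c[1]),
             c[2] + cfg.arc_radius * np.sin(th)], axis=-1)
        dist = np.linalg.norm(pts - near, axis=-1)
        tang = np.stack([-np.sin(th), np.zeros_like(th), np.cos(th)], axis=-1)
        overshoot = cfg.arc_radius * np.maximum.reduce(
            [np.zeros_like(th_raw), -th_raw, th_raw - np.pi / 2])
        return dist, tang, overshoot
    cl = analytic_centerline(cfg, 2)
    x0, x1 = cl[0, 0], cl[1, 0]
    cy, cz = cl[0, 1], cl[0, 2]
    xc = np.clip(pts[..., 0], x0, x1)
    near = np.stack([xc, np.full(xc.shape, cy), np.full(xc.shape, cz)], axis=-1)
    dist = np.linalg.norm(pts - near, axis=-1)
    tang = np.zeros(pts.shape)
    tang[..., 0] = 1.0
    overshoot = np.maximum.reduce(
        [np.zeros_like(xc), x0 - pts[..., 0], pts[..., 0] - x1])
    return dist, tang, overshoot


def _prolate_coeffs(tangent: np.ndarray, eigenvalues) -> np.ndarray:
    """Axially symmetric tensor with principal axis = tangent (λ2 == λ3)."""
    l1, l2, l3 = eigenvalues
    lt = 0.5 * (l2 + l3)  # transverse; symmetric about the axis
    t = tangent
    out = np.empty(t.shape[:-1] + (6,))
    outer = {
        0: t[..., 0] * t[..., 0], 1: t[..., 0] * t[..., 1], 2: t[..., 0] * t[..., 2],
        3: t[..., 1] * t[..., 1], 4: t[..., 1] * t[..., 2], 5: t[..., 2] * t[..., 2],
    }
    iso = {0: 1.0, 1: 0.0, 2: 0.0, 3: 1.0, 4: 0.0, 5: 1.0}
    for k in range(6):
        out[..., k] = lt * iso[k] + (l1 - lt) * outer[k]
    return out


def build_tensor_field(cfg: PhantomConfig) -> tuple[TensorField, GroundTruth]:
    """Construct the noiseless phantom tensor field and its ground truth.

    Voxels with center-to-curve distance ≤ ``tube_radius`` form the bundle
    mask and carry the prolate tensor; within one voxel of the surface the
    tensor blends linearly toward the isotropic background (weight 1 at
    depth ≥ one voxel, 0 at the surface).  The seed and include ROIs are
    one-voxel-thick disks at the two tube ends with radius
    ``cfg.effective_roi_radius``.
    """
    grid = Grid(cfg.grid_shape, cfg.voxel_size, np.full(3, cfg.voxel_size / 2))
    extent = np.asarray(cfg.grid_shape) * cfg.voxel_size

    cl = analytic_centerline(cfg, 400)
    margin = cfg.tube_radius + cfg.voxel_size
    for ax, name in enumerate("xyz"):
        lo, hi = cl[:, ax].min() - margin, cl[:, ax].max() + margin
        if lo < 0 or hi > extent[ax]:
            raise ValueError(f"tube exceeds grid bounds along axis {name}")

    centers = grid.voxel_centers()
    dist, tang, overshoot = _distance_and_tangent(cfg, centers)

    prolate = _prolate_coeffs(tang, cfg.bundle_eigenvalues)
    iso = np.zeros(grid.shape + (6,))
    for k in (0, 3, 5):
        iso[..., k] = cfg.background_diffusivity

    # partial-volume blend over the one-voxel shell inside the surface;
    # the tube ends flat, with the same one-voxel taper past the end planes
    w = np.clip((cfg.tube_radius - dist) / cfg.voxel_size, 0.0, 1.0)
    w *= np.clip(1.0 - overshoot / cfg.voxel_size, 0.0, 1.0)
    coeffs = w[..., None] * prolate + (1.0 - w[..., None]) * iso
    field = TensorField(coeffs, grid)

    bundle_mask = ((dist <= cfg.tube_radius) & (overshoot <= 1e-9)).astype(np.uint8)

    ends = analytic_centerline(cfg, 2)
    _, end_tangs, _ = _distance_and_tangent(cfg, ends)
    rois = []
    for k, (p_end, n_end) in enumerate(zip(ends, end_tangs)):
        inward = n_end if k == 0 else -n_end  # tangent points toward increasing arc length
        rel = centers - p_end
        along = np.tensordot(rel, inward, axes=([-1], [0]))
        radial = np.linalg.norm(rel - along[..., None] * inward, axis=-1)
        # first in-bundle voxel layer at the tube end
        roi = (along >= 0) & (along <= cfg.voxel_size) & (radial <= cfg.effective_roi_radius)
        rois.append((roi & (bundle_mask > 0)).astype(np.uint8))
    truth = GroundTruth(bundle_mask, rois[0], rois[1], grid)
    if truth.seed_roi.sum() == 0 or truth.include_roi.sum() == 0:
        raise ValueError("end-cap ROI is empty; enlarge the tube or roi_radius")
    return field, truth


def simulate_dwi(field: TensorField, scheme: GradientScheme, s0: float) -> DWIVolume:
    """Noiseless signals ``S_k = s0·exp(-b g_kᵀ D g_k)`` per voxel."""
    B = design_matrix(scheme.bvals, scheme.bvecs)  # (K, 6)
    expo = field.coeffs @ B.T
    signals = s0 * np.exp(-expo)
    return DWIVolume(signals, scheme, field.grid.voxel_size, field.grid.origin)


def add_complex_gaussian_noise(dwi: DWIVolume, sigma: float, seed: int) -> DWIVolume:
    """Rician magnitude noise: ``|S + n_r + i·n_i|`` with i.i.d. N(0, σ) parts."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return DWIVolume(dwi.signals.copy(), dwi.scheme, dwi.voxel_size, dwi.origin)
    rng = np.random.default_rng(seed)
    nr = rng.normal(0.0, sigma, dwi.signals.shape)
    ni = rng.normal(0.0, sigma, dwi.signals.shape)
    mag = np.hypot(dwi.signals + nr, ni)
    return DWIVolume(mag, dwi.scheme, dwi.voxel_size, dwi.origin)


def sigma_for_snr(dwi: DWIVolume, bundle_mask: np.ndarray, snr: float) -> float:
    """Per-channel Gaussian σ giving the target magnitude SNR.

    SNR is defined as the mean noise-free b0 signal inside the bundle
    divided by σ.
    """
    if not math.isfinite(snr):
        return 0.0
    b0 = dwi.signals[..., dwi.scheme.bvals == 0].mean(axis=-1)
    return float(b0[bundle_mask > 0].mean() / snr)


@dataclass
class Phantom:
    """Everything one noise realization of the phantom produces."""

    config: PhantomConfig
    field_true: TensorField
    truth: GroundTruth
    scheme: GradientScheme
    dwi: DWIVolume
    tensors: TensorField  # fitted from (possibly noisy) signals
    sigma: float


def generate_phantom(cfg: PhantomConfig, scheme: GradientScheme | None = None) -> Phantom:
    """Build geometry, synthesize DWI, add noise at the configured level, refit.

    Deterministic given ``cfg`` (including ``rng_seed``).
    """
    scheme = scheme or GradientScheme.default30()
    field, truth = build_tensor_field(cfg)
    clean = simulate_dwi(field, scheme, cfg.s0)
    sigma = sigma_for_snr(clean, truth.bundle_mask, cfg.snr)
    noisy = add_complex_gaussian_noise(clean, sigma, cfg.rng_seed)
    tensors = fit_tensor_loglinear(noisy)
    return Phantom(cfg, field, truth, scheme, noisy, tensors, sigma)
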