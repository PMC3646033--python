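"""Diffusion tensor estimation, scalar maps and continuous interpolation.

The single-shell DWI signal follows the Stejskal–Tanner relation
``S_k = S0 · exp(-b g_kᵀ D g_k)`` with a symmetric 3×3 tensor ``D`` per
voxel.  Tensors are stored as 6 coefficients in lower-triangular order
(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz), in mm²/s, on the grid defined in
:mod:`retrack.grid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .grid import Grid

#: index pairs mapping the 6-vector to a symmetric 3x3 matrix
_TRI = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]

# tolerance below which a tensor counts as zero / degenerate
_EPS = 1e-15


def coeffs_to_matrix(c) -> np.ndarray:
    """(..., 6) coefficient array -> (..., 3, 3) symmetric matrices."""
    c = np.asarray(c, dtype=float)
    m = np.empty(c.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_TRI):
        m[..., i, j] = c[..., k]
        m[..., j, i] = c[..., k]
    return m


def matrix_to_coeffs(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., i, j] for (i, j) in _TRI], axis=-1)


@dataclass
class TensorField:
    """Voxel grid of symmetric diffusion tensors.

    ``coeffs`` has shape ``grid.shape + (6,)``; ``clamped`` flags voxels
    where negative eigenvalues were clipped to zero during fitting.
    """

    coeffs: np.ndarray
    grid: Grid
    clamped: np.ndarray | None = dc_field(default=None, repr=False)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != self.grid.shape + (6,):
            raise ValueError(
                f"coeffs shape {self.coeffs.shape} does not match grid {self.grid.shape}"
            )

    def tensor_at(self, idx) -> np.ndarray:
        return coeffs_to_matrix(self.coeffs[tuple(idx)])

    def fa_map(self) -> np.ndarray:
        return fractional_anisotropy(self.coeffs)


def design_matrix(bvals, bvecs) -> np.ndarray:
    """Rows ``b·(gx², 2gxgy, 2gxgz, gy², 2gygz, gz²)`` so that B @ c = b·gᵀDg."""
    bvals = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    if np.any(bvals < 0):
        raise ValueError("negative b-value")
    B = np.column_stack(
        [
            g[:, 0] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            g[:, 1] ** 2,
            2 * g[:, 1] * g[:, 2],
            g[:, 2] ** 2,
        ]
    )
    return bvals[:, None] * B


def fit_tensor_loglinear(dwi, *, weighted: bool = False, clamp: bool = True) -> TensorField:
    """Ordinary least-squares tensor fit in the log-signal domain.

    Solves ``log(S_k/S0) = -b g_kᵀ D g_k`` per voxel.  ``S0`` is the mean
    of the b=0 volumes.  Zero/negative signals are floored to a small
    epsilon before the log.  With ``weighted=True`` a single reweighting
    pass using the predicted signals as weights is applied.

    Parameters
    ----------
    dwi : DWIVolume
        4D signal volume with its gradient scheme.

    Returns
    -------
    TensorField
        Negative eigenvalues are clamped to 0 and flagged when ``clamp``.
    """
    scheme = dwi.scheme
    b0_mask = scheme.bvals == 0
    if b0_mask.sum() < 1:
        raise ValueError("gradient scheme contains no b=0 entry")
    B = design_matrix(scheme.bvals[~b0_mask], scheme.bvecs[~b0_mask])
    if np.linalg.matrix_rank(B) < 6:
        raise ValueError("rank-deficient design matrix: gradient directions are collinear")

    signals = np.asarray(dwi.signals, dtype=float)
    s0 = signals[..., b0_mask].mean(axis=-1)
    s0 = np.maximum(s0, _EPS)
    s = np.maximum(signals[..., ~b0_mask], 1e-12)
    y = -np.log(s / s0[..., None])  # (...,K) target: b gᵀDg

    pinv = np.linalg.pinv(B)
    coeffs = y @ pinv.T

    if weighted:
        # one IRLS pass with weights = predicted signals (Salvador-style WLS)
        w = np.exp(-(coeffs @ B.T))
        w = np.clip(w, 1e-6, None)
        sh = y.shape[:-1]
        yf = y.reshape(-1, y.shape[-1])
        wf = w.reshape(-1, w.shape[-1])
        out = np.empty((yf.shape[0], 6))
        for i in range(yf.shape[0]):  # modest sizes only behind this flag
            Bw = B * wf[i][:, None]
            out[i] = np.linalg.lstsq(Bw, yf[i] * wf[i], rcond=None)[0]
        coeffs = out.reshape(sh + (6,))

    clamped = None
    if clamp:
        m = coeffs_to_matrix(coeffs)
        w_eig, v = np.linalg.eigh(m)
        neg = w_eig < 0
        clamped = np.any(neg, axis=-1)
        if clamped.any():
            w_eig = np.clip(w_eig, 0, None)
            m = np.einsum("...ij,...j,...kj->...ik", v, w_eig, v)
            coeffs = matrix_to_coeffs(m)
    grid = Grid(signals.shape[:3], dwi.voxel_size, dwi.origin)
    return TensorField(coeffs, grid, clamped=clamped)


def principal_eigenvector(t, *, return_degenerate: bool = False):
    """Unit eigenvector of the largest eigenvalue of symmetric tensor(s).

    Sign convention: the first axis (x, then y, then z) along which the
    vector has a non-negligible component is made non-negative, so the
    result is deterministic.  Works on a single (3, 3) matrix, a 6-vector
    of coefficients, or batches thereof.
    """
    t = np.asarray(t, dtype=float)
    if t.shape[-1] == 6 and (t.ndim == 1 or t.shape[-2:] != (3, 3)):
        t = coeffs_to_matrix(t)
    w, v = np.linalg.eigh(t)
    e1 = v[..., :, -1]
    # deterministic sign: first axis with |component| > tol becomes positive
    sign = np.ones(e1.shape[:-1])
    decided = np.zeros(e1.shape[:-1], dtype=bool)
    for ax in range(3):
        comp = e1[..., ax]
        pick = ~decided & (np.abs(comp) > 1e-12)
        sign = np.where(pick & (comp < 0), -1.0, sign)
        decided |= pick
    e1 = e1 * sign[..., None]
    norm = np.linalg.norm(e1, axis=-1, keepdims=True)
    e1 = np.divide(e1, norm, out=np.zeros_like(e1), where=norm > 0)
    # fully zero tensor -> eigh returns a valid basis vector anyway; keep it unit
    if return_degenerate:
        span = w[..., -1] - w[..., -2]
        scale = np.maximum(np.abs(w[..., -1]), _EPS)
        return e1, span <= 1e-9 * scale + _EPS
    return e1


def fractional_anisotropy(t) -> np.ndarray:
    """FA = sqrt(3/2)·‖λ − λ̄‖ / ‖λ‖, computed from tensor invariants.

    Accepts 6-coefficient arrays (..., 6) or matrices (..., 3, 3); returns 0
    for the zero tensor by convention.  Uses ``tr(D²)`` and ``tr(D)`` so no
    eigendecomposition is needed, which keeps the per-step cost of tracking
    low.
    """
    t = np.asarray(t, dtype=float)
    if t.shape[-2:] == (3, 3):
        c = matrix_to_coeffs(t)
    else:
        c = t
    tr = c[..., 0] + c[..., 3] + c[..., 5]
    frob2 = (
        c[..., 0] ** 2
        + c[..., 3] ** 2
        + c[..., 5] ** 2
        + 2 * (c[..., 1] ** 2 + c[..., 2] ** 2 + c[..., 4] ** 2)
    )
    dev2 = np.clip(frob2 - tr**2 / 3.0, 0.0, None)
    # cancellation guard: an exactly isotropic tensor must give exactly 0
    dev2 = np.where(dev2 < 1e-14 * frob2, 0.0, dev2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / frob2)
    return np.where(frob2 > _EPS, fa, 0.0)


def interpolate_many(field: TensorField, pts) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of tensor coefficients at many world points.

    Returns ``(coeffs, inside)`` where ``inside`` marks points within the
    voxel-center hull; coefficients outside are zero-filled.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    v = field.grid.world_to_voxel(pts)
    inside = field.grid.contains_world(pts)
    shape = np.asarray(field.grid.shape)
    vc = np.clip(v, 0, shape - 1)
    i0 = np.floor(vc).astype(np.int64)
    i0 = np.minimum(i0, shape - 2)  # keep the upper cell valid at the edge
    i0 = np.maximum(i0, 0)
    f = vc - i0
    out = np.zeros((pts.shape[0], 6))
    data = field.coeffs
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1 - f[:, 2]
                w = (wx * wy * wz)[:, None]
                out += w * data[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    out[~inside] = 0.0
    return out, inside


def interpolate_tensor(field: TensorField, p):
    """Tensor coefficients at a single world point, or ``None`` outside.

    Returning ``None`` (rather than raising) lets the tracker treat leaving
    the volume as a termination signal.
    """
    c, inside = interpolate_many(field, np.asarray(p, dtype=float)[None, :])
    if not inside[0]:
        return None
    return c[0]
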