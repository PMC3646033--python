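"""File I/O: NIfTI volumes, FSL bval/bvec text, TrackVis TRK streamlines,
JSON-lines debug streamlines and provenance records.

Only axis-aligned isotropic NIfTI geometry is supported; oblique or
sheared affines are rejected with a clear message rather than silently
resampled.  World coordinates are voxel-center based, 0-indexed, in mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import Grid
from .phantom import DWIVolume, GradientScheme
from .tensor import TensorField
from .tracking import StreamlineBundle

__version__ = "0.1.0"


def _grid_from_affine(affine, shape) -> Grid:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if not np.allclose(off_diag, 0, atol=1e-6):
        raise ValueError("unsupported geometry: oblique/sheared affine; "
                         "only axis-aligned volumes are handled")
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise ValueError("unsupported geometry: negative/zero axis scaling")
    if not np.allclose(diag, diag[0], atol=1e-6):
        raise ValueError("unsupported geometry: anisotropic voxels")
    return Grid(tuple(shape[:3]), float(diag[0]), affine[:3, 3].copy())


def read_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = _grid_from_affine(img.affine, data.shape)
    return data, grid


def write_volume(data, grid: Grid, path, dtype=None) -> None:
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms((grid.voxel_size,) * 3 + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def read_mask(path):
    data, grid = read_volume(path)
    return (data > 0).astype(np.uint8), grid


def write_tensor_field(field: TensorField, path) -> None:
    """4D NIfTI with 6 components in lower-triangular order."""
    write_volume(field.coeffs, field.grid, path, dtype=np.float32)


def read_tensor_field(path) -> TensorField:
    data, grid = read_volume(path)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError("tensor volume must be 4D with 6 components")
    return TensorField(np.asarray(data, dtype=float), grid)


# --------------------------------------------------------------------------
# gradients

def write_gradients(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10f")  # FSL layout: 3 rows


def read_gradients(bval_path, bvec_path) -> GradientScheme:
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvals.shape[0] != bvecs.shape[0]:
        raise ValueError(
            f"bval/bvec length mismatch: {bvals.shape[0]} vs {bvecs.shape[0]}")
    return GradientScheme(bvals, bvecs)


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    data, grid = read_volume(nifti_path)
    scheme = read_gradients(bval_path, bvec_path)
    if data.ndim != 4 or data.shape[-1] != scheme.n_entries:
        raise ValueError("DWI 4th dimension does not match gradient scheme")
    return DWIVolume(np.asarray(data, dtype=float), scheme, grid.voxel_size, grid.origin)


# --------------------------------------------------------------------------
# streamlines

def write_streamlines_trk(bundle: StreamlineBundle, grid: Grid, path) -> None:
    """TrackVis TRK with header populated from the reference grid."""
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in bundle],
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "voxel_sizes": (grid.voxel_size,) * 3,
        "dimensions": grid.shape,
        "voxel_to_rasmm": grid.affine.astype(np.float32),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(nib.streamlines.TrkFile(tractogram, header), str(path))


def read_streamlines_trk(path) -> StreamlineBundle:
    trk = nib.streamlines.load(str(path))
    return StreamlineBundle([np.asarray(s, dtype=float) for s in trk.streamlines])


def write_streamlines_jsonl(bundle: StreamlineBundle, path) -> None:
    with open(path, "w") as fh:
        for s in bundle:
            fh.write(json.dumps(np.asarray(s).tolist()) + "\n")


def read_streamlines_jsonl(path) -> StreamlineBundle:
    lines = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                lines.append(np.asarray(json.loads(line), dtype=float))
    return StreamlineBundle(lines)


# --------------------------------------------------------------------------
# provenance

def write_provenance(out_dir, config: dict, seed: int | None = None) -> Path:
    """Record the full effective configuration next to every run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "retrack",
        "version": __version__,
        "rng_seed": seed,
        "coordinates": "world mm, voxel-center based, 0-indexed",
        "config": config,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
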