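"""Voxel grid geometry shared by all volumetric containers.

Conventions used throughout the package: voxel indices are 0-based,
world coordinates are in millimetres, and ``origin`` is the world
position of the *center* of voxel (0, 0, 0).  Voxels are isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Axis-aligned isotropic voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along x, y, z.
    voxel_size : float
        Isotropic voxel edge length in mm.
    origin : ndarray, shape (3,)
        World-mm position of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    def voxel_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.voxel_size

    def world_to_voxel(self, p) -> np.ndarray:
        """Continuous voxel coordinates of world point(s) ``p``."""
        return (np.asarray(p, dtype=float) - self.origin) / self.voxel_size

    def nearest_voxel(self, p) -> np.ndarray:
        """Integer index of the voxel whose center is nearest to ``p``."""
        return np.rint(self.world_to_voxel(p)).astype(np.int64)

    def contains_index(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=-1)

    def contains_world(self, p) -> np.ndarray:
        """True where ``p`` lies inside the voxel-center hull (interpolable region)."""
        v = self.world_to_voxel(p)
        hi = np.asarray(self.shape, dtype=float) - 1.0
        return np.all((v >= 0.0) & (v <= hi), axis=-1)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``shape + (3,)``."""
        ax = [self.origin[i] + self.voxel_size * np.arange(self.shape[i]) for i in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size
        a[:3, 3] = self.origin
        return a

    def same_as(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) <= tol
            and bool(np.allclose(self.origin, other.origin, atol=tol))
        )
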