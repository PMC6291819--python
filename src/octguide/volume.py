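"""Axis-aligned 3-D scalar volumes with a voxel-index -> world-mm mapping.

Conventions (used everywhere in the package):

* world frame is right-handed, units are millimetres;
* voxel indices are 0-based and ``index_to_world`` maps an index to the
  *centre* of that voxel;
* array axes are ``data[i, j, k]`` for world axes (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Volume3D"]


@dataclass
class Volume3D:
    """A scalar image volume plus its affine index-to-world map.

    Parameters
    ----------
    data : (nx, ny, nz) ndarray
        Scalar intensities.
    affine : (4, 4) ndarray
        Homogeneous affine mapping a 0-based voxel index (voxel-centre
        convention) to world mm. Must be invertible with positive spacing.
    modality : str
        ``"CBCT"`` or ``"OCT"``.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-15:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    # -- geometry ----------------------------------------------------------
    @classmethod
    def from_origin_spacing(
        cls, data, origin, spacing, modality: str = "unknown"
    ) -> "Volume3D":
        origin = np.asarray(origin, dtype=float)
        spacing = np.asarray(spacing, dtype=float) * np.ones(3)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = origin
        return cls(data, affine, modality)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size (mm), from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def index_to_world(self, idx) -> np.ndarray:
        """Map fractional voxel indices ``(..., 3)`` to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine[:3, :3])
        return (pts - self.affine[:3, 3]) @ inv.T

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinate of each voxel centre along a (diagonal) axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def contains_world(self, pts, margin_mm: float = 0.0) -> np.ndarray:
        """True where points lie inside the voxel-centre bounding box."""
        idx = self.world_to_index(pts)
        idx = np.atleast_2d(idx)
        lo = -0.5 - margin_mm / self.spacing
        hi = np.asarray(self.shape) - 0.5 + margin_mm / self.spacing
        ok = np.all((idx >= lo) & (idx <= hi), axis=1)
        return ok if ok.size > 1 else bool(ok[0])
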