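"""Rigid (rotation + translation) transforms between scanner frames.

The pipeline estimates one rigid map from the CBCT world frame (mm) to the
laser/OCT device frame (mm). Rotations are proper (det = +1); reflections are
never admitted, since a navigation system mapping a physical skull cannot
mirror it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> R @ p + t`` in world millimetres.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal matrix with determinant +1.
    translation : (3,) ndarray
        Translation in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        # re-orthonormalize via SVD so composed transforms stay clean
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from an axis-angle rotation vector (radians) and translation."""
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, mat4) -> "RigidTransform":
        mat4 = np.asarray(mat4, dtype=float).reshape(4, 4)
        return cls(mat4[:3, :3], mat4[:3, 3])

    # -- algebra -----------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        """Map one point ``(3,)`` or a stack ``(n, 3)`` through the transform."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    # -- serialization -----------------------------------------------------
    def to_matrix(self) -> np.ndarray:
        mat = np.eye(4)
        mat[:3, :3] = self.rotation
        mat[:3, 3] = self.translation
        return mat

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.reshape(-1).tolist(),  # row-major 3x3
            "translation_mm": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation_mm"], dtype=float),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save_matrix_txt(self, path) -> None:
        """Write the 4x4 homogeneous matrix as plain text."""
        np.savetxt(path, self.to_matrix(), fmt="%.12g")

    @classmethod
    def load_matrix_txt(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )
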