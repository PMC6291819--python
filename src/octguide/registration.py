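"""Rigid point-set registration and its error measures (FRE, TRE).

The transform from the CBCT frame to the laser/OCT frame is estimated from
matched fiducial centres by the closed-form least-squares fit: centroid
alignment followed by SVD of the cross-covariance with a determinant-sign
correction that excludes reflections (Kabsch/Umeyama). The closed form is
deterministic — no initialization, no iteration, no seed.

FRE (fiducial registration error) is the RMS residual over the fiducials
used in the fit; the plain mean is also reported since "mean error" in the
clinical literature is often left undefined. TRE (target registration
error) is the displacement a given transform error induces at a target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfigurationError, InsufficientFiducialsError
from .transforms import RigidTransform

__all__ = ["RegistrationResult", "fit_rigid", "target_registration_error"]

_COLLINEAR_TOL = 1e-8


@dataclass
class RegistrationResult:
    """Estimated transform plus fiducial-residual bookkeeping."""

    transform: RigidTransform
    fre_mm: float
    mean_residual_mm: float
    per_fiducial_residuals_mm: np.ndarray
    n_fiducials: int

    def __post_init__(self):
        self.per_fiducial_residuals_mm = np.asarray(
            self.per_fiducial_residuals_mm, float
        ).reshape(-1)
        assert abs(self.fre_mm**2 - np.mean(self.per_fiducial_residuals_mm**2)) < 1e-12

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "fre_mm": self.fre_mm,
            "mean_residual_mm": self.mean_residual_mm,
            "per_fiducial_residuals_mm": self.per_fiducial_residuals_mm.tolist(),
            "n_fiducials": self.n_fiducials,
        }


def fit_rigid(moving, fixed) -> RegistrationResult:
    """Closed-form least-squares rigid fit mapping ``moving`` onto ``fixed``.

    Parameters
    ----------
    moving, fixed : (n, 3) array-like
        Matched point pairs in mm, n >= 3, moving points non-collinear.

    Returns
    -------
    RegistrationResult
        With ``transform`` minimizing ``sum ||R m_i + t - f_i||^2`` over
        proper rigid motions.
    """
    m = np.atleast_2d(np.asarray(moving, float))
    f = np.atleast_2d(np.asarray(fixed, float))
    if m.shape != f.shape or m.shape[1] != 3:
        raise ValueError("moving and fixed must be matched (n, 3) arrays")
    n = len(m)
    if n < 3:
        raise InsufficientFiducialsError(f"rigid fit needs >= 3 pairs, got {n}")
    mc, fc = m.mean(axis=0), f.mean(axis=0)
    m0, f0 = m - mc, f - fc
    s = np.linalg.svd(m0, compute_uv=False)
    if s[1] <= _COLLINEAR_TOL * max(s[0], 1.0):
        raise DegenerateConfigurationError(
            "moving points are collinear; rotation about their axis is unconstrained"
        )
    H = m0.T @ f0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    transform = RigidTransform(R, t)
    resid = np.linalg.norm(transform.apply(m) - f, axis=1)
    return RegistrationResult(
        transform=transform,
        fre_mm=float(np.sqrt(np.mean(resid**2))),
        mean_residual_mm=float(np.mean(resid)),
        per_fiducial_residuals_mm=resid,
        n_fiducials=n,
    )


def target_registration_error(
    est: RigidTransform, true: RigidTransform, targets
) -> np.ndarray:
    """Per-target Euclidean distance between ``est(p)`` and ``true(p)`` in mm."""
    t = np.atleast_2d(np.asarray(targets, float))
    if t.size == 0:
        raise ValueError("targets must be non-empty")
    return np.linalg.norm(est.apply(t) - true.apply(t), axis=1)
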