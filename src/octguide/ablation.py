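"""Laser-frame target transfer, workspace/incidence checks and ablation model.

The Er:YAG marking laser addresses a 10x10x10 mm workspace cube (shared with
the OCT field); the head is tilted so the bone surface meets the beam at
45-90 degrees. Ablation is modeled empirically as a fixed crater depth per
cycle (0.3 mm at default calibration) rather than pulse-energy physics, and
path timing follows the constant 4 mm/s focus-spot speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import RigidTransform

__all__ = [
    "LaserConfig",
    "AblationResult",
    "transfer_targets",
    "check_constraints",
    "simulate_ablation",
    "FLAG_OK",
    "FLAG_OUT_OF_WORKSPACE",
    "FLAG_BAD_INCIDENCE",
]

FLAG_OK = "ok"
FLAG_OUT_OF_WORKSPACE = "out_of_workspace"
FLAG_BAD_INCIDENCE = "bad_incidence"


@dataclass(frozen=True)
class LaserConfig:
    """Device parameters of the combined OCT / Er:YAG laser head."""

    workspace_side_mm: float = 10.0
    working_distance_mm: float = 60.0  # extendable to 100.0
    depth_per_cycle_mm: float = 0.3
    focus_speed_mm_s: float = 4.0
    incidence_range_deg: tuple = (45.0, 90.0)
    power_W: float = 15.0
    pulse_hz: float = 500.0
    pulse_us: tuple = (50.0, 200.0)
    execution_noise_sd_mm: float = 0.0  # beam-pointing jitter; 0 = perfect

    def __post_init__(self):
        for name in (
            "workspace_side_mm",
            "working_distance_mm",
            "depth_per_cycle_mm",
            "focus_speed_mm_s",
            "power_W",
            "pulse_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.incidence_range_deg
        if not (0.0 < lo <= hi <= 90.0):
            raise ValueError("incidence_range_deg must lie within (0, 90]")


@dataclass
class AblationResult:
    """Achieved crater positions (laser frame), depths and path timing."""

    marks_mm: np.ndarray  # (n, 3)
    depths_mm: np.ndarray  # (n,)
    valid_flags: list
    path_time_s: float

    def __post_init__(self):
        self.marks_mm = np.atleast_2d(np.asarray(self.marks_mm, float))
        self.depths_mm = np.asarray(self.depths_mm, float).reshape(-1)

    def to_dict(self) -> dict:
        return {
            "marks_mm": self.marks_mm.tolist(),
            "depths_mm": self.depths_mm.tolist(),
            "valid_flags": list(self.valid_flags),
            "path_time_s": self.path_time_s,
        }


def transfer_targets(plan_points, transform: RigidTransform) -> np.ndarray:
    """Map planned target points into the laser frame; order is preserved."""
    pts = np.atleast_2d(np.asarray(getattr(plan_points, "points_mm", plan_points), float))
    return transform.apply(pts)


def check_constraints(points, normals, cfg: LaserConfig, beam_dir=(0.0, 0.0, -1.0)):
    """Flag each point against workspace and incidence-angle constraints.

    ``out_of_workspace``: any coordinate outside the cube of side
    ``workspace_side_mm`` centred on the device-frame origin.
    ``bad_incidence``: the angle between the surface *plane* and the beam
    falls outside ``incidence_range_deg`` (45-90 deg by default, i.e. the
    surface normal within 45 deg of the incoming beam).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    nrm = np.atleast_2d(np.asarray(normals, float))
    if len(pts) != len(nrm):
        raise ValueError("points and normals must be aligned")
    b = np.asarray(beam_dir, float)
    b = b / np.linalg.norm(b)
    half = cfg.workspace_side_mm / 2.0
    lo, hi = cfg.incidence_range_deg

    flags = []
    for p, n in zip(pts, nrm):
        if np.any(np.abs(p) > half):
            flags.append(FLAG_OUT_OF_WORKSPACE)
            continue
        n = n / np.linalg.norm(n)
        # grazing angle between the surface plane and the beam direction
        grazing = np.degrees(np.arcsin(np.clip(abs(n @ b), 0.0, 1.0)))
        if grazing < lo - 1e-9 or grazing > hi + 1e-9:
            flags.append(FLAG_BAD_INCIDENCE)
        else:
            flags.append(FLAG_OK)
    return flags


def simulate_ablation(
    points,
    flags,
    cfg: LaserConfig,
    n_cycles: int = 1,
    rng: np.random.Generator | None = None,
) -> AblationResult:
    """Execute the marking pass over all ok-flagged targets.

    Each executed mark receives ``n_cycles * depth_per_cycle_mm`` of crater
    depth and an isotropic Gaussian execution-noise offset of
    ``cfg.execution_noise_sd_mm`` (default 0). Skipped points keep depth 0
    and their planned position. Path time is the polyline length through the
    executed marks divided by the focus-spot speed.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if len(flags) != len(pts):
        raise ValueError("flags and points must be aligned")
    ok = np.asarray([f == FLAG_OK for f in flags])
    marks = pts.copy()
    if cfg.execution_noise_sd_mm > 0 and ok.any():
        if rng is None:
            rng = np.random.default_rng()
        marks[ok] += rng.normal(0.0, cfg.execution_noise_sd_mm, (int(ok.sum()), 3))
    depths = np.where(ok, n_cycles * cfg.depth_per_cycle_mm, 0.0)
    ok_marks = marks[ok]
    if len(ok_marks) >= 2:
        length = float(np.linalg.norm(np.diff(ok_marks, axis=0), axis=1).sum())
    else:
        length = 0.0
    return AblationResult(
        marks_mm=marks,
        depths_mm=depths,
        valid_flags=list(flags),
        path_time_s=length / cfg.focus_speed_mm_s,
    )
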