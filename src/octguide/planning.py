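"""Canal segmentation and placement of the V-shaped surface target plan.

The buried canal is segmented by band thresholding (the canal interior is
soft-tissue intensity inside bone), keeping the largest connected component
and closing small gaps. Targets are then placed "directly above the canal
edge in the surgeon's line of sight": the canal mask is projected along the
view direction, the silhouette boundary is extracted at sub-pixel precision,
the rounded end caps of the tube silhouette are trimmed away, and the two
remaining boundary arms are lifted back onto the bone surface along the view
ray and resampled at fixed arc-length spacing. For a bent (V-shaped) canal
the resulting path runs arm -> medial apex -> arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.morphology import medial_axis

from .errors import PlanningError, SegmentationError
from .phantom import HeightField
from .volume import Volume3D

__all__ = [
    "SegmentationMask",
    "TargetPlan",
    "segment_canal",
    "place_targets",
    "project_mask_silhouette",
]

DEFAULT_BAND = (30.0, 120.0)  # between air (0) and bone (200): canal interior


@dataclass
class SegmentationMask:
    """Boolean mask aligned to a source volume grid."""

    mask: np.ndarray
    affine: np.ndarray
    structure: str = "IAC"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        self.affine = np.asarray(self.affine, float).reshape(4, 4)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_points(self) -> np.ndarray:
        idx = np.argwhere(self.mask).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class TargetPlan:
    """Ordered surface targets outlining the canal edge, with normals."""

    points_mm: np.ndarray  # (n, 3), ordered along the mark path
    normals: np.ndarray  # (n, 3) outward unit surface normals
    view_dir: np.ndarray  # unit vector, viewer -> scene
    arm_ids: np.ndarray  # (n,) which silhouette arm each point belongs to
    label: str = "IAC-edge-V"

    def __post_init__(self):
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm, float))
        self.normals = np.atleast_2d(np.asarray(self.normals, float))
        self.view_dir = np.asarray(self.view_dir, float)
        self.arm_ids = np.asarray(self.arm_ids, int)
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.points_mm)

    def to_records(self):
        return [
            {
                "label": f"{self.label}:{i:03d}",
                "arm": int(a),
                "x": float(p[0]),
                "y": float(p[1]),
                "z": float(p[2]),
                "nx": float(n[0]),
                "ny": float(n[1]),
                "nz": float(n[2]),
            }
            for i, (p, n, a) in enumerate(zip(self.points_mm, self.normals, self.arm_ids))
        ]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------
def segment_canal(
    vol: Volume3D, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1]
) -> SegmentationMask:
    """Band-threshold segmentation of the canal in a CBCT volume.

    Keeps the largest connected component in the ``[low, high]`` intensity
    band and applies a one-voxel morphological closing.
    """
    if vol.modality != "CBCT":
        raise ValueError(f"expected a CBCT volume, got modality={vol.modality!r}")
    band = (vol.data >= low) & (vol.data <= high)
    labels, ncomp = ndimage.label(band)
    if ncomp == 0:
        raise SegmentationError(f"no voxels in intensity band [{low}, {high}]")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, ncomp + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    mask = ndimage.binary_closing(mask, structure=ndimage.generate_binary_structure(3, 1))
    if not mask.any():
        raise SegmentationError("segmentation produced an empty mask")
    return SegmentationMask(mask=mask, affine=vol.affine, structure="IAC")


# ---------------------------------------------------------------------------
# silhouette projection and target placement
# ---------------------------------------------------------------------------
def project_mask_silhouette(seg: SegmentationMask, view_dir: np.ndarray):
    """Project mask voxels along ``view_dir`` onto the z=0 lateral grid.

    Returns ``(silhouette, origin_xy, spacing_xy)`` where silhouette is a 2-D
    boolean image on the source volume's lateral grid.
    """
    v = np.asarray(view_dir, float)
    v = v / np.linalg.norm(v)
    if abs(v[2]) < 1e-6:
        raise PlanningError("view direction is parallel to the surface plane")
    pts = seg.world_points()
    if pts.size == 0:
        raise PlanningError("empty segmentation: nothing to project")
    # slide each voxel centre along the view ray to the z = 0 plane
    t = -pts[:, 2] / v[2]
    lat = pts[:, :2] + t[:, None] * v[:2]

    origin_xy = seg.affine[:3, 3][:2]
    spacing_xy = seg.spacing[:2]
    nx, ny = seg.mask.shape[:2]
    ij = np.round((lat - origin_xy) / spacing_xy).astype(int)
    keep = (ij[:, 0] >= 0) & (ij[:, 0] < nx) & (ij[:, 1] >= 0) & (ij[:, 1] < ny)
    if not keep.any():
        raise PlanningError("canal projects entirely outside the volume footprint")
    sil = np.zeros((nx, ny), dtype=bool)
    sil[ij[keep, 0], ij[keep, 1]] = True
    sil = ndimage.binary_closing(sil, structure=np.ones((3, 3), bool))
    return sil, origin_xy, spacing_xy


def _skeleton_endpoints(skel: np.ndarray) -> np.ndarray:
    """Pixels of a 2-D skeleton with exactly one 8-connected neighbour."""
    nb = ndimage.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant")
    return np.argwhere(skel & (nb == 2))


def _resample_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    if s[-1] < spacing:
        return pts[[0, -1]] if len(pts) > 1 else pts
    n = max(2, int(np.floor(s[-1] / spacing)) + 1)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, k]) for k in range(pts.shape[1])])


def _lift_to_surface(lat: np.ndarray, surface: HeightField, v: np.ndarray) -> np.ndarray:
    """Intersect view rays through lateral points (at z=0) with the surface."""
    if abs(v[0]) < 1e-12 and abs(v[1]) < 1e-12:
        z = surface.height(lat[:, 0], lat[:, 1])
        return np.column_stack([lat, z])
    # bisection on f(t) = z(t) - h(x(t), y(t)); bracket generously in t
    t_lo = np.full(len(lat), -50.0)
    t_hi = np.full(len(lat), 50.0)

    def f(t):
        p = lat[:, 0] + t * v[0], lat[:, 1] + t * v[1], 0.0 + t * v[2]
        return p[2] - surface.height(p[0], p[1])

    flo, fhi = f(t_lo), f(t_hi)
    if np.any(np.sign(flo) == np.sign(fhi)):
        raise PlanningError("view ray does not intersect the bone surface")
    for _ in range(60):
        tm = 0.5 * (t_lo + t_hi)
        fm = f(tm)
        swap = np.sign(fm) == np.sign(flo)
        t_lo = np.where(swap, tm, t_lo)
        flo = np.where(swap, fm, flo)
        t_hi = np.where(swap, t_hi, tm)
    t = 0.5 * (t_lo + t_hi)
    return np.column_stack(
        [lat[:, 0] + t * v[0], lat[:, 1] + t * v[1], t * v[2]]
    )


def place_targets(
    seg: SegmentationMask,
    surface: HeightField,
    view_dir=(0.0, 0.0, -1.0),
    spacing_mm: float = 0.5,
) -> TargetPlan:
    """Place ordered targets on the bone surface above the canal silhouette edge.

    The silhouette boundary is traced at sub-pixel precision, the tube's end
    caps are trimmed (within the local tube half-width of each skeleton
    endpoint), and the remaining boundary arms are lifted to the surface
    along the view direction and resampled at ``spacing_mm``. Arms are
    ordered to meet at the silhouette's bend apex when the canal is bent.
    """
    v = np.asarray(view_dir, float)
    v = v / np.linalg.norm(v)
    # the surgeon looks down onto the surface: require the view within 60
    # degrees of the (anti-parallel) mean surface normal
    pts_all = seg.world_points()
    n_mean = surface.normal(pts_all[:, 0].mean(), pts_all[:, 1].mean())
    if float(-v @ n_mean) < np.cos(np.radians(60.0)):
        raise PlanningError("view direction deviates more than 60 deg from the surface normal")

    sil, origin_xy, spacing_xy = project_mask_silhouette(seg, v)
    contours = find_contours(sil.astype(float), 0.5)
    if not contours:
        raise PlanningError("silhouette has no boundary")
    contour = max(contours, key=len)  # (m, 2) fractional (ix, iy)
    cw = contour * spacing_xy + origin_xy  # world lateral coords

    skel, dist = medial_axis(sil, return_distance=True)
    endpoints = _skeleton_endpoints(skel)
    px = float(np.mean(spacing_xy))

    # trim the rounded end caps: contour points within the local half-width
    # (+ a one-pixel guard) of a skeleton endpoint belong to a cap
    keep = np.ones(len(cw), bool)
    for ep in endpoints:
        ep_w = ep * spacing_xy + origin_xy
        r_cap = (dist[tuple(ep)] + 1.5) * px
        keep &= np.linalg.norm(cw - ep_w, axis=1) > r_cap

    if not keep.any():
        raise PlanningError("silhouette too small: everything trimmed as end caps")

    # split the (cyclic) contour into kept runs -> the silhouette arms
    runs = _cyclic_runs(keep)
    arms = [cw[idx] for idx in runs]
    arms = [a for a in arms if len(a) >= 2]
    if not arms:
        raise PlanningError("no silhouette arms left after cap trimming")

    # bend apex: skeleton point farthest from the endpoint-to-endpoint chord
    apex_w = None
    if len(endpoints) >= 2:
        sk_pts = np.argwhere(skel) * spacing_xy + origin_xy
        a_w = endpoints[0] * spacing_xy + origin_xy
        b_w = endpoints[-1] * spacing_xy + origin_xy
        chord = b_w - a_w
        nrm = np.linalg.norm(chord)
        if nrm > 1e-9:
            d = np.abs(np.cross(np.r_[chord, 0.0], np.c_[sk_pts - a_w, np.zeros(len(sk_pts))])[:, 2]) / nrm
            if d.max() > 1.5 * px:  # genuinely bent canal
                apex_w = sk_pts[int(np.argmax(d))]

    # order each arm to END nearest the apex, then reverse alternate arms so
    # the concatenated path runs arm1 -> apex -> arm2
    ordered, arm_ids = [], []
    for ai, arm in enumerate(arms):
        if apex_w is not None:
            d0 = np.linalg.norm(arm[0, :] - apex_w)
            d1 = np.linalg.norm(arm[-1, :] - apex_w)
            if (ai == 0 and d0 > d1) or (ai > 0 and d0 < d1):
                pass
            else:
                arm = arm[::-1]
        rs = _resample_polyline(arm, spacing_mm)
        ordered.append(rs)
        arm_ids.append(np.full(len(rs), ai))
    lat = np.vstack(ordered)
    arm_ids = np.concatenate(arm_ids)

    pts3 = _lift_to_surface(lat, surface, v)
    normals = surface.normal(pts3[:, 0], pts3[:, 1])
    return TargetPlan(
        points_mm=pts3, normals=normals, view_dir=v, arm_ids=arm_ids, label="IAC-edge-V"
    )


def _cyclic_runs(keep: np.ndarray):
    """Contiguous index runs of True in a cyclic boolean array."""
    n = len(keep)
    if keep.all():
        return [np.arange(n)]
    # rotate so position 0 is False, then take plain runs
    start = int(np.argmin(keep))
    rot = np.roll(keep, -start)
    runs, cur = [], []
    for i, k in enumerate(rot):
        if k:
            cur.append((i + start) % n)
        elif cur:
            runs.append(np.asarray(cur))
            cur = []
    if cur:
        runs.append(np.asarray(cur))
    return runs
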