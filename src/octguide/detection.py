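"""Fiducial sphere localization in CBCT and OCT volumes.

CBCT: the titanium level is isolated by Otsu thresholding of the upper
intensity tail, connected components are filtered by equivalent-sphere
diameter, and each sphere centre is the intensity-weighted centroid — the
partial-volume rendering makes this estimator sub-voxel accurate for
symmetric spheres.

OCT: only the upper spherical cap of each titanium sphere reflects, so the
bright cap surface is extracted per A-scan column and a sphere of *known*
physical radius is least-squares fitted to the partial cap (the visible cap
alone constrains a free radius poorly). A free-radius fit is available for
diagnostics.

Correspondence between the two sets is exact: exhaustive search over
injective assignments minimizing the discrepancy between inter-point
distance matrices. Symmetric configurations that admit two labelings are an
error, never a guess.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .errors import AmbiguousMatchError, InsufficientFiducialsError
from .volume import Volume3D

__all__ = [
    "FiducialSet",
    "Correspondence",
    "detect_spheres_cbct",
    "detect_spheres_oct",
    "match_fiducials",
    "fit_sphere_known_radius",
    "fit_sphere_free",
]

MAX_FIDUCIALS = 6  # keeps exhaustive correspondence exact


@dataclass
class FiducialSet:
    """Labelled sub-voxel sphere-centre estimates in one scanner frame."""

    centers_mm: np.ndarray  # (n, 3)
    radii_mm: np.ndarray  # (n,)
    quality: np.ndarray  # (n,) in [0, 1]
    frame: str  # "CBCT" | "OCT"

    def __post_init__(self):
        self.centers_mm = np.atleast_2d(np.asarray(self.centers_mm, float))
        self.radii_mm = np.asarray(self.radii_mm, float).reshape(-1)
        self.quality = np.asarray(self.quality, float).reshape(-1)
        if not (len(self.centers_mm) == len(self.radii_mm) == len(self.quality)):
            raise ValueError("centers, radii and quality must have equal length")

    def __len__(self) -> int:
        return len(self.centers_mm)

    def to_records(self):
        return [
            {
                "label": i,
                "x_mm": float(c[0]),
                "y_mm": float(c[1]),
                "z_mm": float(c[2]),
                "r_mm": float(r),
                "quality": float(q),
            }
            for i, (c, r, q) in enumerate(
                zip(self.centers_mm, self.radii_mm, self.quality)
            )
        ]


@dataclass
class Correspondence:
    """Injective pairing between two fiducial sets and its residual (mm)."""

    pairs: list
    residual: float

    def permutation(self, n_a: int) -> np.ndarray:
        """Index into set b for each of the first ``n_a`` points of set a."""
        perm = np.full(n_a, -1, dtype=int)
        for ia, ib in self.pairs:
            perm[ia] = ib
        return perm


# ---------------------------------------------------------------------------
# sphere fitting primitives
# ---------------------------------------------------------------------------
def fit_sphere_known_radius(points: np.ndarray, radius_mm: float):
    """Least-squares centre of a sphere of known radius through surface points.

    Minimizes ``sum (||p - c|| - r)^2`` with a robust (soft-L1) loss; the
    initial centre sits one radius below the cap apex.

    Returns ``(center, rms_residual)``.
    """
    p = np.atleast_2d(np.asarray(points, float))
    x0 = np.array([p[:, 0].mean(), p[:, 1].mean(), p[:, 2].max() - radius_mm])

    def resid(c):
        return np.linalg.norm(p - c, axis=1) - radius_mm

    sol = optimize.least_squares(resid, x0, loss="soft_l1", f_scale=0.05)
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return sol.x, rms


def fit_sphere_free(points: np.ndarray):
    """Free-radius sphere fit: algebraic (linear) estimate refined geometrically.

    Returns ``(center, radius, rms_residual)``.
    """
    p = np.atleast_2d(np.asarray(points, float))
    # algebraic: ||p||^2 = 2 c.p + (r^2 - ||c||^2)
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = (p**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def resid(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    out = optimize.least_squares(resid, np.append(c0, r0), loss="soft_l1", f_scale=0.05)
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return out.x[:3], float(out.x[3]), rms


# ---------------------------------------------------------------------------
# CBCT detection
# ---------------------------------------------------------------------------
def _titanium_threshold(data: np.ndarray) -> float:
    """Threshold isolating the titanium intensity level.

    Otsu on the upper intensity tail (foreground split first, then a second
    split within the foreground), floored at the midpoint between the bone
    level (foreground median) and the titanium peak (maximum after a 3^3
    boxcar, which suppresses single-voxel noise excursions). The floor
    matters because Otsu degenerates when one class — the handful of
    titanium voxels — is vastly smaller than the other.
    """
    t1 = threshold_otsu(data)
    upper = data[data > t1]
    if upper.size < 2 or np.ptp(upper) < 1e-12:
        raise InsufficientFiducialsError(
            "fewer than 3 fiducials found (no titanium-level intensities)"
        )
    med = float(np.median(upper))
    peak = float(ndimage.uniform_filter(data, size=3).max())
    if peak - med < 4.0 * float(np.std(upper)):
        raise InsufficientFiducialsError(
            "fewer than 3 fiducials found (no titanium-level intensities)"
        )
    return max(float(threshold_otsu(upper)), 0.5 * (med + peak))


def detect_spheres_cbct(
    vol: Volume3D, expected_diameter_mm: float, n_expected: int
) -> FiducialSet:
    """Locate titanium spheres in a CBCT volume at sub-voxel precision.

    Components whose equivalent-sphere diameter deviates from the expected
    diameter by more than 50% are discarded; surviving components are
    localized by the intensity-weighted centroid in world mm.
    """
    if vol.modality != "CBCT":
        raise ValueError(f"expected a CBCT volume, got modality={vol.modality!r}")
    data = np.asarray(vol.data, float)
    if np.ptp(data) < 1e-12:
        raise InsufficientFiducialsError("fewer than 3 fiducials found (uniform volume)")
    thr = _titanium_threshold(data)
    bw = data > thr
    labels, ncomp = ndimage.label(bw)
    voxvol = float(np.prod(vol.spacing))

    centers, radii, quality = [], [], []
    for lab in range(1, ncomp + 1):
        mask = labels == lab
        nvox = int(mask.sum())
        d_eq = (6.0 * nvox * voxvol / np.pi) ** (1.0 / 3.0)
        if abs(d_eq - expected_diameter_mm) > 0.5 * expected_diameter_mm:
            continue
        # weights over the component plus its 1-voxel shell (partial volumes)
        grown = ndimage.binary_dilation(mask)
        w = np.where(grown, np.clip(data - thr, 0.0, None), 0.0)
        idx = np.argwhere(grown).astype(float)
        wts = w[grown]
        centroid_idx = (idx * wts[:, None]).sum(axis=0) / wts.sum()
        centers.append(vol.index_to_world(centroid_idx))
        radii.append(d_eq / 2.0)
        quality.append(max(0.0, 1.0 - abs(d_eq - expected_diameter_mm) / expected_diameter_mm))

    if len(centers) < 3:
        raise InsufficientFiducialsError(
            f"fewer than 3 fiducials found ({len(centers)} detections)"
        )
    order = np.argsort(quality)[::-1]
    if len(centers) > n_expected:
        warnings.warn(
            f"{len(centers)} candidate fiducials found, keeping the "
            f"{n_expected} best by quality",
            stacklevel=2,
        )
        order = order[:n_expected]
    order = np.sort(order)  # preserve component order among the kept
    return FiducialSet(
        centers_mm=np.asarray(centers)[order],
        radii_mm=np.asarray(radii)[order],
        quality=np.asarray(quality)[order],
        frame="CBCT",
    )


# ---------------------------------------------------------------------------
# OCT detection
# ---------------------------------------------------------------------------
def detect_spheres_oct(
    vol: Volume3D,
    expected_diameter_mm: float,
    n_expected: int,
    min_cap_extent: float = 0.35,
    min_cap_points: int = 10,
    max_fit_rms_frac: float = 0.15,
) -> FiducialSet:
    """Locate titanium spheres in an OCT volume from their bright upper caps.

    The volume is first despeckled with a 3x3x3 boxcar (multiplicative
    speckle is uncorrelated voxel to voxel, so local compounding suppresses
    it without erasing the wide, thick cap band). Bright voxels are then
    clustered; per cluster the topmost bright voxel of each A-scan column
    gives a cap-surface point cloud, to which a sphere of known radius
    ``expected_diameter_mm / 2`` is fitted. Caps whose lateral extent
    subtends too small a fraction of the radius, or whose fit residual
    exceeds ``max_fit_rms_frac`` of the radius, are dropped (unstable fit).
    """
    if vol.modality != "OCT":
        raise ValueError(f"expected an OCT volume, got modality={vol.modality!r}")
    data = ndimage.uniform_filter(np.asarray(vol.data, float), size=3)
    pos = data[data > 1e-6]
    if pos.size < 2:
        raise InsufficientFiducialsError("fewer than 3 fiducials found (empty volume)")
    thr = float(threshold_otsu(pos))
    bw = data > thr
    labels, ncomp = ndimage.label(bw)
    r = expected_diameter_mm / 2.0

    # a real cap covers ~pi r^2 worth of A-scan columns; require a fraction
    # of that so isolated speckle clusters are skipped cheaply
    expected_cols = np.pi * r**2 / float(vol.spacing[0] * vol.spacing[1])
    min_size = max(min_cap_points, int(0.05 * expected_cols))
    sizes = ndimage.sum_labels(
        np.ones_like(labels, dtype=np.int32), labels, np.arange(1, ncomp + 1)
    )
    candidates = np.where(sizes >= min_size)[0] + 1
    objects = ndimage.find_objects(labels)

    centers, radii, quality = [], [], []
    for lab in candidates:
        sl = objects[lab - 1]
        ii, jj, kk = np.where(labels[sl] == lab)
        ii = ii + sl[0].start
        jj = jj + sl[1].start
        kk = kk + sl[2].start
        # topmost bright voxel per lateral column -> cap surface
        flat = ii * data.shape[1] + jj
        order = np.lexsort((kk, flat))
        flat, kk_s = flat[order], kk[order]
        last = np.r_[np.diff(flat) != 0, True]
        top_flat, top_k = flat[last], kk_s[last]
        pts_idx = np.column_stack([top_flat // data.shape[1], top_flat % data.shape[1], top_k])
        pts = vol.index_to_world(pts_idx.astype(float))
        # a cap covers a known fraction of A-scan columns and is never wider
        # than the sphere: gate on column count and lateral extent before
        # spending a fit on speckle fragments or bone-surface patches
        if len(pts) < max(min_cap_points, 0.2 * expected_cols):
            warnings.warn(
                f"cluster {lab}: cap too small for a stable sphere fit, dropped",
                stacklevel=2,
            )
            continue
        lat_extent = np.max(
            np.linalg.norm(pts[:, :2] - pts[:, :2].mean(axis=0), axis=1)
        )
        if lat_extent < min_cap_extent * r or lat_extent > 1.5 * r:
            warnings.warn(
                f"cluster {lab}: lateral extent {lat_extent:.2f} mm not cap-like, dropped",
                stacklevel=2,
            )
            continue
        c, rms = fit_sphere_known_radius(pts, r)
        if rms > max_fit_rms_frac * r:
            warnings.warn(
                f"cluster {lab}: sphere fit residual {rms:.3f} mm too large, dropped",
                stacklevel=2,
            )
            continue
        centers.append(c)
        radii.append(r)
        quality.append(max(0.0, 1.0 - rms / r))

    # deduplicate: two candidates within one radius describe the same sphere
    if centers:
        keep_idx = []
        for i in np.argsort(quality)[::-1]:
            if all(
                np.linalg.norm(np.asarray(centers[i]) - np.asarray(centers[j])) > r
                for j in keep_idx
            ):
                keep_idx.append(i)
        keep_idx = sorted(keep_idx)
        centers = [centers[i] for i in keep_idx]
        radii = [radii[i] for i in keep_idx]
        quality = [quality[i] for i in keep_idx]

    if len(centers) < 3:
        raise InsufficientFiducialsError(
            f"fewer than 3 fiducials found ({len(centers)} stable caps)"
        )
    order = np.argsort(quality)[::-1]
    if len(centers) > n_expected:
        warnings.warn(
            f"{len(centers)} candidate caps found, keeping the {n_expected} best",
            stacklevel=2,
        )
        order = order[:n_expected]
    order = np.sort(order)
    return FiducialSet(
        centers_mm=np.asarray(centers)[order],
        radii_mm=np.asarray(radii)[order],
        quality=np.asarray(quality)[order],
        frame="OCT",
    )


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------
def _distance_matrix(pts: np.ndarray) -> np.ndarray:
    d = pts[:, None, :] - pts[None, :, :]
    return np.linalg.norm(d, axis=-1)


def match_fiducials(
    a: FiducialSet, b: FiducialSet, ambiguity_tol: float = 1e-6
) -> Correspondence:
    """Exhaustive injective matching by inter-point distance patterns.

    Minimizes the sum of squared differences between corresponding entries of
    the two distance matrices over all injective assignments (point counts
    capped at 6 so the search stays exact). Two assignments within
    ``ambiguity_tol`` (mm^2) of each other raise :class:`AmbiguousMatchError`.
    """
    pa, pb = a.centers_mm, b.centers_mm
    na, nb = len(pa), len(pb)
    if na < 3 or nb < 3:
        raise InsufficientFiducialsError("matching requires at least 3 points per set")
    if max(na, nb) > MAX_FIDUCIALS:
        raise ValueError(f"at most {MAX_FIDUCIALS} fiducials supported")
    swapped = na > nb
    if swapped:
        pa, pb, na, nb = pb, pa, nb, na
    Da, Db = _distance_matrix(pa), _distance_matrix(pb)
    iu = np.triu_indices(na, k=1)

    best_cost, second_cost, best_perm = np.inf, np.inf, None
    for perm in itertools.permutations(range(nb), na):
        perm = np.asarray(perm)
        diff = Da[iu] - Db[perm[iu[0]], perm[iu[1]]]
        cost = float(diff @ diff)
        if cost < best_cost:
            second_cost, best_cost, best_perm = best_cost, cost, perm
        elif cost < second_cost:
            second_cost = cost
    if second_cost - best_cost < ambiguity_tol:
        raise AmbiguousMatchError(
            "two labelings explain the fiducial distance pattern equally well "
            f"(cost gap {second_cost - best_cost:.2e} mm^2)"
        )
    n_pairs_dist = len(iu[0])
    residual = float(np.sqrt(best_cost / n_pairs_dist))
    if swapped:
        pairs = [(int(bi), int(ai)) for ai, bi in enumerate(best_perm)]
        pairs.sort()
    else:
        pairs = [(int(ai), int(bi)) for ai, bi in enumerate(best_perm)]
    return Correspondence(pairs=pairs, residual=residual)
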