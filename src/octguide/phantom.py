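"""Synthetic paired CBCT / OCT phantoms with exact ground truth.

The phantom stands in for the cadaver temporal bone and the two scanners:

* a CBCT volume (0.3 mm isotropic voxels) containing a bone slab bounded
  above by a smooth height-field surface, a buried V-shaped canal (internal
  auditory canal surrogate) and four 1 mm titanium fiducial spheres resting
  on the bone surface in a non-collinear zig-zag, 1-2 mm apart;
* an OCT volume covering the 10x10x10 mm laser workspace, with fine axial
  sampling, exponential attenuation limited to ~1 mm penetration into bone,
  multiplicative speckle, and fiducials visible only as their upper
  spherical caps (infrared light does not penetrate titanium) with a shadow
  beneath;
* the hidden rigid transform between the two frames, known exactly.

Fiducial spheres are rendered into CBCT by supersampled partial-volume
occupancy so that sub-voxel localization is meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FieldOfViewError, PhantomConfigError
from .transforms import RigidTransform
from .volume import Volume3D

__all__ = [
    "HeightField",
    "CanalSpec",
    "NoiseSpec",
    "IntensityModel",
    "OctRenderParams",
    "PhantomSpec",
    "GroundTruth",
    "make_cbct_phantom",
    "make_oct_volume",
    "render_cbct_volume",
    "default_true_transform",
]


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class HeightField:
    """Smooth bone surface ``z = h(x, y)`` with analytic normals.

    ``coeffs`` are the polynomial coefficients ``(1, x, y, x^2, x*y, y^2)``;
    an optional Gaussian bump can be superposed.
    """

    coeffs: tuple = (2.0, 0.04, -0.06, -0.010, 0.0, -0.008)
    bump_amp: float = 0.0
    bump_center: tuple = (0.0, 0.0)
    bump_sigma: float = 2.0

    def height(self, x, y):
        c = self.coeffs
        h = c[0] + c[1] * x + c[2] * y + c[3] * x**2 + c[4] * x * y + c[5] * y**2
        if self.bump_amp != 0.0:
            bx, by = self.bump_center
            h = h + self.bump_amp * np.exp(
                -((x - bx) ** 2 + (y - by) ** 2) / (2 * self.bump_sigma**2)
            )
        return h

    def gradient(self, x, y):
        c = self.coeffs
        gx = c[1] + 2 * c[3] * x + c[4] * y
        gy = c[2] + c[4] * x + 2 * c[5] * y
        if self.bump_amp != 0.0:
            bx, by = self.bump_center
            g = self.bump_amp * np.exp(
                -((x - bx) ** 2 + (y - by) ** 2) / (2 * self.bump_sigma**2)
            )
            gx = gx - g * (x - bx) / self.bump_sigma**2
            gy = gy - g * (y - by) / self.bump_sigma**2
        return gx, gy

    def normal(self, x, y):
        """Outward (upward) unit surface normal(s), shape ``(..., 3)``."""
        gx, gy = self.gradient(x, y)
        n = np.stack(np.broadcast_arrays(-gx, -gy, np.ones_like(gx + gy)), axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


@dataclass(frozen=True)
class CanalSpec:
    """Buried tube: lateral axis polyline at fixed depth below the surface.

    The default axis is a V whose apex points medially (+y), emulating the
    converging outline of the internal auditory canal.
    """

    axis_xy: tuple = ((-3.5, -2.0), (0.0, 1.5), (3.5, -2.0))
    radius_mm: float = 0.8
    depth_mm: float = 2.5  # axis depth below the bone surface

    def axis_points(self, surface: HeightField) -> np.ndarray:
        xy = np.asarray(self.axis_xy, dtype=float)
        z = surface.height(xy[:, 0], xy[:, 1]) - self.depth_mm
        return np.column_stack([xy, z])


@dataclass(frozen=True)
class NoiseSpec:
    cbct_gaussian_sd: float = 15.0  # intensity units
    oct_speckle_scale: float = 0.4  # 1/sqrt(looks); 0 disables speckle
    oct_penetration_bone_mm: float = 1.0
    oct_attenuation_per_mm: float = 2.0

    def __post_init__(self):
        for name in (
            "cbct_gaussian_sd",
            "oct_speckle_scale",
            "oct_penetration_bone_mm",
            "oct_attenuation_per_mm",
        ):
            if getattr(self, name) < 0:
                raise PhantomConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class IntensityModel:
    """Nominal CBCT intensity levels. Titanium sits far above bone so the
    upper-tail threshold is well-posed (> bone + 6 noise SDs at defaults)."""

    air: float = 0.0
    soft_tissue: float = 60.0
    bone: float = 200.0
    titanium: float = 1000.0


@dataclass(frozen=True)
class OctRenderParams:
    """Reflectance model: metallic caps reflect specularly and much more
    strongly than the diffusely scattering bone surface."""

    reflect_bone: float = 0.3
    reflect_cap: float = 1.0
    cap_decay_mm: float = 0.08
    cap_band_mm: float = 0.2


def default_true_transform() -> RigidTransform:
    """Modest head tilt mapping the surgical field into the lower OCT cube."""
    R = RigidTransform.from_rotvec((0.06, -0.05, 0.10)).rotation
    anchor_cbct = np.array([0.0, 0.9, 2.0])
    anchor_oct = np.array([0.0, 0.0, -2.2])
    return RigidTransform(R, anchor_oct - R @ anchor_cbct)


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic specimen + scanner pair."""

    cbct_voxel_mm: float = 0.3
    cbct_fov_mm: float = 19.2
    oct_voxel_axial_mm: float = 0.03
    oct_voxel_lateral_mm: float = 0.03
    fov_oct_mm: float = 10.0
    n_fiducials: int = 4
    fiducial_diameter_mm: float = 1.0
    fiducial_spacing_mm: tuple = (1.0, 2.0)  # surface-to-surface gap interval
    fiducial_jitter_mm: float = 0.05
    bone_surface: HeightField = field(default_factory=HeightField)
    canal: CanalSpec = field(default_factory=CanalSpec)
    true_transform: RigidTransform = field(default_factory=default_true_transform)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    intensities: IntensityModel = field(default_factory=IntensityModel)
    oct_render: OctRenderParams = field(default_factory=OctRenderParams)
    supersample: int = 4
    noncollinearity_tol_mm: float = 0.2
    seed: int = 0

    # -- derived grids -----------------------------------------------------
    def cbct_grid(self):
        n = int(round(self.cbct_fov_mm / self.cbct_voxel_mm))
        origin = -(n - 1) / 2.0 * self.cbct_voxel_mm
        return n, np.full(3, origin), np.full(3, self.cbct_voxel_mm)

    def oct_grid(self):
        nlat = int(round(self.fov_oct_mm / self.oct_voxel_lateral_mm))
        nax = int(round(self.fov_oct_mm / self.oct_voxel_axial_mm))
        spacing = np.array(
            [self.oct_voxel_lateral_mm, self.oct_voxel_lateral_mm, self.oct_voxel_axial_mm]
        )
        shape = np.array([nlat, nlat, nax])
        origin = -(shape - 1) / 2.0 * spacing
        return shape, origin, spacing

    # -- fiducial layout ---------------------------------------------------
    def fiducial_centers(self) -> np.ndarray:
        """Sphere centres (mm, CBCT frame), resting on the bone surface.

        Base layout is a zig-zag row (strongly non-collinear) on the
        craniotomy-edge side of the canal. Consecutive centre distances ramp
        across the allowed spacing interval so the inter-point distance
        pattern has no symmetry: a reversal-symmetric row would make the
        distance-based correspondence ambiguous up to detection noise.
        Per-seed jitter perturbs the lateral positions.
        """
        n = self.n_fiducials
        i = np.arange(n)
        d = self.fiducial_diameter_mm
        lo, hi = self.fiducial_spacing_mm
        # consecutive centre distances spanning the gap interval with margin
        dist = np.linspace(d + lo + 0.15 * (hi - lo), d + hi - 0.15 * (hi - lo), n - 1)
        dy = 2.0
        dx = np.sqrt(np.clip(dist**2 - dy**2, 0.01, None))
        x = np.r_[0.0, np.cumsum(dx)]
        x -= x.mean()
        y = np.where(i % 2 == 0, 2.0, 2.0 + dy)
        xy = np.column_stack([x, y]).astype(float)
        if self.fiducial_jitter_mm > 0:
            rng = np.random.default_rng([self.seed, 7])
            xy += rng.uniform(-self.fiducial_jitter_mm, self.fiducial_jitter_mm, xy.shape)
        r = self.fiducial_diameter_mm / 2.0
        z = self.bone_surface.height(xy[:, 0], xy[:, 1]) + r
        return np.column_stack([xy, z])

    # -- validation --------------------------------------------------------
    def validate(self) -> np.ndarray:
        """Check all spec invariants; return the fiducial centres."""
        if self.n_fiducials < 3:
            raise PhantomConfigError("n_fiducials must be >= 3")
        if self.supersample < 1:
            raise PhantomConfigError("supersample must be >= 1")
        centers = self.fiducial_centers()
        d = self.fiducial_diameter_mm
        # consecutive surface-to-surface gaps inside the stated interval
        gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1) - d
        lo, hi = self.fiducial_spacing_mm
        if np.any(gaps < lo - 1e-9) or np.any(gaps > hi + 1e-9):
            raise PhantomConfigError(
                f"consecutive fiducial gaps {np.round(gaps, 3)} outside [{lo}, {hi}] mm"
            )
        # no pairwise overlap
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if dist.min() < d:
            raise PhantomConfigError("fiducial spheres overlap each other")
        # non-collinearity: RMS distance from the best-fit line
        c = centers - centers.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        if s[1] / np.sqrt(len(centers)) < self.noncollinearity_tol_mm:
            raise PhantomConfigError("fiducial centres are (near-)collinear")
        # canal strictly below the surface
        if self.canal.depth_mm - self.canal.radius_mm < 0.3:
            raise PhantomConfigError("canal reaches within 0.3 mm of the bone surface")
        # spheres clear of the canal tube
        axis = self.canal.axis_points(self.bone_surface)
        dmin = _dist_to_polyline(centers, axis).min()
        if dmin < self.canal.radius_mm + d / 2.0:
            raise PhantomConfigError("a fiducial sphere intersects the canal tube")
        return centers

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Exact analytic truth the cadaver study never had."""

    fiducial_centers_cbct: np.ndarray
    fiducial_centers_oct: np.ndarray
    canal_mask: np.ndarray
    surface: HeightField
    canal: CanalSpec
    true_transform: RigidTransform

    def to_dict(self) -> dict:
        return {
            "fiducial_centers_cbct_mm": self.fiducial_centers_cbct.tolist(),
            "fiducial_centers_oct_mm": self.fiducial_centers_oct.tolist(),
            "true_transform": self.true_transform.to_dict(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------
def _dist_to_polyline(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Min distance from each point (n,3) to a polyline given by vertices (k,3)."""
    p = np.atleast_2d(points)
    best = np.full(len(p), np.inf)
    for a, b in zip(vertices[:-1], vertices[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        best = np.minimum(best, np.linalg.norm(p - proj, axis=1))
    return best


def sphere_occupancy(center, radius, origin, spacing, shape, supersample):
    """Partial-volume occupancy of a sphere on a voxel grid.

    Returns ``(slices, frac)`` where ``frac`` is, for each voxel in the
    bounding box, the fraction of ``supersample**3`` sub-cells whose centre
    lies inside the sphere.
    """
    center = np.asarray(center, float)
    origin = np.asarray(origin, float)
    spacing = np.asarray(spacing, float)
    shape = np.asarray(shape, int)
    lo = np.maximum(np.floor((center - radius - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((center + radius - origin) / spacing).astype(int) + 2, shape)
    if np.any(hi <= lo):
        sl = tuple(slice(a, a) for a in lo)
        return sl, np.zeros((0, 0, 0))
    s = int(supersample)
    off = (np.arange(s) + 0.5) / s - 0.5
    d2 = []
    for ax in range(3):
        coords = origin[ax] + spacing[ax] * np.arange(lo[ax], hi[ax])
        sub = coords[:, None] + off[None, :] * spacing[ax]  # (n, s)
        d2.append((sub - center[ax]) ** 2)
    inside = (
        d2[0][:, None, None, :, None, None]
        + d2[1][None, :, None, None, :, None]
        + d2[2][None, None, :, None, None, :]
    ) <= radius**2
    frac = inside.reshape(*inside.shape[:3], -1).mean(axis=-1)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return sl, frac


def render_cbct_volume(
    spec: PhantomSpec,
    sphere_centers,
    include_canal: bool = True,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Render a CBCT volume of the phantom bone with spheres at given centres.

    Used both for the primary scan (fiducials on the craniotomy edge) and for
    the verification rescan (spheres placed on the ablated sites).

    Returns ``(Volume3D, canal_mask)``.
    """
    n, origin, spacing = spec.cbct_grid()
    im = spec.intensities
    x = origin[0] + spacing[0] * np.arange(n)
    y = origin[1] + spacing[1] * np.arange(n)
    z = origin[2] + spacing[2] * np.arange(n)
    h = spec.bone_surface.height(x[:, None], y[None, :])  # (n, n)
    data = np.where(z[None, None, :] <= h[:, :, None], im.bone, im.air).astype(float)

    canal_mask = np.zeros((n, n, n), dtype=bool)
    if include_canal:
        axis = spec.canal.axis_points(spec.bone_surface)
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        dist = _dist_to_polyline(pts, axis).reshape(n, n, n)
        canal_mask = dist < spec.canal.radius_mm
        data[canal_mask] = im.soft_tissue

    r = spec.fiducial_diameter_mm / 2.0
    for c in np.atleast_2d(np.asarray(sphere_centers, float)):
        sl, frac = sphere_occupancy(c, r, origin, spacing, (n, n, n), spec.supersample)
        data[sl] = frac * im.titanium + (1.0 - frac) * data[sl]

    sd = spec.noise.cbct_gaussian_sd if noise_sd is None else noise_sd
    if sd > 0:
        if rng is None:
            rng = np.random.default_rng([spec.seed, 11])
        data = data + rng.normal(0.0, sd, data.shape)

    vol = Volume3D.from_origin_spacing(data, origin, spacing, modality="CBCT")
    return vol, canal_mask


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------
def make_cbct_phantom(spec: PhantomSpec):
    """Generate the CBCT phantom and its exact ground truth.

    Returns
    -------
    (Volume3D, GroundTruth)
    """
    centers = spec.validate()
    vol, canal_mask = render_cbct_volume(spec, centers, include_canal=True)
    truth = GroundTruth(
        fiducial_centers_cbct=centers,
        fiducial_centers_oct=spec.true_transform.apply(centers),
        canal_mask=canal_mask,
        surface=spec.bone_surface,
        canal=spec.canal,
        true_transform=spec.true_transform,
    )
    return vol, truth


def make_oct_volume(
    spec: PhantomSpec, truth: GroundTruth, noise_scale: float | None = None
) -> Volume3D:
    """Render the OCT volume of the transformed phantom.

    Signal exists only from the bone surface down to the penetration depth,
    with exponential attenuation; each fiducial appears as its bright upper
    spherical cap with a shadow beneath; multiplicative speckle is applied.

    The depth used for attenuation is measured along the bone-frame vertical;
    for the modest tilts the device allows (surface within 45 degrees of the
    beam) this is a few-percent approximation of the true optical path.
    """
    shape, origin, spacing = spec.oct_grid()
    nx, ny, nz = (int(v) for v in shape)
    half = spec.fov_oct_mm / 2.0
    r = spec.fiducial_diameter_mm / 2.0
    rp = spec.oct_render
    centers = np.atleast_2d(truth.fiducial_centers_oct)

    for i, c in enumerate(centers):
        if c[2] + r > 0.0:
            raise FieldOfViewError(
                f"fiducial {i} is not in the lower half of the OCT field "
                f"(cap top z = {c[2] + r:.2f} mm)"
            )
        if (
            abs(c[0]) + r > half
            or abs(c[1]) + r > half
            or c[2] - r < -half
        ):
            raise FieldOfViewError(f"fiducial {i} falls outside the OCT field of view")

    x = origin[0] + spacing[0] * np.arange(nx)
    y = origin[1] + spacing[1] * np.arange(ny)
    z = origin[2] + spacing[2] * np.arange(nz)

    Tinv = spec.true_transform.inverse()
    Ri, ti = Tinv.rotation, Tinv.translation
    mu = spec.noise.oct_attenuation_per_mm
    pen = spec.noise.oct_penetration_bone_mm

    out = np.zeros((nx, ny, nz), dtype=float)
    chunk = max(1, int(4e6 // (nx * ny)))  # bound peak memory for fine grids
    for k0 in range(0, nz, chunk):
        zc = z[k0 : k0 + chunk]
        qx = (
            Ri[0, 0] * x[:, None, None]
            + Ri[0, 1] * y[None, :, None]
            + Ri[0, 2] * zc[None, None, :]
            + ti[0]
        )
        qy = (
            Ri[1, 0] * x[:, None, None]
            + Ri[1, 1] * y[None, :, None]
            + Ri[1, 2] * zc[None, None, :]
            + ti[1]
        )
        qz = (
            Ri[2, 0] * x[:, None, None]
            + Ri[2, 1] * y[None, :, None]
            + Ri[2, 2] * zc[None, None, :]
            + ti[2]
        )
        depth = spec.bone_surface.height(qx, qy) - qz
        sig = np.where(
            (depth >= 0.0) & (depth <= pen), rp.reflect_bone * np.exp(-mu * depth), 0.0
        )
        out[:, :, k0 : k0 + chunk] = sig

    # fiducial caps: bright upper hemisphere, shadow cone beneath
    for c in centers:
        ix = np.where(np.abs(x - c[0]) < r)[0]
        iy = np.where(np.abs(y - c[1]) < r)[0]
        if ix.size == 0 or iy.size == 0:
            continue
        rho2 = (x[ix][:, None] - c[0]) ** 2 + (y[iy][None, :] - c[1]) ** 2
        foot = rho2 < r**2
        zcap = np.full_like(rho2, -np.inf)
        zcap[foot] = c[2] + np.sqrt(r**2 - rho2[foot])
        sub = out[np.ix_(ix, iy)]  # (fx, fy, nz) view copy
        zg = z[None, None, :]
        zc3 = zcap[:, :, None]
        shadow = foot[:, :, None] & (zg < zc3)
        sub[shadow] = 0.0
        band = foot[:, :, None] & (zg <= zc3) & (zg > zc3 - rp.cap_band_mm)
        vals = rp.reflect_cap * np.exp(-(zc3 - zg) / rp.cap_decay_mm)
        sub[band] = np.broadcast_to(vals, sub.shape)[band]
        out[np.ix_(ix, iy)] = sub

    scale = spec.noise.oct_speckle_scale if noise_scale is None else noise_scale
    if scale > 0:
        rng = np.random.default_rng([spec.seed, 13])
        looks = 1.0 / scale**2
        nzi = out > 0
        out[nzi] *= rng.gamma(looks, 1.0 / looks, int(nzi.sum()))

    return Volume3D.from_origin_spacing(out, origin, spacing, modality="OCT")
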