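"""Phantom generation: geometry, partial-volume rendering, OCT physics, determinism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from octguide.errors import FieldOfViewError, PhantomConfigError
from octguide.phantom import (
    CanalSpec,
    PhantomSpec,
    make_cbct_phantom,
    make_oct_volume,
    render_cbct_volume,
    sphere_occupancy,
)
from octguide.transforms import RigidTransform

from conftest import NOISE_FREE


def titanium_threshold(spec):
    return 0.5 * (spec.intensities.bone + spec.intensities.titanium)


class TestCbctPhantom:
    def test_four_titanium_components(self):
        vol, _ = make_cbct_phantom(PhantomSpec(seed=1))
        _, ncomp = ndimage.label(vol.data > titanium_threshold(PhantomSpec()))
        assert ncomp == 4

    def test_ground_truth_centers_consistent(self, phantom_clean, spec_clean):
        _, truth = phantom_clean
        mapped = spec_clean.true_transform.apply(truth.fiducial_centers_cbct)
        assert np.allclose(mapped, truth.fiducial_centers_oct, atol=1e-14)

    def test_sphere_on_voxel_center_is_reflection_symmetric(self, spec_clean):
        # one sphere floating in air, centred exactly on a voxel centre
        n, origin, spacing = spec_clean.cbct_grid()
        idx = np.array([40, 40, 52])
        center = origin + spacing * idx
        vol, _ = render_cbct_volume(
            spec_clean, center[None, :], include_canal=False, noise_sd=0.0
        )
        r_vox = 4
        sl = tuple(slice(i - r_vox, i + r_vox + 1) for i in idx)
        block = vol.data[sl] - spec_clean.intensities.air
        for ax in range(3):
            assert np.abs(block - np.flip(block, axis=ax)).max() == 0.0

    def test_partial_volume_mass_conservation(self):
        # rendered sphere "mass" vs the closed-form sphere volume
        spec = replace(PhantomSpec(), supersample=8)
        n, origin, spacing = spec.cbct_grid()
        _, frac = sphere_occupancy(
            np.array([0.07, -0.11, 0.13]), 0.5, origin, spacing, (n, n, n), 8
        )
        rendered = frac.sum() * spacing.prod()
        analytic = 4.0 / 3.0 * np.pi * 0.5**3
        assert abs(rendered - analytic) / analytic < 0.01

    def test_determinism(self):
        spec = PhantomSpec(seed=9)
        v1, t1 = make_cbct_phantom(spec)
        v2, t2 = make_cbct_phantom(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1.fiducial_centers_cbct, t2.fiducial_centers_cbct)
        v3, _ = make_cbct_phantom(PhantomSpec(seed=10))
        assert not np.array_equal(v1.data, v3.data)

    def test_fiducial_spacing_and_noncollinearity(self, phantom_clean, spec_clean):
        _, truth = phantom_clean
        c = truth.fiducial_centers_cbct
        gaps = np.linalg.norm(np.diff(c, axis=0), axis=1) - spec_clean.fiducial_diameter_mm
        lo, hi = spec_clean.fiducial_spacing_mm
        assert np.all(gaps >= lo) and np.all(gaps <= hi)
        s = np.linalg.svd(c - c.mean(axis=0), compute_uv=False)
        assert s[1] / np.sqrt(len(c)) >= spec_clean.noncollinearity_tol_mm

    @pytest.mark.parametrize(
        "bad_spec",
        [
            PhantomSpec(n_fiducials=2),
            PhantomSpec(fiducial_spacing_mm=(-0.6, -0.2)),  # forces overlapping spheres
            replace(PhantomSpec(), canal=CanalSpec(depth_mm=1.0, radius_mm=0.8)),
        ],
        ids=["too-few-fiducials", "overlapping-spacing", "canal-reaches-surface"],
    )
    def test_invalid_specs_rejected(self, bad_spec):
        with pytest.raises(PhantomConfigError):
            make_cbct_phantom(bad_spec)

    def test_canal_mask_below_surface(self, phantom_clean, spec_clean):
        vol, truth = phantom_clean
        idx = np.argwhere(truth.canal_mask).astype(float)
        pts = vol.index_to_world(idx)
        h = truth.surface.height(pts[:, 0], pts[:, 1])
        assert np.all(pts[:, 2] < h)


class TestOctVolume:
    def test_no_signal_beyond_penetration(self, spec_clean, phantom_clean, oct_clean):
        _, truth = phantom_clean
        vol = oct_clean
        nz = np.argwhere(vol.data > 0)
        pts = vol.index_to_world(nz[:: max(1, len(nz) // 5000)].astype(float))
        q = spec_clean.true_transform.inverse().apply(pts)
        depth = spec_clean.bone_surface.height(q[:, 0], q[:, 1]) - q[:, 2]
        pen = spec_clean.noise.oct_penetration_bone_mm
        # caps protrude above the surface (depth < 0); bone signal must stop at pen
        assert depth.max() <= pen + 1e-9

    def test_brightest_voxels_on_upper_cap(self, spec_clean, phantom_clean, oct_clean):
        _, truth = phantom_clean
        vol = oct_clean
        peak = vol.data.max()
        idx = np.argwhere(vol.data > 0.98 * peak).astype(float)
        pts = vol.index_to_world(idx)
        r = spec_clean.fiducial_diameter_mm / 2.0
        half_voxel = 0.5 * vol.spacing.max()
        d = np.linalg.norm(
            pts[:, None, :] - truth.fiducial_centers_oct[None, :, :], axis=-1
        )
        nearest = d.min(axis=1)
        which = d.argmin(axis=1)
        assert np.all(np.abs(nearest - r) <= half_voxel + 1e-9)
        # upper cap only: brightest voxels sit above their sphere's centre plane
        cz = truth.fiducial_centers_oct[which, 2]
        assert np.all(pts[:, 2] >= cz - half_voxel)

    def test_shadow_beneath_cap(self, spec_clean, phantom_clean, oct_clean):
        _, truth = phantom_clean
        vol = oct_clean
        c = truth.fiducial_centers_oct[0]
        idx = np.round(vol.world_to_index(c)).astype(int)
        column = vol.data[idx[0], idx[1], :]
        z = vol.axis_coords(2)
        assert column[z < c[2]].max(initial=0.0) == 0.0

    def test_determinism_bit_identical(self, phantom_study_noisy, spec_study_noisy):
        _, truth = phantom_study_noisy
        v1 = make_oct_volume(spec_study_noisy, truth)
        v2 = make_oct_volume(spec_study_noisy, truth)
        assert np.array_equal(v1.data, v2.data)

    def test_fiducial_outside_fov_raises(self, spec_clean):
        bad = replace(
            spec_clean,
            true_transform=RigidTransform(np.eye(3), np.array([0.0, 0.0, 3.0])),
        )
        _, truth = make_cbct_phantom(bad)
        with pytest.raises(FieldOfViewError, match="fiducial"):
            make_oct_volume(bad, truth)
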