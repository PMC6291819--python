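# Methods

`octguide` simulates, at desk scale, an image-guided workflow for marking the
projection of the internal auditory canal (IAC) onto the superior petrous
bone surface: a CBCT scan provides the plan, an OCT-tracked Er:YAG laser
executes it, and four 1 mm titanium spheres visible in both modalities link
the two frames. Because no imaging data from the original cadaver experiments
is available, every input is generated by a phantom model with exact ground
truth, and the workflow's accuracy is measured by Monte-Carlo simulation.

## Phantom model

**Geometry.** The bone is a half-space bounded above by a smooth height
field `z = h(x, y)` (quadratic polynomial, optional Gaussian bump), so
surface normals are analytic. The IAC surrogate is a capsule-shaped tube:
all points within 0.8 mm of a V-shaped axis polyline buried 2.5 mm below the
surface (apex pointing medially). Four titanium spheres of 1 mm diameter
rest tangentially on the surface near the craniotomy edge.

**Fiducial arrangement.** Sphere centres form a zig-zag row whose
consecutive centre distances *ramp* across the allowed 1–2 mm
surface-to-surface gap interval (gaps ≈ 1.14, 1.54, 1.82 mm). The ramp is
deliberate: a zig-zag with constant steps is symmetric under index
reversal, which makes the inter-point distance pattern — the only
information available to correspondence matching — ambiguous up to
detection noise. With the ramp, the second-best assignment cost stays
above 0.6 mm² for every placement-jitter draw (±0.05 mm per coordinate),
orders of magnitude above detection-induced fluctuations. Non-collinearity
is enforced as an RMS distance of ≥ 0.2 mm from the best-fit line.

**CBCT rendering.** 64³ voxels at 0.3 mm. Four nominal intensity levels
(air 0, soft tissue 60, bone 200, titanium 1000); the titanium level sits
more than six noise standard deviations above bone so thresholding is
well-posed. Spheres are rendered by supersampled partial-volume occupancy
(default 4³ sub-cells per voxel; rendered sphere mass matches the analytic
volume within 1 % at ≥ 4), which is what makes sub-voxel centroid
localization meaningful. Gaussian intensity noise (default sd 15) is added
last.

**OCT rendering.** A 10 mm cube matching the laser workspace, 0.03 mm axial
sampling. Signal exists only from the bone surface down to 1 mm depth
(penetration limit in bone), attenuating as `exp(-2 d)` per mm. Titanium
reflects specularly and blocks the infrared beam, so each sphere appears
only as its bright upper cap (a 0.2 mm band decaying below the analytic cap
surface) with a shadow beneath; bone reflectance is 0.3 versus 1.0 for the
caps. Fully multiplicative speckle is drawn per voxel from a Gamma
distribution with shape `1/scale²` (default scale 0.4 ≈ 6 looks). Depth is
measured along the bone-frame vertical rather than the beam, a few-percent
approximation valid for the modest tilts the incidence constraint allows.

**Determinism.** All stochastic draws flow from one integer seed through
independent numpy `SeedSequence` substreams (fiducial jitter, CBCT noise,
OCT speckle), so identical specs give bit-identical volumes.

## Detection

**CBCT.** The titanium level is isolated by Otsu thresholding of the upper
intensity tail, floored at the midpoint between the foreground median
(bone) and the boxcar-smoothed maximum (titanium peak) — the floor matters
because Otsu degenerates when one class holds ~100 of ~170 000 voxels.
Connected components are filtered by equivalent-sphere diameter (±50 % of
the expected 1 mm) and localized by the intensity-weighted centroid over
the component and its one-voxel shell. Noise-free localization error is
~0.01 mm (3–5 % of a voxel), with a deterministic quantization bias of
similar size.

**OCT.** The volume is despeckled with a 3×3×3 boxcar (speckle is
uncorrelated voxel-to-voxel; the cap band is wide and thick enough to
survive), thresholded by Otsu over positive intensities, and clustered.
Candidate caps must cover ≥ 20 % of the analytic cap footprint in A-scan
columns and be no wider than 1.5 sphere radii. Per cluster, the topmost
bright voxel of each column forms a cap-surface point cloud, to which a
sphere of *known* radius (0.5 mm) is fitted by robust least squares — the
visible cap constrains a free radius poorly, though a free-radius variant
exists and recovers the 1 mm diameter within 0.05 mm on noise-free
renders. Fits with RMS residual above 15 % of the radius are dropped, and
candidates within one radius of a better one are treated as fragments of
the same sphere and merged. Typical centre accuracy is 0.03 mm.

**Correspondence.** Exhaustive search over injective assignments (≤ 6
points, so exact) minimizing the sum of squared differences between the two
inter-point distance matrices. Two assignments within 1e-6 mm² raise an
ambiguity error rather than guessing — a navigation system must not
silently mislabel markers.

## Registration and error measures

The CBCT→laser transform is the closed-form least-squares rigid fit
(centroid alignment plus SVD of the cross-covariance with determinant-sign
correction; no iteration, no seed). FRE is the RMS fiducial residual; the
plain mean is also reported because "mean error" is often left undefined in
the clinical literature. TRE is the displacement a transform error induces
at a target; for a pure rotation it follows `2 sin(θ/2) d` with `d` the
distance from the axis, which the tests verify.

## Planning

The canal is segmented by band thresholding (30–120, between air and bone),
keeping the largest connected component with a one-voxel closing; Dice
against ground truth exceeds 0.99 at default noise. Targets are placed
"directly above the canal edge in the line of sight": mask voxels are
projected along the view direction onto the lateral plane, the silhouette
boundary is traced at sub-pixel precision, the tube's rounded end caps are
trimmed (contour points within the local medial-axis half-width of a
skeleton endpoint), and the remaining boundary arms are lifted back to the
bone surface along the view ray and resampled at 0.5 mm — a spacing chosen
near the ablation-spot scale, since the physical workflow does not fix one.
For the V-shaped canal this yields the outer and inner silhouette edges,
each a V meeting at the medial apex; for a straight tube it degenerates to
two parallel lines one diameter apart. All planned points lie strictly
outside the canal by construction (the surface is 1.7 mm above the canal
top at defaults).

## Ablation model

Ablation is calibrated empirically, not simulated physically: each cycle
removes a fixed 0.3 mm of bone at every executed target, and path time is
polyline length divided by the 4 mm/s focus-spot speed. Targets are flagged
against the 10 mm workspace cube (centred on the device origin) and the
45–90° incidence window between surface plane and beam before execution;
flagged targets are skipped with zero depth. Beam-pointing jitter is a
configurable isotropic Gaussian, default 0 in the device configuration and
0.05 mm in the Monte-Carlo study's execution-error source.

## The verification study

Each replicate draws a random head tilt (≤ 12°, uniform axis) placing the
field in the lower half of the OCT cube, renders both volumes, runs the
full chain, and then imitates the verification procedure: spheres are
placed at the achieved mark positions (mapped back to the plan frame
through the *true* transform), a fresh CBCT is rendered and re-detected,
and the re-measured positions are compared with the planned targets,
paired by optimal assignment. Because a physical verification sphere is
1 mm wide, spheres go on a greedy subset of marks kept ≥ 2 mm apart (≤ 6
per replicate); rendering one at every 0.5 mm target would merge them into
an undetectable blob. Desired-vs-applied comparison happens in the plan's
native CBCT frame. Replicate failures (detection, ambiguity, constraint
loss) are counted and reported, never dropped silently.

Error sources can be toggled independently: CBCT intensity noise, OCT
speckle, the image-based measurement channel itself (off = ground-truth
centres and exact mark measurement), and execution jitter. With everything
off the loop closes to numerical precision, which pins the pipeline's
systematic error at zero before noise is layered on.

**Problem sizes.** The study default is 200 replicates on 64³ CBCT and
128×128×334 OCT grids (0.3 mm CBCT voxels; 0.03 mm axial OCT sampling with
a 10/128 ≈ 0.078 mm lateral A-scan pitch — a realistic pitch for a
spectral-domain system, and the volume scale the study is designed around).
Stand-alone phantom defaults keep 0.03 mm sampling on both OCT axes. A full
200-replicate study runs in a few minutes on one CPU.

## What the phantom does and does not show

The generator reproduces the geometry and first-order imaging behaviour the
workflow depends on: partial-volume sphere appearance in CBCT, cap-only
visibility with shadowing in OCT, shallow penetration, speckle, and a
hidden rigid inter-frame transform. It does not model CT beam hardening or
metal artifacts, OCT wave optics or refraction, tissue inhomogeneity,
deformation between scans, or marker placement error relative to bone —
so a passing study demonstrates the soundness of the algorithmic chain at
realistic noise levels, not the full error budget of the physical system.
Known limitations: the incidence model treats the surface as locally
planar; attenuation depth is measured along the bone vertical; verification
spheres are assumed to sit exactly at the crater centres.
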