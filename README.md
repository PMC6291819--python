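# octguide

Simulation study of CBCT/OCT-guided laser labeling of the internal auditory
canal (IAC) in the middle cranial fossa approach.

In this surgical workflow the IAC is invisible from the superior petrous
bone surface; a cone-beam CT (CBCT) scan supplies the plan, and an Er:YAG
marking laser — sharing its optics with an optical coherence tomography
(OCT) scanner — shallowly ablates the canal's outline onto the bone so the
surgeon can drill safely. Four 1 mm titanium spheres on the craniotomy edge,
visible in both modalities, link the CBCT frame to the laser/OCT frame.
This package re-creates that workflow end to end on synthetic phantoms with
known ground truth, so the achievable accuracy — reported as roughly 300 μm
in cadaver experiments — can be measured, attributed and stress-tested in
simulation. It is written for researchers in image-guided surgery and
medical image analysis who want a fully controlled, reproducible model of
the pipeline.

## What it computes

* **Phantom** (`octguide.phantom`) — paired CBCT (0.3 mm voxels) and OCT
  (10 mm cube, ~1 mm penetration in bone, speckle) volumes of a bone
  surface, a buried V-shaped canal, and titanium fiducials rendered with
  supersampled partial-volume occupancy; the hidden rigid transform between
  frames is known exactly.
* **Detection** (`octguide.detection`) — sub-voxel sphere localization:
  intensity-weighted centroids in CBCT, known-radius least-squares cap fits
  in OCT, and exact exhaustive correspondence by inter-point distance
  patterns (ambiguous configurations are an error, never a guess).
* **Registration** (`octguide.registration`) — the closed-form rigid fit
  `min_{R,t} Σᵢ ‖R mᵢ + t − fᵢ‖²` via SVD of the cross-covariance with
  reflection exclusion; fiducial registration error (FRE, RMS residual) and
  target registration error (TRE).
* **Planning** (`octguide.planning`) — canal segmentation by band
  thresholding and placement of ordered targets on the bone surface
  directly above the canal's silhouette edge along the viewing direction
  (the V-shaped mark path).
* **Ablation** (`octguide.ablation`) — transfer into the laser frame,
  10 mm-workspace and 45–90° incidence checks, and the empirical crater
  model (0.3 mm depth per cycle, 4 mm/s path speed).
* **Evaluation** (`octguide.evaluation`) — a seeded Monte-Carlo study of
  the complete loop, including the verification rescan ("place spheres on
  the ablated sites, rescan, compare"), plus an error budget per source.

See `docs/methods.md` for the model details and their assumptions.

## Worked example

One specimen, end to end:

```python
from octguide import (PhantomSpec, make_cbct_phantom, make_oct_volume,
                      detect_spheres_cbct, detect_spheres_oct,
                      match_fiducials, fit_rigid, study_phantom_spec)

spec = study_phantom_spec(seed=1)          # 0.3 mm CBCT, 10 mm OCT cube
cbct, truth = make_cbct_phantom(spec)
oct_vol = make_oct_volume(spec, truth)
fc = detect_spheres_cbct(cbct, 1.0, 4)
fo = detect_spheres_oct(oct_vol, 1.0, 4)
corr = match_fiducials(fc, fo)
reg = fit_rigid(fc.centers_mm[[a for a, _ in corr.pairs]],
                fo.centers_mm[[b for _, b in corr.pairs]])
print(corr.pairs, f"FRE {reg.fre_mm:.4f} mm")
```

Running the numbered drivers reproduces the full analysis
(`python analysis/01_simulate_phantom.py`, then 02…05); step 02 prints,
for the default seed:

```
detected 4 CBCT and 4 OCT fiducials
correspondence [(0, 0), (1, 1), (2, 2), (3, 3)], pattern residual 0.0181 mm
CBCT localization error: 0.0126 mm mean (max 0.0216)
OCT  localization error: 0.0317 mm mean (max 0.0348)
FRE 0.0122 mm; TRE at a canal-distance probe 0.0323 mm
```

i.e. both detectors localize the 1 mm spheres to a few hundredths of a
millimetre, the labeling is recovered exactly, and the fitted transform
displaces a probe point near the canal by ~32 μm. Step 03 then segments
the canal (Dice 0.996), places 42 targets along the two arms of the V, and
ablates one 0.30 mm cycle over a 5.4 s path; step 04 runs the 200-replicate
verification study, whose pooled mean desired-vs-applied error of ~79 μm
(max 197 μm) sits comfortably inside the ~300 μm accuracy envelope reported
for the physical system; step 05 splits that error among CBCT noise, OCT
speckle, measurement quantization and execution jitter.

A stage-per-verb CLI (`octguide generate|segment|plan|detect|match|
register|transfer|ablate|study|pipeline`) wraps the same functions for
shell use.

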