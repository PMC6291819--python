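"""Generate one paired CBCT/OCT phantom and record its ground truth.

Emulates one specimen of the cadaver workflow: a petrous-bone slab with a
buried V-shaped canal, four 1 mm titanium fiducials on the craniotomy edge
(1-2 mm apart, non-collinear), a CBCT scan at 0.3 mm voxels and an OCT scan
of the 10 mm laser workspace. Volumes go to scratch/ (large, regenerable);
the ground-truth table goes to results/.
"""

import json
import os

import numpy as np

from octguide import io as ogio
from octguide.evaluation import study_phantom_spec
from octguide.phantom import make_cbct_phantom, make_oct_volume

os.makedirs("scratch/phantom", exist_ok=True)
os.makedirs("results", exist_ok=True)

spec = study_phantom_spec(seed=1)
vol_cbct, truth = make_cbct_phantom(spec)
vol_oct = make_oct_volume(spec, truth)

ogio.write_volume(vol_cbct, "scratch/phantom/cbct.nii.gz")
ogio.write_volume(vol_oct, "scratch/phantom/oct.nii.gz")
truth.save_json("results/01_phantom_ground_truth.json")

gaps = np.linalg.norm(np.diff(truth.fiducial_centers_cbct, axis=0), axis=1)
gaps -= spec.fiducial_diameter_mm
print(f"CBCT volume: {vol_cbct.shape} voxels at {vol_cbct.spacing[0]:.2f} mm")
print(f"OCT volume:  {vol_oct.shape} voxels over a {spec.fov_oct_mm:.0f} mm cube")
print(f"fiducials:   {len(truth.fiducial_centers_cbct)} spheres of "
      f"{spec.fiducial_diameter_mm:.1f} mm, surface gaps "
      f"{np.array2string(gaps, precision=2)} mm (spec interval "
      f"{spec.fiducial_spacing_mm})")
print(f"true transform: rotation {spec.true_transform.rotation_angle_deg():.1f} deg, "
      f"translation {np.array2string(spec.true_transform.translation, precision=2)} mm")
print("ground truth -> results/01_phantom_ground_truth.json")
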