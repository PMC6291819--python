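"""Volume, point-set and transform readers/writers.

Volumes round-trip through NIfTI (``.nii``/``.nii.gz``) or MetaImage
(``.mha``/``.mhd``) via SimpleITK; point sets, transforms and reports use
plain JSON/CSV. The voxel-centre affine convention of :class:`Volume3D` maps
directly onto the ITK origin/spacing/direction model.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .detection import FiducialSet
from .planning import TargetPlan
from .volume import Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "write_fiducials",
    "read_fiducials",
    "write_plan_csv",
]

_VOLUME_EXTS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_ext(path: str) -> None:
    if not any(str(path).endswith(e) for e in _VOLUME_EXTS):
        raise IOError(
            f"unrecognized volume extension for {path!r}; use one of {_VOLUME_EXTS}"
        )


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume; data and index->world affine survive the round trip."""
    _check_ext(path)
    # ITK arrays are indexed (z, y, x); our volumes are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    direction = vol.affine[:3, :3] / vol.spacing[None, :]
    img.SetDirection(tuple(direction.reshape(-1)))
    if str(path).endswith((".mha", ".mhd")):
        img.SetMetaData("modality", vol.modality)
    sitk.WriteImage(img, str(path))


def read_volume(path, modality: str | None = None) -> Volume3D:
    """Read a volume written by :func:`write_volume` (or any NIfTI/MetaImage).

    ``modality`` overrides whatever the file header carries.
    """
    _check_ext(path)
    if not os.path.exists(path):
        raise IOError(f"volume file not found: {path!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot read volume {path!r}: {exc}") from exc
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing())
    origin = np.asarray(img.GetOrigin())
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing[None, :]
    affine[:3, 3] = origin
    if modality is None:
        try:
            modality = img.GetMetaData("modality")
        except RuntimeError:
            modality = "unknown"
        if modality not in ("CBCT", "OCT"):
            modality = "unknown"
    return Volume3D(data=data, affine=affine, modality=modality)


def write_fiducials(fids: FiducialSet, path) -> None:
    """FiducialSet as JSON (``.json``) or CSV (anything else)."""
    records = fids.to_records()
    if str(path).endswith(".json"):
        with open(path, "w") as fh:
            json.dump({"frame": fids.frame, "fiducials": records}, fh, indent=2)
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def read_fiducials(path) -> FiducialSet:
    with open(path) as fh:
        d = json.load(fh)
    recs = d["fiducials"]
    return FiducialSet(
        centers_mm=np.array([[r["x_mm"], r["y_mm"], r["z_mm"]] for r in recs]),
        radii_mm=np.array([r["r_mm"] for r in recs]),
        quality=np.array([r["quality"] for r in recs]),
        frame=d["frame"],
    )


def write_plan_csv(plan: TargetPlan, path) -> None:
    pd.DataFrame(plan.to_records()).to_csv(path, index=False)
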