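"""End-to-end pipeline driver: one demonstration specimen plus the study.

Mirrors the study's step list as a linear run — generate, segment, plan,
detect (both modalities), match, register, transfer, ablate, verify — with
every intermediate artifact written to disk, then runs the Monte-Carlo
accuracy study and writes its report. Idempotent given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import io as ogio
from .ablation import LaserConfig, check_constraints, simulate_ablation
from .detection import detect_spheres_cbct, detect_spheres_oct, match_fiducials
from .errors import OctGuideError, PipelineStageError
from .evaluation import StudyConfig, run_accuracy_study
from .phantom import PhantomSpec, make_cbct_phantom, make_oct_volume
from .planning import place_targets, segment_canal
from .registration import fit_rigid

__all__ = ["PipelineConfig", "run_pipeline", "phantom_spec_from_yaml", "load_pipeline_config"]

log = logging.getLogger(__name__)


def _from_dict(cls, d: dict):
    """Build a (possibly nested) dataclass from a plain dict with defaulting."""
    if d is None:
        return cls()
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if isinstance(v, dict):
            default = names[k].default_factory() if names[k].default_factory is not dataclasses.MISSING else None
            if default is not None and dataclasses.is_dataclass(default):
                v = _from_dict(type(default), v)
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return cls(**kwargs)


def phantom_spec_from_yaml(path) -> PhantomSpec:
    with open(path) as fh:
        return _from_dict(PhantomSpec, yaml.safe_load(fh))


def laser_config_from_yaml(path) -> LaserConfig:
    with open(path) as fh:
        return _from_dict(LaserConfig, yaml.safe_load(fh))


@dataclass
class PipelineConfig:
    """Paths and knobs for one full pipeline run."""

    out_dir: str = "pipeline_out"
    phantom_yaml: str | None = None
    laser_yaml: str | None = None
    study_yaml: str | None = None
    seed: int = 0
    n_replicates: int = 200
    verbosity: str = "INFO"

    def __post_init__(self):
        for p in (self.phantom_yaml, self.laser_yaml, self.study_yaml):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"referenced config file does not exist: {p}")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        return _from_dict(PipelineConfig, yaml.safe_load(fh))


def run_pipeline(cfg: PipelineConfig) -> int:
    """Execute all stages, writing artifacts under ``cfg.out_dir``.

    Returns 0 on success; stage failures raise :class:`PipelineStageError`
    carrying the stage name.
    """
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    os.makedirs(cfg.out_dir, exist_ok=True)
    out = lambda name: os.path.join(cfg.out_dir, name)

    spec = (
        phantom_spec_from_yaml(cfg.phantom_yaml) if cfg.phantom_yaml else PhantomSpec()
    )
    spec = replace(spec, seed=cfg.seed)
    laser = laser_config_from_yaml(cfg.laser_yaml) if cfg.laser_yaml else LaserConfig()

    def stage(name, fn, *args, **kwargs):
        log.info("stage: %s", name)
        try:
            return fn(*args, **kwargs)
        except (OctGuideError, ValueError) as exc:
            raise PipelineStageError(name, str(exc)) from exc

    vol_cbct, truth = stage("generate", make_cbct_phantom, spec)
    ogio.write_volume(vol_cbct, out("cbct.nii.gz"))
    truth.save_json(out("ground_truth.json"))

    seg = stage("segment", segment_canal, vol_cbct)
    from .volume import Volume3D

    ogio.write_volume(
        Volume3D(seg.mask.astype(np.uint8), seg.affine, "CBCT"), out("canal_mask.nii.gz")
    )

    plan = stage("plan", place_targets, seg, truth.surface)
    ogio.write_plan_csv(plan, out("plan.csv"))

    fids_cbct = stage(
        "detect-cbct", detect_spheres_cbct, vol_cbct, spec.fiducial_diameter_mm, spec.n_fiducials
    )
    ogio.write_fiducials(fids_cbct, out("fiducials_cbct.json"))

    vol_oct = stage("render-oct", make_oct_volume, spec, truth)
    ogio.write_volume(vol_oct, out("oct.nii.gz"))
    fids_oct = stage(
        "detect-oct", detect_spheres_oct, vol_oct, spec.fiducial_diameter_mm, spec.n_fiducials
    )
    ogio.write_fiducials(fids_oct, out("fiducials_oct.json"))

    corr = stage("match", match_fiducials, fids_cbct, fids_oct)
    with open(out("correspondence.json"), "w") as fh:
        json.dump({"pairs": corr.pairs, "residual_mm": corr.residual}, fh, indent=2)

    reg = stage(
        "register",
        fit_rigid,
        fids_cbct.centers_mm[[a for a, _ in corr.pairs]],
        fids_oct.centers_mm[[b for _, b in corr.pairs]],
    )
    reg.transform.save_json(out("transform.json"))
    reg.transform.save_matrix_txt(out("transform_4x4.txt"))
    with open(out("registration.json"), "w") as fh:
        json.dump(reg.to_dict(), fh, indent=2)

    pts_laser = stage("transfer", reg.transform.apply, plan.points_mm)
    normals_laser = plan.normals @ reg.transform.rotation.T
    flags = stage("constraints", check_constraints, pts_laser, normals_laser, laser)
    abl = stage("ablate", simulate_ablation, pts_laser, flags, laser, 1)
    with open(out("ablation.json"), "w") as fh:
        json.dump(abl.to_dict(), fh, indent=2)

    study = StudyConfig(
        n_replicates=cfg.n_replicates, phantom=_study_phantom(spec), laser=laser, seed=cfg.seed
    )
    report = stage("verify", run_accuracy_study, study)
    report.save_json(out("accuracy_report.json"))
    report.errors_frame().to_csv(out("accuracy_errors.csv"), index=False)
    log.info(
        "study: mean %.3f mm, rms %.3f mm, max %.3f mm over %d replicates (%d failed)",
        report.mean_mm,
        report.rms_mm,
        report.max_mm,
        report.n_replicates,
        report.n_failed,
    )
    return 0


def _study_phantom(spec: PhantomSpec) -> PhantomSpec:
    """Coarsen the lateral OCT pitch to the study's 128-column scale."""
    return replace(spec, oct_voxel_lateral_mm=max(spec.oct_voxel_lateral_mm, 10.0 / 128.0))
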