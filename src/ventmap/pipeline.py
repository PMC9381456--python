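"""End-to-end per-subject and cohort workflow.

Per subject: lung masks → deformable registration of both inspiration scans
to the baseline expiration (the anatomical reference) → inverse-Jacobian ×
density-ratio ventilation → temporal registration of the two warped
inspirations → density / volume change maps → tissue classification →
cross-tabulated summary, with registration QC (subjects whose mask-surface
misalignment exceeds 2 mm are flagged excluded, not crashed).

For phantom studies the ground-truth deformations can be injected
(``use_truth_fields``), bypassing registration: the breathing field and
truth Jacobian drive ventilation, and the truth temporal field drives the
volume-change map.  This isolates the analysis chain from registration
error and is what the statistical calibration runs use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage
import yaml

from .deformation import JacobianMap, invert_jacobian, jacobian_determinant
from .image import (
    HU_LAA,
    HU_NAA_HAA,
    HU_VESSEL,
    VolumetricImage,
    classify_tissue,
    make_lung_mask,
    write_volume,
)
from .longitudinal import ChangeMaps, combine, density_change, temporal_volume_change
from .phantom import PhantomSpec, PhantomTruth, make_cohort
from .registration import (
    MISALIGNMENT_LIMIT_MM,
    RegistrationConfig,
    qc_misalignment,
    register_deformable,
    warp,
)
from .stats import StudyResult, SubjectSummary, build_report, run_study, summarize_subject
from .ventilation import (
    CATEGORY_EDGES,
    DENOMINATOR_GUARD_HU,
    VentilationMap,
    categorize,
    compute_ventilation,
)

__all__ = ["PipelineConfig", "SubjectResult", "run_subject", "run_cohort", "run_phantom_cohort"]


@dataclass
class PipelineConfig:
    """All thresholds and settings of the analysis, defaulting to the
    standard values: HU class bounds −950/−600/−250, category edges
    0.25/0.5/0.75, 2 mm misalignment limit, 50 HU denominator guard."""

    hu_low: float = HU_LAA
    hu_naa_haa: float = HU_NAA_HAA
    hu_high: float = HU_VESSEL
    category_edges: tuple[float, float, float] = CATEGORY_EDGES
    misalignment_limit_mm: float = MISALIGNMENT_LIMIT_MM
    denominator_guard_hu: float = DENOMINATOR_GUARD_HU
    density_ratio_mode: str = "raw-hu"  # or "physical"
    jacobian_floor: float = 0.05
    registration: RegistrationConfig = dataclass_field(default_factory=RegistrationConfig)
    use_truth_fields: bool = False
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        reg = RegistrationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("registration", {}).items()
        })
        for key in ("category_edges",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(registration=reg, **raw)


@dataclass
class SubjectResult:
    """Everything the per-subject pipeline produces."""

    summary: SubjectSummary
    ventilation: VentilationMap
    changes: ChangeMaps
    tissue: "np.ndarray | None" = None
    misalignment_mm: float = float("nan")
    excluded: bool = False
    stage_log: list[str] = dataclass_field(default_factory=list)


class StageError(RuntimeError):
    """Pipeline failure with the offending stage in the message."""


def _stage(log: list[str], name: str):
    log.append(name)


def run_subject(
    config: PipelineConfig,
    baseline_insp: VolumetricImage,
    baseline_exp: VolumetricImage,
    followup_insp: VolumetricImage,
    truth: PhantomTruth | None = None,
    subject_id: str = "subject",
) -> SubjectResult:
    """Run the full voxelwise workflow for one subject.

    ``truth`` enables ground-truth field injection when
    ``config.use_truth_fields`` is set.  QC failure (misalignment above the
    limit) marks the summary excluded; stage errors raise
    :class:`StageError` tagged with the stage name.
    """
    log: list[str] = []
    if config.use_truth_fields and truth is None:
        raise StageError("setup: use_truth_fields requires phantom truth")

    try:
        _stage(log, "lung_mask")
        exp_mask = (
            truth.lung_mask_exp if truth is not None else make_lung_mask(baseline_exp)
        )

        _stage(log, "register_baseline")
        if config.use_truth_fields:
            field_b = truth.insp_to_exp_displacement
        else:
            field_b, _ = register_deformable(baseline_exp, baseline_insp, config.registration)
        insp_warped, insp_valid = warp(baseline_insp, field_b)

        _stage(log, "register_followup")
        if config.use_truth_fields:
            field_f = truth.followup_to_exp_displacement
        else:
            field_f, _ = register_deformable(baseline_exp, followup_insp, config.registration)
        followup_warped, fu_valid = warp(followup_insp, field_f)

        _stage(log, "qc")
        moving_mask = (
            truth.lung_mask_insp if truth is not None else make_lung_mask(baseline_insp)
        )
        warped_mask, _ = warp(
            VolumetricImage(moving_mask.astype(float), baseline_insp.spacing,
                            baseline_insp.origin, baseline_insp.direction),
            field_b, interpolation="nearest",
        )
        qc = qc_misalignment(
            exp_mask, warped_mask.data >= 0.5, baseline_exp.spacing,
            limit_mm=config.misalignment_limit_mm,
        )
        misalignment = qc.surface_misalignment_mean_mm
        excluded = qc.excluded

        _stage(log, "jacobian")
        if config.use_truth_fields:
            inv_jac = JacobianMap(
                truth.insp_to_exp_jacobian, baseline_exp.spacing, baseline_exp.origin,
                baseline_exp.direction.copy(), provenance="truth",
            )
        else:
            jac = jacobian_determinant(field_b, provenance="baseline_insp→exp")
            inv_jac = invert_jacobian(jac, floor=config.jacobian_floor)

        _stage(log, "classify")
        tissue = classify_tissue(insp_warped, exp_mask)

        _stage(log, "ventilation")
        vent = compute_ventilation(
            baseline_exp, insp_warped, inv_jac, tissue,
            density_ratio_mode=config.density_ratio_mode,
            guard_hu=config.denominator_guard_hu,
            warp_valid=insp_valid,
        )
        vent = categorize(vent, edges=config.category_edges)

        _stage(log, "temporal_registration")
        if config.use_truth_fields:
            temporal_field = truth.temporal_displacement
        else:
            temporal_field, _ = register_deformable(
                insp_warped, followup_warped, config.registration
            )

        _stage(log, "change_maps")
        dmaps = density_change(insp_warped, followup_warped, insp_valid, fu_valid)
        vmaps = temporal_volume_change(temporal_field)
        changes = combine(dmaps, vmaps)
        # peel one voxel at the pleural boundary: the interpolation kernel of
        # the warped images straddles an ~900 HU step there, which biases
        # voxelwise change estimates
        changes.valid &= ndimage.binary_erosion(exp_mask)

        _stage(log, "summary")
        summary = summarize_subject(
            vent, tissue, changes, subject_id=subject_id, misalignment_mm=misalignment
        )
        summary.excluded = excluded
    except (ValueError, RuntimeError) as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(f"{log[-1] if log else 'setup'}: {exc}") from exc

    result = SubjectResult(
        summary=summary,
        ventilation=vent,
        changes=changes,
        tissue=tissue.labels,
        misalignment_mm=misalignment,
        excluded=excluded,
        stage_log=log,
    )
    if config.out_dir:
        _persist(config, result, baseline_exp, insp_warped, followup_warped, subject_id)
    return result


def _persist(config, result, baseline_exp, insp_warped, followup_warped, subject_id) -> None:
    d = os.path.join(config.out_dir, subject_id)
    os.makedirs(d, exist_ok=True)
    write_volume(baseline_exp.like(np.nan_to_num(result.ventilation.values, nan=-1.0)),
                 os.path.join(d, "ventilation.nii.gz"))
    write_volume(baseline_exp.like(result.ventilation.category_labels.astype(np.float32)),
                 os.path.join(d, "ventilation_categories.nii.gz"))
    write_volume(insp_warped, os.path.join(d, "baseline_insp_warped.nii.gz"))
    write_volume(followup_warped, os.path.join(d, "followup_insp_warped.nii.gz"))
    if result.changes.density_change_hu is not None:
        write_volume(baseline_exp.like(result.changes.density_change_hu),
                     os.path.join(d, "density_change_hu.nii.gz"))
    if result.changes.volume_change_pct is not None:
        write_volume(baseline_exp.like(result.changes.volume_change_pct),
                     os.path.join(d, "volume_change_pct.nii.gz"))
    result.summary.table.to_csv(os.path.join(d, "summary.csv"), float_format="%.6g")
    with open(os.path.join(d, "run_log.json"), "w") as fh:
        json.dump(
            {"subject": subject_id, "stages": result.stage_log,
             "misalignment_mm": result.misalignment_mm, "excluded": result.excluded,
             "config_hash": config.config_hash()},
            fh, indent=2,
        )


def run_cohort(
    config: PipelineConfig,
    subjects: list[tuple[VolumetricImage, VolumetricImage, VolumetricImage, PhantomTruth | None]],
) -> StudyResult:
    """Run :func:`run_subject` over a cohort and pool the statistics."""
    summaries = []
    for i, (insp, exp_img, fu, truth) in enumerate(subjects):
        res = run_subject(config, insp, exp_img, fu, truth=truth, subject_id=f"s{i:03d}")
        summaries.append(res.summary)
    study = run_study(summaries)
    if config.out_dir:
        build_report(study, config.out_dir, config_repr=repr(config))
    return study


def run_phantom_cohort(
    config: PipelineConfig,
    spec_template: PhantomSpec | None = None,
    n_subjects: int = 10,
    coupling_strength: float = 15.0,
    seed: int | None = None,
) -> StudyResult:
    """Generate a phantom cohort and analyze it under ``config``."""
    spec_template = spec_template or PhantomSpec.default()
    seed = config.seed if seed is None else seed
    cohort = make_cohort(spec_template, n_subjects, coupling_strength, seed=seed)
    return run_cohort(config, cohort)
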