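"""Serial structural change between baseline and follow-up inspiration CT.

Both inspiration scans are first warped to the baseline expiration grid
(the common anatomical reference), then:

* density change (HU) = follow-up − baseline, voxelwise; positive values
  mean densification (a fibrosis-progression signature);
* temporal volume change (%) = (det J_temporal − 1) · 100, from the Jacobian
  of the residual registration of the follow-up-warped image onto the
  baseline-warped image; negative values mean volume loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .deformation import jacobian_determinant
from .image import VolumetricImage
from .registration import DisplacementField

__all__ = ["ChangeMaps", "density_change", "temporal_volume_change", "FOLDING_WARN_FRACTION"]

#: Above this folding fraction the temporal Jacobian is suspect.
FOLDING_WARN_FRACTION = 0.01


@dataclass
class ChangeMaps:
    """Voxelwise longitudinal change on the expiration reference grid."""

    density_change_hu: np.ndarray | None = None
    volume_change_pct: np.ndarray | None = None
    valid: np.ndarray | None = None
    folding_fraction: float = 0.0
    warnings: list[str] = dataclass_field(default_factory=list)

    def merged_valid(self, *extra: np.ndarray) -> np.ndarray:
        masks = [m for m in (self.valid, *extra) if m is not None]
        out = masks[0].copy()
        for m in masks[1:]:
            out &= m
        return out


def density_change(
    baseline_insp_warped: VolumetricImage,
    followup_insp_warped: VolumetricImage,
    baseline_valid: np.ndarray | None = None,
    followup_valid: np.ndarray | None = None,
) -> ChangeMaps:
    """Voxelwise follow-up − baseline attenuation difference in HU."""
    if not baseline_insp_warped.same_grid(followup_insp_warped):
        raise ValueError("warped baseline and follow-up must share the expiration grid")
    diff = np.asarray(followup_insp_warped.data, dtype=float) - np.asarray(
        baseline_insp_warped.data, dtype=float
    )
    valid = np.ones(diff.shape, dtype=bool)
    if baseline_valid is not None:
        valid &= np.asarray(baseline_valid, dtype=bool)
    if followup_valid is not None:
        valid &= np.asarray(followup_valid, dtype=bool)
    return ChangeMaps(density_change_hu=diff, valid=valid)


def temporal_volume_change(temporal_field: DisplacementField) -> ChangeMaps:
    """Per-voxel volume change (%) from the temporal displacement field.

    The field comes from registering the follow-up-warped inspiration
    (moving) onto the baseline-warped inspiration (fixed), both on the
    expiration grid, so det J is the local follow-up/baseline volume ratio.
    """
    jm = jacobian_determinant(temporal_field, provenance="temporal")
    pct = (jm.values - 1.0) * 100.0
    cm = ChangeMaps(
        volume_change_pct=pct,
        valid=jm.values > 0,
        folding_fraction=jm.folding_fraction,
    )
    if jm.folding_fraction > FOLDING_WARN_FRACTION:
        cm.warnings.append(
            f"temporal field folding fraction {jm.folding_fraction:.3%} exceeds "
            f"{FOLDING_WARN_FRACTION:.0%}"
        )
    return cm


def combine(density: ChangeMaps, volume: ChangeMaps) -> ChangeMaps:
    """Merge density- and volume-change fragments into one map set."""
    valid = density.merged_valid() & volume.merged_valid()
    return ChangeMaps(
        density_change_hu=density.density_change_hu,
        volume_change_pct=volume.volume_change_pct,
        valid=valid,
        folding_fraction=volume.folding_fraction,
        warnings=[*density.warnings, *volume.warnings],
    )
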