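"""Normalized regional ventilation from paired breath-hold CT.

The per-voxel ventilation surrogate combines the deformation-based and the
density-based measurement:

    v = 1 − J_inv · ( HU_exp / HU_inspWarped )

where J_inv is the inverse Jacobian (local expiration/inspiration volume
ratio, ≤ 1 during exhale) of the inspiration→expiration registration and
the attenuation ratio acts as a density correction.  With raw signed HU
(air = −1000, tissue ≈ 0) the attenuation ratio equals the air-fraction
ratio, so v has the stated limits exactly: 0 for no volume change and 1 for
complete expiratory collapse.  An alternative physical-density mode using
HU + 1000 is available for sensitivity analysis.

Values are clamped to [0, 1] (the clamped fraction is reported, so heavy
clamping is visible) and binned into four categories:

    C1 = [0, 0.25)   low / non-ventilated (peribronchovascular)
    C2 = [0.25, 0.5) low-to-normal ventilation
    C3 = [0.5, 0.75) moderately increased ventilation
    C4 = [0.75, 1]   severely increased ventilation
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from enum import IntEnum

import numpy as np

from .deformation import JacobianMap
from .image import TissueClassMap, VolumetricImage

__all__ = [
    "CATEGORY_EDGES",
    "DENOMINATOR_GUARD_HU",
    "VentCategory",
    "VentilationMap",
    "compute_ventilation",
    "categorize",
]

#: Category bin edges on normalized ventilation.
CATEGORY_EDGES = (0.25, 0.5, 0.75)
#: Warped-inspiration attenuation magnitudes below this are unreliable denominators.
DENOMINATOR_GUARD_HU = 50.0


class VentCategory(IntEnum):
    INVALID = 0
    C1 = 1
    C2 = 2
    C3 = 3
    C4 = 4


@dataclass
class VentilationMap:
    """Normalized regional ventilation in [0, 1] plus category labels."""

    values: np.ndarray  # NaN where invalid
    valid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = dataclass_field(default_factory=lambda: np.eye(3))
    out_of_range_fraction: float = 0.0
    category_labels: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def category_counts(self) -> dict[str, int]:
        if self.category_labels is None:
            raise ValueError("categories not computed yet; call categorize()")
        n = np.bincount(self.category_labels.ravel(), minlength=5)
        return {c.name: int(n[c.value]) for c in VentCategory}


def compute_ventilation(
    exp_image: VolumetricImage,
    insp_warped: VolumetricImage,
    inverse_jacobian: JacobianMap,
    tissue: TissueClassMap,
    density_ratio_mode: str = "raw-hu",
    guard_hu: float = DENOMINATOR_GUARD_HU,
    warp_valid: np.ndarray | None = None,
) -> VentilationMap:
    """Voxelwise normalized regional ventilation on the expiration grid.

    Computed only on parenchymal (NAA ∪ HAA) voxels of ``tissue``; voxels
    with |denominator| below ``guard_hu`` or outside the warp domain are
    INVALID.  Results are clamped to [0, 1]; the clamped fraction (relative
    to valid voxels) is reported.
    """
    if not (exp_image.same_grid(insp_warped) and exp_image.shape == inverse_jacobian.shape
            and exp_image.shape == tissue.shape):
        raise ValueError("ventilation inputs must share the expiration grid")
    if density_ratio_mode not in ("raw-hu", "physical"):
        raise ValueError(f"unknown density_ratio_mode: {density_ratio_mode!r}")

    if density_ratio_mode == "raw-hu":
        num = np.asarray(exp_image.data, dtype=float)
        den = np.asarray(insp_warped.data, dtype=float)
    else:  # physical density ∝ HU + 1000
        num = np.asarray(exp_image.data, dtype=float) + 1000.0
        den = np.asarray(insp_warped.data, dtype=float) + 1000.0

    valid = tissue.analysis_mask & (np.abs(den) >= guard_hu)
    if warp_valid is not None:
        valid &= np.asarray(warp_valid, dtype=bool)
    if not valid.any():
        raise ValueError("no valid voxels for ventilation computation")

    v = np.full(exp_image.shape, np.nan)
    ratio = np.zeros_like(v)
    np.divide(num, den, out=ratio, where=valid)
    v[valid] = 1.0 - inverse_jacobian.values[valid] * ratio[valid]

    out_of_range = valid & ((v < 0) | (v > 1))
    frac = float(np.count_nonzero(out_of_range)) / float(np.count_nonzero(valid))
    v[valid] = np.clip(v[valid], 0.0, 1.0)

    return VentilationMap(
        values=v,
        valid=valid,
        spacing=exp_image.spacing,
        origin=exp_image.origin,
        direction=exp_image.direction.copy(),
        out_of_range_fraction=frac,
    )


def categorize(vmap: VentilationMap, edges: tuple[float, float, float] = CATEGORY_EDGES) -> VentilationMap:
    """Fill half-open category bins C1–C4 (top bin closed at 1) in place.

    INVALID propagates from the validity mask; per-category voxel counts are
    available as ``vmap.category_counts``.
    """
    e1, e2, e3 = edges
    if not (0.0 < e1 < e2 < e3 < 1.0):
        raise ValueError(f"category edges must be increasing inside (0,1), got {edges}")
    labels = np.zeros(vmap.shape, dtype=np.int8)
    v = vmap.values
    ok = vmap.valid & np.isfinite(v)
    labels[ok & (v < e1)] = VentCategory.C1
    labels[ok & (v >= e1) & (v < e2)] = VentCategory.C2
    labels[ok & (v >= e2) & (v < e3)] = VentCategory.C3
    labels[ok & (v >= e3)] = VentCategory.C4  # closed top edge: v = 1 → C4
    vmap.category_labels = labels
    return vmap
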