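"""Volumetric CT images in Hounsfield units: container, NIfTI I/O, lung
masking and attenuation-based tissue classification.

The attenuation classes follow the quantitative-CT conventions for
interstitial lung disease:

* ``EXCLUDED_LOW``  — HU < −950, emphysema-like low attenuation (LAA).
* ``NAA``           — −950 ≤ HU ≤ −600, normal attenuation areas.
* ``HAA``           — −600 < HU ≤ −250, high attenuation areas
  (ground-glass-like pathological parenchyma).
* ``EXCLUDED_HIGH`` — HU > −250, vessels / consolidation, removed from
  parenchymal analysis.

The NAA/HAA boundary is conventionally printed as "−599 HU" on integer CT
data; on continuous HU we treat NAA as the closed interval [−950, −600] and
HAA as (−600, −250] so no 1-HU gap is left unclassified.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import IntEnum

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "HU_LAA",
    "HU_NAA_HAA",
    "HU_VESSEL",
    "TissueClass",
    "VolumetricImage",
    "TissueClassMap",
    "read_volume",
    "write_volume",
    "make_lung_mask",
    "classify_tissue",
    "in_plane_voxel_size_mm",
]

#: Lower attenuation threshold (emphysema / air cysts), HU.
HU_LAA = -950.0
#: NAA/HAA boundary, HU.
HU_NAA_HAA = -600.0
#: Upper threshold (intrapulmonary vessels, consolidation), HU.
HU_VESSEL = -250.0


class TissueClass(IntEnum):
    """Per-voxel attenuation class labels."""

    OUTSIDE = 0
    EXCLUDED_LOW = 1
    NAA = 2
    HAA = 3
    EXCLUDED_HIGH = 4


@dataclass
class VolumetricImage:
    """A 3-D scalar grid in HU with physical-space metadata.

    Arrays are indexed ``(x, y, z)``; ``spacing``/``origin`` are in mm and
    ``direction`` holds direction cosines as a 3x3 matrix (world =
    ``origin + direction @ (index * spacing)``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3-D scalar volume, got {self.data.ndim}-D data"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 index→world affine."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumetricImage | TissueClassMap", atol: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, getattr(other, "direction", np.eye(3)), atol=atol)
        )

    def like(self, data: np.ndarray) -> "VolumetricImage":
        """New image with the same geometry and different voxel data."""
        return VolumetricImage(data, self.spacing, self.origin, self.direction.copy())

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World (mm) coordinate grids for each voxel centre (axis-aligned)."""
        axes = [self.origin[i] + self.spacing[i] * np.arange(self.shape[i]) for i in range(3)]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]


@dataclass
class TissueClassMap:
    """Per-voxel :class:`TissueClass` labels plus bookkeeping."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    direction: np.ndarray
    source: str = ""

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def counts(self) -> dict[str, int]:
        n = np.bincount(self.labels.ravel(), minlength=5)
        return {c.name: int(n[c.value]) for c in TissueClass}

    @property
    def analysis_mask(self) -> np.ndarray:
        """Boolean mask of parenchymal voxels entering the analysis (NAA ∪ HAA)."""
        return (self.labels == TissueClass.NAA) | (self.labels == TissueClass.HAA)

    @property
    def lung_mask(self) -> np.ndarray:
        return self.labels != TissueClass.OUTSIDE


def _decompose_affine(affine: np.ndarray):
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate affine: zero-length direction column")
    direction = m / spacing
    origin = affine[:3, 3]
    return tuple(spacing), tuple(origin), direction


def read_volume(path: str | os.PathLike) -> VolumetricImage:
    """Read a 3-D NIfTI volume.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        If the file is not a 3-D scalar volume or the header is unreadable.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header-error types
        raise ValueError(f"unreadable image header in {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D scalar data, got shape {data.shape}")
    spacing, origin, direction = _decompose_affine(img.affine)
    return VolumetricImage(data, spacing, origin, direction)


def write_volume(image: VolumetricImage, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz)."""
    out = nib.Nifti1Image(np.asarray(image.data, dtype=np.float32), image.affine)
    out.header.set_zooms(image.spacing)
    nib.save(out, str(path))


def make_lung_mask(
    image: VolumetricImage,
    method: str = "threshold",
    provided: np.ndarray | None = None,
    threshold_hu: float = HU_VESSEL,
) -> np.ndarray:
    """Build the lung mask.

    ``threshold`` mode keeps the largest connected component of voxels with
    HU below ``threshold_hu`` (default −250) and fills enclosed holes
    (intrapulmonary vessels).  ``provided`` mode passes a user mask through
    unchanged.
    """
    if method == "provided":
        if provided is None:
            raise ValueError("method='provided' requires a mask array")
        mask = np.asarray(provided).astype(bool)
        if mask.shape != image.shape:
            raise ValueError("provided mask shape does not match image")
        if not mask.any():
            raise ValueError("provided lung mask is empty")
        return mask
    if method != "threshold":
        raise ValueError(f"unknown lung mask method: {method!r}")

    candidate = image.data < threshold_hu
    if not candidate.any():
        raise ValueError("empty lung mask: no voxels below threshold")
    labels, nlab = ndimage.label(candidate)
    sizes = ndimage.sum_labels(np.ones(1), labels, index=np.arange(1, nlab + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return mask


def classify_tissue(image: VolumetricImage, lung_mask: np.ndarray) -> TissueClassMap:
    """Partition in-mask voxels into attenuation classes.

    Every in-mask voxel receives exactly one of {EXCLUDED_LOW, NAA, HAA,
    EXCLUDED_HIGH}; out-of-mask voxels are OUTSIDE.
    """
    lung_mask = np.asarray(lung_mask).astype(bool)
    if lung_mask.shape != image.shape:
        raise ValueError("lung mask geometry does not match image")
    hu = image.data
    labels = np.zeros(image.shape, dtype=np.int8)
    labels[lung_mask & (hu < HU_LAA)] = TissueClass.EXCLUDED_LOW
    labels[lung_mask & (hu >= HU_LAA) & (hu <= HU_NAA_HAA)] = TissueClass.NAA
    labels[lung_mask & (hu > HU_NAA_HAA) & (hu <= HU_VESSEL)] = TissueClass.HAA
    labels[lung_mask & (hu > HU_VESSEL)] = TissueClass.EXCLUDED_HIGH
    return TissueClassMap(
        labels=labels,
        spacing=image.spacing,
        origin=image.origin,
        direction=image.direction.copy(),
        source="classify_tissue",
    )


def in_plane_voxel_size_mm(field_of_view_mm: float, matrix: int) -> float:
    """In-plane voxel size for a reconstruction field of view and matrix,
    rounded to the 0.01 mm conventionally printed (35 cm / 512 → 0.68 mm)."""
    if field_of_view_mm <= 0 or matrix <= 0:
        raise ValueError("field of view and matrix must be positive")
    return round(field_of_view_mm / matrix, 2)
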