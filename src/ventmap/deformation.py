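"""Jacobian-determinant maps of displacement fields.

For a displacement field u(x) in mm on the reference grid, the Jacobian map
holds det(I + ∇u) with the gradient taken in physical coordinates
(spacing-aware finite differences: central at interior voxels, one-sided at
the boundary).  With fields stored as expiration-grid → inspiration maps the
determinant is the local inspiration/expiration volume ratio V_insp/V_exp
(≥ 1 during exhale); the ventilation equation consumes its reciprocal — the
"inverse Jacobian", the expiration/inspiration volume ratio in (0, 1] —
obtained with :func:`invert_jacobian`.

Anisotropic voxels (e.g. 0.68 × 0.68 × 1 mm) are handled by differentiating
in mm, not index units.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .registration import DisplacementField

__all__ = ["JacobianMap", "jacobian_determinant", "invert_jacobian"]


@dataclass
class JacobianMap:
    """Scalar det(I + ∇u) grid plus folding/clamping bookkeeping."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = dataclass_field(default_factory=lambda: np.eye(3))
    provenance: str = ""
    folding_fraction: float = 0.0
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Jacobian values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def like(self, values: np.ndarray, provenance: str = "") -> "JacobianMap":
        return JacobianMap(
            values, self.spacing, self.origin, self.direction.copy(),
            provenance or self.provenance,
        )


def jacobian_determinant(field: DisplacementField, provenance: str = "") -> JacobianMap:
    """Voxelwise det(I + ∇u) of a displacement field.

    Requires ≥ 3 voxels per axis (central differences in the interior).  The
    fraction of non-positive (folding) voxels is reported on the map.
    """
    shape = field.shape
    if min(shape) < 3:
        raise ValueError(f"field grid {shape} too small for finite differences (need ≥ 3 per axis)")
    if not np.allclose(field.direction, np.eye(3), atol=1e-6):
        raise ValueError("jacobian_determinant requires an axis-aligned reference grid")
    u = field.vectors
    sp = field.spacing

    # F[i][j] = δ_ij + ∂u_i/∂x_j, gradients in mm
    grad = [[None] * 3 for _ in range(3)]
    for i in range(3):
        gs = np.gradient(u[..., i], *sp, edge_order=1)
        for j in range(3):
            grad[i][j] = gs[j]
    f = [[grad[i][j] + (1.0 if i == j else 0.0) for j in range(3)] for i in range(3)]

    det = (
        f[0][0] * (f[1][1] * f[2][2] - f[1][2] * f[2][1])
        - f[0][1] * (f[1][0] * f[2][2] - f[1][2] * f[2][0])
        + f[0][2] * (f[1][0] * f[2][1] - f[1][1] * f[2][0])
    )
    jm = JacobianMap(
        det, field.spacing, field.origin, field.direction.copy(), provenance
    )
    jm.folding_fraction = float(np.mean(det <= 0))
    return jm


def invert_jacobian(jmap: JacobianMap, floor: float = 0.05) -> JacobianMap:
    """Voxelwise reciprocal of a Jacobian map.

    Values below ``floor`` are clamped to it before inversion (clamping
    policy, not an error); the clamp count is carried on the result.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    vals = np.asarray(jmap.values, dtype=float)
    clamped = vals < floor
    out = 1.0 / np.maximum(vals, floor)
    res = jmap.like(out, provenance=f"1/({jmap.provenance or 'jacobian'})")
    res.n_clamped = int(np.count_nonzero(clamped))
    res.folding_fraction = jmap.folding_fraction
    return res
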