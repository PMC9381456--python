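"""Digital lung phantoms with known ventilation, deformation and progression.

Each phantom is a triplet of breath-hold CT volumes — baseline inspiration,
baseline expiration, follow-up inspiration — generated from a one-compartment
air/tissue mixture model:

* a voxel's air fraction is β = −HU/1000 (air −1000 HU, tissue ≈ 0 HU);
* tissue volume is conserved between breath-holds, all volume change is air;
* a smooth ground-truth ventilation field v*(x) ∈ [0, 1] gives the exhaled
  air fraction, so the local expiration/inspiration volume ratio is
  J* = 1 − v*·β_insp, the expiratory air fraction is
  β_exp = β_insp·(1 − v*)/J*, and HU_exp = −1000·β_exp.

Under this model the regional-ventilation equation
``v = 1 − J·(HU_exp/HU_insp)`` inverts the generator exactly, which gives a
sharp recovery target for the analysis pipeline.

A smooth driving field (base level + apico-basal gradient + focal hot
spots, taking the place of v* above with a spatially smoothed air fraction)
sets the target volume-change field J*.  The expiratory deformation is
realized as a lung-centre-anchored sequential contraction along all three
axes, each targeting J*^(1/3), so the composed analytic Jacobian equals J*
while per-axis strains stay physiological; the finite-difference residual
of the discrete realization is reported on the truth object.  The
expiration image is then defined from the actually-warped inspiration image
by exact tissue-mass scaling, τ_exp = τ_insp/J* with τ = 1 + HU/1000, and
the stored truth ventilation is the realized per-voxel exhaled fraction
v = (1 − J*)/β_insp.  Both the ventilation-equation identity and tissue-mass
conservation therefore hold voxel-exactly on the noise-free variant; noise
is added after deformation.

Follow-up inspiration plants a monotone coupling between the baseline
ventilation category and structural progression: a density offset (HU) and
a volume-scaling contraction per category, plus noise.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from .deformation import jacobian_determinant
from .image import TissueClassMap, VolumetricImage, classify_tissue, write_volume
from .registration import DisplacementField, warp, write_field
from .ventilation import CATEGORY_EDGES

__all__ = [
    "PhantomError",
    "VentilationFieldParams",
    "ProgressionModel",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "mass_conservation",
    "make_cohort",
    "write_phantom",
]


class PhantomError(ValueError):
    """Raised for infeasible phantom specifications."""


def mass_conservation(hu_insp: float, exhaled_fraction: float) -> tuple[float, float]:
    """Closed-form one-compartment exhale model for a single voxel.

    Given inspiratory attenuation and the exhaled fraction of its air,
    returns ``(J, HU_exp)``: the expiration/inspiration volume ratio
    J = 1 − v·β and the expiratory attenuation −1000·β·(1 − v)/J.  At v = 1
    the voxel loses all air: J = 1 − β and HU_exp = 0 (complete collapse);
    at v = 0 nothing changes.
    """
    beta = -hu_insp / 1000.0
    if not 0.0 <= beta <= 1.0:
        raise PhantomError(f"inspiratory HU {hu_insp} outside the air/tissue range")
    if not 0.0 <= exhaled_fraction <= 1.0:
        raise PhantomError(f"exhaled fraction {exhaled_fraction} outside [0, 1]")
    j = 1.0 - exhaled_fraction * beta
    hu_exp = -1000.0 * beta * (1.0 - exhaled_fraction) / j if j > 0 else 0.0
    return j, hu_exp


@dataclass
class VentilationFieldParams:
    """Smooth ground-truth ventilation field v*(x).

    v* = base + apico-basal gradient + focal hot spots + smooth random
    texture, tapered to zero over ``edge_taper_mm`` at the pleural boundary
    (mimicking the poorly ventilated peribronchovascular/peripheral rim) and
    clipped to [0, 1].  Defaults target the ventilation-category volume
    fractions reported for fibrotic lungs: roughly C2 ≈ 23 %, C3 ≈ 53 %,
    C4 ≈ 22 % with a small C1 rim.
    """

    base: float = 0.65
    apicobasal_span: float = 0.40  # v* increases toward the lung base (+z)
    hotspots: list[tuple[tuple[float, float, float], float, float]] = dataclass_field(
        default_factory=list
    )  # (center mm, sigma mm, amplitude)
    texture_sd: float = 0.0  # optional random modulation; 0 keeps the field smooth
    texture_corr_mm: float = 12.0
    edge_taper_mm: float = 0.8


@dataclass
class ProgressionModel:
    """Planted baseline-ventilation → follow-up change coupling.

    Density gains (HU) and volume changes (%) are keyed by the ground-truth
    ventilation category at baseline; C1 voxels are treated as
    non-ventilating and get no planted change.  Defaults emulate the
    magnitudes reported for normal-attenuation fibrotic lung: density gains
    of roughly +24/+32/+58 HU and volume changes of +2.2/−0.8/−3.7 % for
    C2/C3/C4.
    """

    density_gain_hu: dict[str, float] = dataclass_field(
        default_factory=lambda: {"C2": 24.0, "C3": 32.0, "C4": 58.0}
    )
    volume_change_pct: dict[str, float] = dataclass_field(
        default_factory=lambda: {"C2": 2.25, "C3": -0.8, "C4": -3.74}
    )
    density_noise_sd: float = 15.0
    enabled: bool = True


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_center_mm: tuple[float, float, float] | None = None  # default: grid centre
    lung_semi_axes_mm: tuple[float, float, float] | None = None
    naa_base_hu: float = -850.0
    body_hu: float = 40.0
    hu_noise_sd: float = 25.0
    exp_noise_sd: float = 12.0
    parenchymal_texture: list[tuple[float, float]] = dataclass_field(
        default_factory=list
    )  # (correlation mm, SD HU): multi-scale vascular-like anatomy texture
    haa_patches: list[tuple[tuple[float, float, float], float, float]] = dataclass_field(
        default_factory=list
    )  # (center mm, radius mm, HU in (−600, −250])
    vessel_tubes: list[tuple[int, tuple[float, float], float, float]] = dataclass_field(
        default_factory=list
    )  # (axis, in-plane point mm, radius mm, HU > −250)
    emphysema_blobs: list[tuple[tuple[float, float, float], float, float]] = dataclass_field(
        default_factory=list
    )  # (center mm, radius mm, HU < −950)
    ventilation: VentilationFieldParams = dataclass_field(default_factory=VentilationFieldParams)
    progression: ProgressionModel = dataclass_field(default_factory=ProgressionModel)
    map_smoothing_mm: float = 4.0  # smoothing of the air fraction / progression ratio
    jacobian_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise PhantomError(f"grid_shape must be ≥ 16 per axis, got {self.grid_shape}")
        extent = [self.spacing[i] * (self.grid_shape[i] - 1) for i in range(3)]
        if self.lung_center_mm is None:
            self.lung_center_mm = tuple(e / 2 for e in extent)
        if self.lung_semi_axes_mm is None:
            self.lung_semi_axes_mm = tuple(0.5 * e - 3.0 * self.spacing[i] for i, e in enumerate(extent))
        for i in range(3):
            lo = self.lung_center_mm[i] - self.lung_semi_axes_mm[i]
            hi = self.lung_center_mm[i] + self.lung_semi_axes_mm[i]
            if lo < 2 * self.spacing[i] or hi > extent[i] - 2 * self.spacing[i]:
                raise PhantomError(
                    f"lung ellipsoid does not fit inside the grid with a 2-voxel margin on axis {i}"
                )

    @classmethod
    def default(
        cls,
        grid_shape: tuple[int, int, int] = (64, 64, 64),
        spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
        seed: int = 0,
        with_structures: bool = True,
    ) -> "PhantomSpec":
        """A spec with lung structures (HAA patches, vessels, emphysema)
        placed at fixed fractional positions of the lung, so the same
        anatomy scales to any grid size."""
        spec = cls(grid_shape=grid_shape, spacing=spacing, seed=seed)
        c = np.asarray(spec.lung_center_mm)
        a = np.asarray(spec.lung_semi_axes_mm)
        # keep structure scales proportional to lung size so small desk-scale
        # grids carry the same relative anatomy
        scale = float(a.min()) / 44.0
        spec.ventilation.texture_corr_mm = 12.0 * scale
        spec.map_smoothing_mm = 4.0 * scale
        spec.parenchymal_texture = [
            (25.0 * scale, 30.0), (12.0 * scale, 35.0), (6.0 * scale, 45.0)
        ]
        if with_structures:
            rel = lambda f: tuple(c + np.asarray(f) * a)  # noqa: E731
            spec.haa_patches = [
                (rel((0.45, 0.3, -0.35)), 0.30 * a.min(), -400.0),
                (rel((-0.4, -0.45, 0.3)), 0.25 * a.min(), -450.0),
                (rel((0.1, -0.3, 0.55)), 0.20 * a.min(), -350.0),
            ]
            spec.vessel_tubes = [
                (2, (c[0] - 0.35 * a[0], c[1] + 0.1 * a[1]), 0.07 * a.min(), -50.0),
                (1, (c[0] + 0.3 * a[0], c[2] - 0.2 * a[2]), 0.06 * a.min(), -80.0),
            ]
            spec.emphysema_blobs = [(rel((-0.3, 0.4, -0.5)), 0.15 * a.min(), -980.0)]
            spec.ventilation.hotspots = [
                (rel((0.35, -0.35, 0.45)), 0.5 * a.min(), 0.14),
                (rel((-0.45, 0.25, 0.35)), 0.5 * a.min(), 0.14),
            ]
        return spec


def _stats_default(
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    seed: int = 0,
) -> PhantomSpec:
    """Spec for statistical-calibration cohorts: homogeneous normal
    parenchyma (no focal structures, no anatomy texture), smooth ventilation
    field with hot spots.  Calibration of the paired-contrast machinery
    should not be confounded by the boundary/partial-volume measurement
    systematics that structured phantoms probe separately."""
    spec = PhantomSpec.default(grid_shape=grid_shape, seed=seed, with_structures=False)
    spec.parenchymal_texture = []
    c = np.asarray(spec.lung_center_mm)
    a = np.asarray(spec.lung_semi_axes_mm)
    rel = lambda f: tuple(c + np.asarray(f) * a)  # noqa: E731
    spec.ventilation.hotspots = [
        (rel((0.35, -0.35, 0.45)), 0.5 * a.min(), 0.14),
        (rel((-0.45, 0.25, 0.35)), 0.5 * a.min(), 0.14),
    ]
    return spec


PhantomSpec.stats_default = staticmethod(_stats_default)


@dataclass
class PhantomTruth:
    """Ground-truth grids of one phantom, on the expiration reference grid
    unless suffixed ``_insp``."""

    ventilation_field: np.ndarray  # v* on the expiration grid
    ventilation_field_insp: np.ndarray
    insp_to_exp_displacement: DisplacementField
    insp_to_exp_jacobian: np.ndarray  # J* = local expiration/inspiration volume ratio, ≤ 1
    followup_to_exp_displacement: DisplacementField  # breathing-only (see module docs)
    temporal_displacement: DisplacementField
    temporal_density_change: np.ndarray  # planted expectation, HU
    temporal_volume_change: np.ndarray  # planted expectation, %
    tissue_class: TissueClassMap
    lung_mask_exp: np.ndarray
    lung_mask_insp: np.ndarray
    insp_noisefree: np.ndarray
    insp_warped_noisefree: np.ndarray
    hu_exp_noisefree: np.ndarray
    jacobian_fit_residual: float
    class_fractions_insp: dict[str, float]


# --- per-column map machinery ------------------------------------------------
# Breathing is realized as a sequential per-axis contraction T = Tz∘Ty∘Tx,
# each factor a monotone 1-D map per grid column targeting J*^(1/3), so the
# composed Jacobian determinant equals J* while per-axis strains stay
# moderate (diaphragm plus chest-wall motion rather than a single-axis
# collapse).  The planted progression map acts along z only (it is small).

def _cumulative_map(
    j: np.ndarray, coord: np.ndarray, axis: int, anchor: float | None = None
) -> np.ndarray:
    """c′(c) = ∫ J dc along each column of ``axis``; strictly increasing for
    J > 0.  ``anchor`` fixes the plane c = anchor (e.g. the lung centre, so
    contraction spreads symmetrically); default anchors the column start."""
    f = coord[0] + cumulative_trapezoid(j, coord, axis=axis, initial=0.0)
    if anchor is not None:
        dc = coord[1] - coord[0]
        idx = np.clip((anchor - coord[0]) / dc, 0.0, len(coord) - 1 - 1e-9)
        i0, w = int(idx), idx - int(idx)
        fm = np.moveaxis(f, axis, -1)
        f_anchor = fm[..., i0] * (1 - w) + fm[..., i0 + 1] * w
        f = f - np.expand_dims(f_anchor, axis) + anchor
    return f


def _invert_monotone(
    f: np.ndarray, coord: np.ndarray, targets: np.ndarray, axis: int
) -> np.ndarray:
    """Per-column inverse of a strictly increasing map ``f`` sampled on
    ``coord`` along ``axis``: returns g with f(g) = targets (linear
    interpolation, linear edge extrapolation)."""
    fm = np.moveaxis(f, axis, -1)
    n = fm.shape[-1]
    dc = coord[1] - coord[0]
    k = np.sum(fm[..., :, None] < targets.reshape((1,) * fm.ndim + (-1,))[0], axis=-2)
    k = np.clip(k, 1, n - 1)
    f0 = np.take_along_axis(fm, k - 1, axis=-1)
    f1 = np.take_along_axis(fm, k, axis=-1)
    w = (targets - f0) / (f1 - f0)
    g = coord[0] + (k - 1 + w) * dc
    return np.moveaxis(g, -1, axis)


def _sample_z(arr: np.ndarray, zq: np.ndarray, z0: float, dz: float) -> np.ndarray:
    """Linear interpolation of ``arr`` along axis 2 at z-coordinates ``zq``
    (same leading shape), clamped to the grid."""
    nz = arr.shape[2]
    idx = np.clip((zq - z0) / dz, 0.0, nz - 1 - 1e-9)
    i0 = idx.astype(np.int64)
    w = idx - i0
    a0 = np.take_along_axis(arr, i0, axis=2)
    a1 = np.take_along_axis(arr, i0 + 1, axis=2)
    return a0 * (1.0 - w) + a1 * w


def _samp(arr: np.ndarray, px: np.ndarray, py: np.ndarray, pz: np.ndarray,
          spacing) -> np.ndarray:
    """Trilinear sampling of ``arr`` at world-mm points (origin 0)."""
    return ndimage.map_coordinates(
        arr, [px / spacing[0], py / spacing[1], pz / spacing[2]],
        order=1, mode="nearest",
    )


def _build_breathing_maps(j_insp: np.ndarray, axes: list[np.ndarray], spacing,
                          anchor: tuple[float, float, float] | None = None):
    """Construct the three-axis contraction realizing det = J*.

    Returns ``(u_inv, d_fwd)``: the inverse displacement (expiration grid →
    inspiration points) and the forward displacement (inspiration grid →
    expiration points), both in mm.
    """
    x, y, z = axes
    anchor = anchor or (None, None, None)
    ja = np.cbrt(j_insp)
    gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")

    # Tx: contract along x; target det Jx at inspiration coords
    x1 = _cumulative_map(ja, x, axis=0, anchor=anchor[0])
    xi = _invert_monotone(x1, x, x, axis=0)  # x-inverse on the (x',y,z) grid

    # Ty: target det Jy at T1^{-1}
    a2 = _samp(ja, xi, gy, gz, spacing)
    y2 = _cumulative_map(a2, y, axis=1, anchor=anchor[1])
    yi = _invert_monotone(y2, y, y, axis=1)

    # Tz: target det Jz at (T2∘T1)^{-1}
    y0g = yi
    x0g = _samp(xi, gx, y0g, gz, spacing)
    a3 = _samp(ja, x0g, y0g, gz, spacing)
    z3 = _cumulative_map(a3, z, axis=2, anchor=anchor[2])
    zi = _invert_monotone(z3, z, z, axis=2)

    # inverse map S = Tx^{-1} ∘ Ty^{-1} ∘ Tz^{-1} on the expiration grid
    z0 = zi
    y0 = _samp(yi, gx, gy, z0, spacing)
    x0 = _samp(xi, gx, y0, z0, spacing)
    u_inv = np.stack([x0 - gx, y0 - gy, z0 - gz], axis=-1)

    # forward map Φ = Tz ∘ Ty ∘ Tx on the inspiration grid
    px = x1
    py = _samp(y2, px, gy, gz, spacing)
    pz = _samp(z3, px, py, gz, spacing)
    d_fwd = np.stack([px - gx, py - gy, pz - gz], axis=-1)
    return u_inv, d_fwd


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _soft_saturate(v: np.ndarray, hi: float = 0.96, knee: float = 0.16) -> np.ndarray:
    """C¹ squashing of the upper range into (·, hi): identity below
    ``hi − knee``, tanh saturation above.  Keeps the ventilation field
    smooth where it would clip at 1 (a hard clip puts kinks into the
    Jacobian) and bounds the exhale Jacobian away from zero.  The lower
    bound stays a hard floor at 0 so a zero field stays exactly zero."""
    b = hi - knee
    out = np.maximum(np.asarray(v, dtype=float), 0.0)
    top = out > b
    out[top] = b + knee * np.tanh((out[top] - b) / knee)
    return out


def _categorize_truth(v: np.ndarray) -> np.ndarray:
    """Category index 1..4 of ground-truth ventilation (0 outside lung/v=0)."""
    e1, e2, e3 = CATEGORY_EDGES
    cat = np.ones(v.shape, dtype=np.int8)
    cat[v >= e1] = 2
    cat[v >= e2] = 3
    cat[v >= e3] = 4
    return cat


# --- generator ---------------------------------------------------------------

def _build_class_image(
    spec: PhantomSpec, x, y, z3, lung: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    hu = np.full(spec.grid_shape, spec.body_hu, dtype=float)
    hu[lung] = spec.naa_base_hu
    # multi-scale correlated texture: the vascular/septal structure real lung
    # parenchyma shows at every scale; it is anatomy (it deforms with the
    # lung), distinct from scanner noise, and it is what image registration
    # locks onto
    if spec.parenchymal_texture:
        add = np.zeros(spec.grid_shape)
        for corr, sd_hu in spec.parenchymal_texture:
            noise = rng.standard_normal(spec.grid_shape)
            sig = [max(corr / s, 0.5) for s in spec.spacing]
            noise = ndimage.gaussian_filter(noise, sig)
            sd = float(np.prod([1.0 / np.sqrt(2.0 * np.sqrt(np.pi) * s) for s in sig]))
            add += (sd_hu / sd) * noise
        hu[lung] += add[lung]
    for center, radius, val in spec.haa_patches:
        d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z3 - center[2]) ** 2
        hu[(d2 <= radius**2) & lung] = val
    for center, radius, val in spec.emphysema_blobs:
        d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z3 - center[2]) ** 2
        hu[(d2 <= radius**2) & lung] = val
    for axis, point, radius, val in spec.vessel_tubes:
        planes = [c for i, c in enumerate((x, y, z3)) if i != axis]
        d2 = (planes[0] - point[0]) ** 2 + (planes[1] - point[1]) ** 2
        hu[(d2 <= radius**2) & lung] = val
    return np.maximum(hu, -1000.0)  # nothing is less attenuating than air


def _build_ventilation(
    spec: PhantomSpec, x, y, z3, lung: np.ndarray, rho: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    p = spec.ventilation
    c = spec.lung_center_mm
    a = spec.lung_semi_axes_mm
    v = p.base + p.apicobasal_span * (z3 - c[2]) / (2.0 * a[2])
    for center, sigma, amp in p.hotspots:
        d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z3 - center[2]) ** 2
        v = v + amp * np.exp(-0.5 * d2 / sigma**2)
    if p.texture_sd > 0:
        noise = rng.standard_normal(spec.grid_shape)
        sig = [max(p.texture_corr_mm / s, 0.5) for s in spec.spacing]
        noise = ndimage.gaussian_filter(noise, sig)
        # smoothing iid unit noise leaves variance ∏ 1/(2√π σ_i); rescale
        # analytically (the in-lung empirical SD is unstable on small grids)
        sd = float(np.prod([1.0 / np.sqrt(2.0 * np.sqrt(np.pi) * s) for s in sig]))
        v = v + noise * (p.texture_sd / sd)
    if v[lung].min() < -0.5 or v[lung].max() > 1.5:
        raise PhantomError(
            "ventilation field parameters produce values far outside [0, 1]; "
            f"raw range [{v[lung].min():.2f}, {v[lung].max():.2f}]"
        )
    # taper to zero at the pleural boundary; distance approximated from the
    # ellipsoid coordinate
    d_boundary = (1.0 - rho) * min(a)
    v = _soft_saturate(v) * _smoothstep(d_boundary / max(p.edge_taper_mm, 1e-6))
    v[~lung] = 0.0
    return v


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VolumetricImage, VolumetricImage, VolumetricImage, PhantomTruth]:
    """Generate one phantom triplet plus ground truth.

    Returns ``(baseline_insp, baseline_exp, followup_insp, truth)``.
    Deterministic for a given spec (all randomness from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing
    axes = [sp[i] * np.arange(spec.grid_shape[i]) for i in range(3)]
    x, y, z3 = np.meshgrid(*axes, indexing="ij")
    z = axes[2]
    dz = sp[2]
    c = spec.lung_center_mm
    a = spec.lung_semi_axes_mm
    rho = np.sqrt(
        ((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((z3 - c[2]) / a[2]) ** 2
    )
    lung = rho <= 1.0

    hu_nf = _build_class_image(spec, x, y, z3, lung, rng)
    v_drive = _build_ventilation(spec, x, y, z3, lung, rho, rng)

    # smooth air fraction drives the deformation so the field is smooth even
    # across tissue-class boundaries
    beta = np.clip(-hu_nf / 1000.0, 0.0, 1.0)
    sig = [spec.map_smoothing_mm / s for s in sp]
    beta_s = ndimage.gaussian_filter(beta, sig)
    j_insp = 1.0 - v_drive * beta_s
    if j_insp.min() <= spec.jacobian_floor:
        raise PhantomError(
            f"infeasible exhale: J* reaches {j_insp.min():.3f} ≤ floor {spec.jacobian_floor}"
        )

    insp_nf = VolumetricImage(hu_nf, sp)
    hu_noisy = hu_nf if spec.hu_noise_sd == 0 else hu_nf + rng.normal(0, spec.hu_noise_sd, hu_nf.shape)
    insp = VolumetricImage(hu_noisy, sp)

    # breathing map: three-axis contraction with det = J*, anchored at the
    # lung centre so contraction spreads symmetrically
    u, d_fwd = _build_breathing_maps(j_insp, axes, sp, anchor=tuple(c))
    field = DisplacementField(u, sp)

    sx, sy, sz = x + u[..., 0], y + u[..., 1], z3 + u[..., 2]  # S(x_e)
    j_exp = _samp(j_insp, sx, sy, sz, sp)
    rho_exp = np.sqrt(
        ((sx - c[0]) / a[0]) ** 2 + ((sy - c[1]) / a[1]) ** 2 + ((sz - c[2]) / a[2]) ** 2
    )
    lung_exp = rho_exp <= 1.0

    # expiration HU by exact tissue-mass scaling: τ_exp = τ_insp / J*.  The
    # realized per-voxel exhaled fraction is then v = (1 − J*)/β_insp with
    # the *actual* warped air fraction, so mass conservation and the
    # ventilation-equation identity both hold voxel-exactly.
    insp_warped_nf, _ = warp(insp_nf, field)
    insp_warped_noisy, _ = warp(insp, field)
    hu_exp_nf = (1000.0 + insp_warped_nf.data) / j_exp - 1000.0
    hu_exp = (1000.0 + insp_warped_noisy.data) / j_exp - 1000.0
    if spec.exp_noise_sd > 0:
        hu_exp = hu_exp + rng.normal(0, spec.exp_noise_sd, hu_exp.shape)
    exp_img = VolumetricImage(hu_exp, sp)

    beta_w_nf = np.clip(-insp_warped_nf.data / 1000.0, 0.0, 1.0)
    v_exp = np.clip((1.0 - j_exp) / np.maximum(beta_w_nf, 0.05), 0.0, 1.0)
    v_exp[~lung_exp] = 0.0
    beta_nf = np.clip(-hu_nf / 1000.0, 0.0, 1.0)
    v_insp = np.clip((1.0 - j_insp) / np.maximum(beta_nf, 0.05), 0.0, 1.0)
    v_insp[~lung] = 0.0

    # planted progression keyed to the baseline ventilation category
    prog = spec.progression
    cat_insp = _categorize_truth(v_insp)
    cat_insp[~lung] = 0
    gains = np.zeros(spec.grid_shape)
    jt = np.ones(spec.grid_shape)
    if prog.enabled:
        for name, idx in (("C2", 2), ("C3", 3), ("C4", 4)):
            sel = cat_insp == idx
            gains[sel] = prog.density_gain_hu.get(name, 0.0)
            jt[sel] = 1.0 + prog.volume_change_pct.get(name, 0.0) / 100.0
        jt = ndimage.gaussian_filter(jt, sig)
        if jt.min() <= 0:
            raise PhantomError(
                f"infeasible progression: volume loss implies temporal J = {jt.min():.3f} ≤ 0"
            )

    zf = _cumulative_map(jt, z, axis=2)  # baseline z → follow-up z (z-only, small)
    zb_at_f = _invert_monotone(zf, z, z, axis=2)
    followup_data = _sample_z(hu_noisy + gains, zb_at_f, z[0], dz)
    if prog.density_noise_sd > 0:
        followup_data = followup_data + rng.normal(0, prog.density_noise_sd, followup_data.shape)
    followup = VolumetricImage(followup_data, sp)

    # Truth warp for the follow-up scan: the composed map T_bf ∘ S, i.e. the
    # anatomical correspondence an ideal follow-up→expiration registration
    # would find (progression absorbed, boundaries aligned); the warped
    # follow-up then differs from the warped baseline by the planted density
    # gains only.
    zf_of_exp = _samp(zf, sx, sy, sz, sp)  # T_bf moves z only
    u_fu = np.stack([sx - x, sy - y, zf_of_exp - z3], axis=-1)

    # temporal truth on the expiration grid: u_t = Φ ∘ T_bf ∘ S − id, whose
    # Jacobian is the planted follow-up/baseline volume ratio (≈ J_t); this
    # is the progression residual an ideal temporal registration measures.
    # With no progression the composition is the identity analytically, so
    # skip the (slightly lossy) numerical evaluation outright.
    if prog.enabled and np.any(jt != 1.0):
        u_t = np.empty((*spec.grid_shape, 3))
        u_t[..., 0] = sx + _samp(d_fwd[..., 0], sx, sy, zf_of_exp, sp) - x
        u_t[..., 1] = sy + _samp(d_fwd[..., 1], sx, sy, zf_of_exp, sp) - y
        u_t[..., 2] = zf_of_exp + _samp(d_fwd[..., 2], sx, sy, zf_of_exp, sp) - z3
    else:
        u_t = np.zeros((*spec.grid_shape, 3))
    temporal_field = DisplacementField(u_t, sp)

    jt_exp = _samp(jt, sx, sy, sz, sp)
    gains_exp = _samp(gains, sx, sy, sz, sp)

    tissue_truth = classify_tissue(VolumetricImage(insp_warped_nf.data, sp), lung_exp)

    det_fd = jacobian_determinant(field).values
    core = ndimage.binary_erosion(lung_exp, iterations=2)
    resid = float(np.max(np.abs(1.0 / det_fd[core] - j_exp[core]))) if core.any() else 0.0

    n_lung = int(np.count_nonzero(lung))
    cls_nf = classify_tissue(insp_nf, lung)
    frac = {k: v / n_lung for k, v in cls_nf.counts.items() if k != "OUTSIDE"}

    truth = PhantomTruth(
        ventilation_field=v_exp,
        ventilation_field_insp=v_insp,
        insp_to_exp_displacement=field,
        insp_to_exp_jacobian=j_exp,
        followup_to_exp_displacement=DisplacementField(u_fu, sp),
        temporal_displacement=temporal_field,
        temporal_density_change=gains_exp,
        temporal_volume_change=(jt_exp - 1.0) * 100.0,
        tissue_class=tissue_truth,
        lung_mask_exp=lung_exp,
        lung_mask_insp=lung,
        insp_noisefree=hu_nf,
        insp_warped_noisefree=insp_warped_nf.data,
        hu_exp_noisefree=hu_exp_nf,
        jacobian_fit_residual=resid,
        class_fractions_insp=frac,
    )
    return insp, exp_img, followup, truth


# --- cohorts -----------------------------------------------------------------

def make_cohort(
    spec_template: PhantomSpec,
    n_subjects: int,
    coupling_strength: float = 15.0,
    seed: int = 0,
    between_subject_sd_hu: float = 10.0,
    volume_coupling_pct: float | None = None,
    between_subject_sd_pct: float = 1.0,
) -> list[tuple[VolumetricImage, VolumetricImage, VolumetricImage, PhantomTruth]]:
    """Generate a cohort of phantoms with randomized geometry and texture.

    ``coupling_strength`` is the planted density gain in HU per ventilation
    category step, i.e. the planted C4 − C2 density difference is
    2·coupling_strength; per-subject gains are jittered with
    ``between_subject_sd_hu``.  The volume plant follows the same linear
    pattern with ``volume_coupling_pct`` per category step (default scaled
    from the density coupling), negative = loss.  ``coupling_strength = 0``
    is the null model: no expected difference between categories.
    Deterministic given ``seed``.
    """
    if n_subjects < 2:
        raise PhantomError("a cohort needs at least 2 subjects")
    if volume_coupling_pct is None:
        volume_coupling_pct = coupling_strength * (1.85 / 15.0)
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        spec = _randomized_spec(spec_template, rng)
        gj = rng.normal(0, between_subject_sd_hu, 3)
        vj = rng.normal(0, between_subject_sd_pct, 3)
        spec.progression = ProgressionModel(
            density_gain_hu={
                "C2": 0.0 + gj[0],
                "C3": coupling_strength + gj[1],
                "C4": 2.0 * coupling_strength + gj[2],
            },
            volume_change_pct={
                "C2": 0.0 + vj[0],
                "C3": -volume_coupling_pct + vj[1],
                "C4": -2.0 * volume_coupling_pct + vj[2],
            },
            density_noise_sd=spec_template.progression.density_noise_sd,
            enabled=True,
        )
        spec.seed = int(rng.integers(0, 2**31 - 1))
        out.append(generate_phantom(spec))
    return out


def _randomized_spec(template: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Jitter lung geometry, ventilation level and hot-spot placement."""
    spec = dataclasses.replace(template)
    spec.ventilation = dataclasses.replace(template.ventilation)
    a0 = np.asarray(template.lung_semi_axes_mm)
    scale = rng.uniform(0.92, 1.05, 3)
    semi = a0 * scale
    extent = np.asarray([spec.spacing[i] * (spec.grid_shape[i] - 1) for i in range(3)])
    center = np.asarray(template.lung_center_mm)
    semi = np.minimum(semi, np.minimum(center, extent - center) - 2.01 * np.asarray(spec.spacing))
    spec.lung_semi_axes_mm = tuple(semi)
    spec.ventilation.base = template.ventilation.base + rng.normal(0, 0.03)
    # re-place structures at new fractional positions
    c, a = center, semi
    rel = lambda f: tuple(c + np.asarray(f) * a)  # noqa: E731
    spec.haa_patches = [
        (rel(rng.uniform(-0.55, 0.55, 3)), r, hu) for (_, r, hu) in template.haa_patches
    ]
    spec.emphysema_blobs = [
        (rel(rng.uniform(-0.5, 0.5, 3)), r, hu) for (_, r, hu) in template.emphysema_blobs
    ]
    spec.vessel_tubes = list(template.vessel_tubes)
    spec.ventilation.hotspots = [
        (rel(rng.uniform(-0.5, 0.5, 3)), sig, amp)
        for (_, sig, amp) in template.ventilation.hotspots
    ]
    return spec


# --- persistence -------------------------------------------------------------

def write_phantom(
    out_dir: str | os.PathLike,
    insp: VolumetricImage,
    exp_img: VolumetricImage,
    followup: VolumetricImage,
    truth: PhantomTruth,
    prefix: str = "subject",
) -> dict[str, str]:
    """Write a phantom triplet plus truth grids as NIfTI and a JSON summary."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _w(name: str, img: VolumetricImage) -> None:
        p = os.path.join(out_dir, f"{prefix}_{name}.nii.gz")
        write_volume(img, p)
        paths[name] = p

    _w("baseline_insp", insp)
    _w("baseline_exp", exp_img)
    _w("followup_insp", followup)
    _w("truth_ventilation", exp_img.like(truth.ventilation_field))
    _w("truth_jacobian", exp_img.like(truth.insp_to_exp_jacobian))
    fp = os.path.join(out_dir, f"{prefix}_truth_field.nii.gz")
    write_field(truth.insp_to_exp_displacement, fp)
    paths["truth_field"] = fp
    summary = {
        "jacobian_fit_residual": truth.jacobian_fit_residual,
        "class_fractions_insp": truth.class_fractions_insp,
        "lung_voxels_exp": int(np.count_nonzero(truth.lung_mask_exp)),
        "mean_truth_ventilation": float(
            truth.ventilation_field[truth.lung_mask_exp].mean()
        ),
    }
    sp = os.path.join(out_dir, f"{prefix}_truth_summary.json")
    with open(sp, "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["truth_summary"] = sp
    return paths
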