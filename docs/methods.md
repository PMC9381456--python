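# Methods

## The measurement

`ventmap` implements voxelwise functional CT of the lung from three
breath-hold acquisitions per subject: baseline inspiration, baseline
expiration, and follow-up inspiration. The baseline expiration scan is the
anatomical reference; both inspiration scans are deformably registered to it
so every derived map lives in one coordinate system.

**Regional ventilation.** CT cannot measure gas exchange, so the fractional
air-volume change between inspiration and expiration serves as a surrogate
for local ventilation. The package combines the deformation-based and the
density-based measurement:

    v = 1 − J_inv · ( HU_exp / HU_inspWarped )

where `J_inv` is the inverse Jacobian determinant of the
inspiration→expiration registration — the local expiration/inspiration
volume ratio, ≤ 1 during exhale — and the attenuation ratio corrects for
density change. With displacement fields stored on the expiration grid
mapping to inspiration points, `det(I + ∇u)` is V_insp/V_exp, and the
equation consumes its reciprocal; this is the only sign convention under
which the stated limits hold (v = 0 for no volume change, v = 1 for
complete expiratory collapse), and it is verified by the phantom identity
below.

**Why raw signed HU.** "Lung density" in the equation is deliberately the
raw signed attenuation: with air at −1000 HU and tissue near 0 HU, −HU/1000
is the voxel's air fraction β, so the raw-HU ratio equals the air-fraction
ratio and the equation's limits are exact under one-compartment air/tissue
mass conservation. A physical-density mode (HU + 1000) is available behind
`density_ratio_mode="physical"` for sensitivity analysis. Values are
clamped to [0, 1] rather than rescaled — the clamped fraction is reported so
heavy clamping is visible — because no specific normalizing transform is
part of the method beyond the equation's own range.

**Categories.** Ventilation is binned into C1 = [0, 0.25), C2 = [0.25, 0.5),
C3 = [0.5, 0.75), C4 = [0.75, 1]. C1 voxels (peribronchovascular rim) are
kept in the frequency tables but treated as non-ventilating and excluded
from contrast statistics. Normal ventilation centres around 0.5, so C2 is
low-to-normal, C3 moderately and C4 severely increased ventilation.

**Tissue classes.** Analysis is restricted to parenchyma by attenuation on
the warped baseline inspiration: below −950 HU (emphysema-like) and above
−250 HU (vessels, consolidation) are excluded; normal attenuation areas
(NAA) are [−950, −600] HU and high attenuation areas (HAA) are
(−600, −250] HU, analysed separately. The conventional integer boundary
"−599 HU" is treated as the open edge of −600 on continuous data so no 1-HU
gap exists. Classification is computed on the warped inspiration image —
the attenuation thresholds are inspiratory conventions, but all voxelwise
analysis happens on the expiration grid, so the classification source is
warped into that frame.

**Longitudinal change.** After both inspirations are warped to the
expiration reference, density change (HU, positive = densification) is the
voxelwise difference follow-up − baseline, and volume change (%) is
(det J − 1)·100 of the *temporal* registration of the follow-up-warped onto
the baseline-warped image. One boundary voxel is peeled from the change-map
validity: the interpolation kernel of the warped images straddles the
~900 HU pleural step there and biases voxelwise differences.

**Statistics.** The pairing unit is the subject: each subject contributes
one mean ΔHU and one mean ΔV% per (tissue class × category) cell; pooling
voxels across subjects would pseudo-replicate. Contrasts (C4 vs C2,
C4 vs C3, per class and metric) are two-sided paired t-tests across
subjects' cell means; raw p-values without multiplicity correction (a small
set of pre-specified contrasts). Pooled tables default to across-subject
mean ± SD; an across-voxel (count-weighted) mode exists behind
`pool_study(..., across="voxels")`. Subjects whose lung-mask surface
misalignment after warping exceeds 2 mm (mean symmetric surface distance)
are excluded. Note that a rigid shift of s mm produces a mean surface
distance of roughly 0.6·s (surfaces parallel to the shift slide along
themselves), so the mean-distance criterion flags rigid shifts of about
4 mm and above; how misalignment should be operationalized is not uniquely
determined and landmark-based measures would behave differently.

## The registration engine

A multi-resolution demons scheme written directly on numpy/scipy: an
intensity-difference-driven iterative update with Gaussian smoothing of the
update (fluid-like, σ 1.5 voxels) and of the accumulated field (elastic-like,
σ 0.8 voxels), step bound 1 voxel/iteration, over a 3-level shrink pyramid
(4/2/1; 300/150/80 iteration caps with windowed early stopping and
best-residual tracking). Two design points matter:

* **Mass-preserving residual.** Breath-hold pairs violate brightness
  constancy — exhaled lung is denser. Images are compared as log tissue
  fraction, log(1 + HU/1000), and the warped moving term carries an
  additive log det(I + ∇u): exactly the brightness relation implied by
  air/tissue mass conservation, so the true deformation is a fixed point of
  the residual. Same-inflation pairs (the temporal registration) can use
  the plain intensity residual.
* **Moment initialization.** The bulk inspiration→expiration volume change
  (tens of mm of displacement) is seeded by per-axis shift+scale matching
  of lung-mask first/second moments before demons refines. The mask
  threshold for this step is −100 HU rather than −250 HU: strongly
  ventilated parenchyma can compress above −250 HU at end-exhale, and
  cutting it off biases the expiratory centroid apically.

The engine is fully deterministic (full-grid residual, no sampling, no
RNG). On default 64³ phantoms it recovers the breathing field to a mean
endpoint error of roughly 1.3–1.8 voxels inside the lung in a few seconds on
one CPU. For the ventilation Jacobian the estimated field is smoothed with
σ = 2 voxels before differentiation (`jacobian_field_smoothing`-style
post-regularization is conventional for Jacobian maps; the truth-field
experiments show the ventilation-relevant content of J lies at scales the
smoothing preserves).

Jacobian determinants are computed by spacing-aware central differences
(one-sided at grid boundaries) in physical mm — anisotropic voxels such as
0.68 × 0.68 × 1 mm would otherwise bias the determinant — with folding
(det ≤ 0) counted and reported, and reciprocals floored at 0.05 with a
clamp counter.

## The phantom generator

Each synthetic subject is built from a one-compartment air/tissue mixture:
air fraction β = −HU/1000, tissue volume conserved between breath-holds,
all volume change is air.

* **Anatomy.** An ellipsoidal lung (semi-axes ≈ 0.7 of the grid half-extent)
  in a soft-tissue body (+40 HU); NAA parenchyma at −850 HU; three HAA
  patches (−350…−450 HU, ~9 % of lung), two vessel tubes (> −250 HU), one
  emphysema blob (−980 HU); multi-scale correlated parenchymal texture
  (SD 30/35/45 HU at 25/12/6 mm correlation, scaled with lung size) that
  models the vascular/septal structure registration locks onto; i.i.d.
  scanner noise (SD 25 HU inspiration, 12 HU expiration) added separately
  after deformation. HU is floored at −1000.
* **Ventilation drive.** A smooth field: base 0.65, apico-basal gradient
  spanning 0.40 (higher at the base), two Gaussian hot spots (amplitude
  0.14, σ = 0.5·min semi-axis), softly saturated below 0.96 (a hard clip
  would put kinks into the Jacobian) and tapered to zero within 0.8 mm of
  the pleura. These values were fixed once so that the NAA
  ventilation-category volume fractions approximate the distribution
  reported for fibrotic lungs — C1/C2/C3/C4 ≈ 2/23/53/22 % — and the HAA
  distribution then emerges C4-heavy (~40–46 %), qualitatively matching the
  reported HAA pattern without separate tuning: denser tissue holds less
  air, so the same volume change is a larger fraction of it.
* **Deformation.** The target volume-change field is J* = 1 − v·β_s with a
  4 mm-smoothed air fraction (patch boundaries would otherwise make the
  field non-smooth). It is realized as a lung-centre-anchored sequential
  contraction along x, then y, then z, each targeting J*^{1/3} via exact
  cumulative-integral 1-D maps, so the composed analytic Jacobian equals J*
  while per-axis strains stay physiological (~20 %, diaphragm plus chest
  wall rather than single-axis collapse). The finite-difference determinant
  of the realized field agrees with J* to a mean of ~0.002 and a max of
  0.02–0.05 over the interior lung (worst where v approaches saturation and
  J* ≈ 0.2 compresses features several-fold); this residual is a property
  of the discrete measurement operator — the construction is analytically
  exact — and is reported on the truth object.
* **Expiration image.** HU_exp is defined from the actually-warped
  inspiration by exact tissue-mass scaling τ_exp = τ_inspWarped/J*
  (τ = 1 + HU/1000), and the stored truth ventilation is the realized
  per-voxel exhaled fraction v = (1 − J*)/β. Consequently both the
  ventilation-equation identity and tissue-mass conservation hold
  voxel-exactly on the noise-free variant — the analysis equation inverts
  the generator to machine precision, and the mass-preserving registration
  residual is zero at the true deformation. (An earlier design that built
  J* from the smoothed β but kept the per-voxel ventilation field violated
  mass conservation at texture scale and measurably biased registration
  away from the truth.)
* **Progression.** Follow-up inspiration adds a density offset and a z-axis
  volume-scaling contraction per baseline ventilation category, plus noise.
  Defaults emulate reported normal-parenchyma magnitudes: +24/+32/+58 HU
  and +2.25/−0.8/−3.74 % for C2/C3/C4; per-voxel progression noise SD
  15 HU. `make_cohort` replaces the gains with a linear coupling —
  `coupling_strength` HU per category step (planted C4 − C2 difference =
  2×coupling; the analogous volume coupling defaults to 1.85 %/step scaled
  with it) — jittered per subject and category with SD 10 HU / 1 %, and
  randomizes lung geometry (±~8 %), ventilation base (±0.03) and
  structure/hot-spot placement, all reproducibly from one seed.
* **Truth injection.** For registration-free testing the truth object
  carries the ideal output of each registration stage: the breathing field
  (ventilation), the *composed* progression∘breathing map for the follow-up
  warp (so the density-change map equals the planted gains — an ideal
  follow-up registration aligns the progressed anatomy), and the
  progression-residual field for the temporal stage (so the volume-change
  map equals the planted loss). The two injected follow-up-related fields
  are deliberately different stages' ideals: a single consistent warp would
  either leak rim artifacts into ΔHU or absorb the volume signal entirely —
  the same trade-off the real pipeline resolves through registration
  regularization. The composed truth temporal field carries ~0.5 % mean
  determinant discretization error, so planted-volume recovery is asserted
  at 1–1.5 % absolute.

**What the phantom does not model:** airway trees, cardiac motion, gravity
and posture dependence, scanner noise spectra and beam hardening,
respiratory-depth variability, hysteresis between inspiration and
expiration pathways, and real fibrosis texture (honeycombing,
reticulation). Passing tests therefore demonstrate correctness of the
computational chain and calibration of the statistics under the stated
generative model — not clinical validity on patient scans.

## Verification design and problem sizes

* Closed-form anchors (single-voxel mass-conservation cases, category
  edges, the 35 cm/512 → 0.68 mm geometry identity) are exact.
* Truth-injected recovery runs at 64³ (noise-free: identity to < 1e-4;
  the observed error is ~1e-16).
* End-to-end registration recovery runs at 64³ with 2 mm voxels (a few
  seconds per registration).
* Statistical calibration uses 1000 null cohorts and 100 planted cohorts of
  n = 20 subjects at 20³ with truth injection — the calibration targets the
  contrast machinery, so the cohorts use the homogeneous-parenchyma spec
  (`PhantomSpec.stats_default()`): focal structures add boundary/partial-
  volume measurement systematics that the planted-recovery tests probe
  separately. Measured at these conditions: type-I error ≈ 4.7–6 %,
  power ≈ 97–100 % at p < 0.001 for the planted 30 HU effect, with the
  measured C4 − C2 difference attenuated to ≈ 19–20 HU by category
  cross-assignment at coarse grids (interpolation smears category bands a
  few voxels thick).

## Known limitations

* The end-to-end ventilation recovery with the built-in engine reaches
  mean |v − v*| ≈ 0.03–0.05 and 75–87 % category agreement inside the lung
  at 64³ (seed-dependent). Agreement above 90 % would require near-exact
  Jacobian recovery — even the ground-truth Jacobian combined with measured
  warped images yields only ~92 % under default noise, since a ±0.02
  perturbation of v flips several percent of voxels across the 0.25-wide
  bin edges — i.e. sub-voxel accuracy of field *derivatives* on a ~50 %
  volume-change deformation. That is beyond this demons-class engine on a
  64³ desk-scale problem; clinical-resolution data (0.68 mm in-plane) give
  registration far more structure per unit deformation.
* In registration mode the follow-up→expiration alignment partially absorbs
  progression-induced shrinkage into the warp, attenuating the temporal
  volume-change signal; this ambiguity is intrinsic to the workflow (any
  perfectly converged registration would absorb it entirely) and is why
  volume-change validation relies on truth injection.
* No intensity harmonization is applied between time points before
  subtraction.
* The built-in engine assumes axis-aligned geometry; oblique direction
  cosines are honoured in warping/resampling but not by the demons core.
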