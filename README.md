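# ventmap

Voxelwise functional CT of the lung: registration-based **regional
ventilation** from paired inspiration/expiration scans, spatially correlated
with **longitudinal density and volume change** on follow-up CT.

In progressive fibrosing lung disease (e.g. IPF), regions that are
abnormally *over*-ventilated at baseline are suspected precursors of later
fibrotic remodeling — densification and volume loss. Testing that
hypothesis needs a voxel-level chain: align three breath-hold CT volumes
(baseline inspiration, baseline expiration, follow-up inspiration) into one
coordinate system, quantify per-voxel ventilation at baseline, measure
per-voxel structural change at follow-up, and compare the change across
baseline-ventilation strata with cohort statistics. `ventmap` implements
that chain for radiology/image-analysis researchers, together with a
digital lung-phantom generator that provides ground truth for every stage.

## The measurement

With the baseline expiration scan as the anatomical reference and both
inspiration scans deformably warped onto it, normalized regional
ventilation is

  v = 1 − J⁻¹ · ( HU_exp / HU_inspWarped ),  v ∈ [0, 1],

where J⁻¹ is the inverse Jacobian determinant of the
inspiration→expiration displacement field (local expiration/inspiration
volume ratio) and the attenuation ratio is the density correction; v = 0
means no volume change, v = 1 complete expiratory collapse. Ventilation is
binned into C1–C4 at 0.25/0.5/0.75; analysis runs separately for normal
(−950…−600 HU) and high (−600…−250 HU) attenuation parenchyma. Follow-up
change is the voxelwise density difference (HU) and the temporal-Jacobian
volume change (%), summarized per subject and category and compared with
paired t-tests (C4 vs C2, C4 vs C3). See `docs/methods.md` for the model,
the built-in mass-preserving demons registration engine, and the phantom
physics (a one-compartment air/tissue mixture that the ventilation
equation inverts exactly).

## Worked example

Generate a six-subject phantom cohort (32³ grids) with a planted coupling
of 15 HU densification per ventilation-category step, analyze it with
ground-truth deformations injected, and print the paired contrasts:

```
$ ventmap run-all --seed 1 --subjects 6 --grid 32 --truth-fields --out-dir demo
n=6 analyzed, 0 excluded
NAA C4 vs C2 density: mean diff +15.26, 95% CI [4.49, 26.03], p=0.01487
NAA C4 vs C2 volume: mean diff -3.07, 95% CI [-3.73, -2.40], p=7.473e-05
NAA C4 vs C3 density: mean diff +2.66, 95% CI [-8.44, 13.76], p=0.5646
NAA C4 vs C3 volume: mean diff -1.09, 95% CI [-1.55, -0.63], p=0.001756
HAA C4 vs C2 density: mean diff +8.51, 95% CI [1.47, 15.56], p=0.03104
HAA C4 vs C2 volume: mean diff -4.99, 95% CI [-8.42, -1.56], p=0.01897
HAA C4 vs C3 density: mean diff -3.29, 95% CI [-10.17, 3.59], p=0.2736
HAA C4 vs C3 volume: mean diff -0.75, 95% CI [-1.04, -0.45], p=0.001327
```

Reading this: severely over-ventilated normal parenchyma (C4) densified
~15 HU more and lost ~3 % more volume than low-to-normal regions (C2) —
the planted monotone coupling, recovered with the expected attenuation from
category cross-assignment at this small grid size and detected by the
paired tests at n = 6. `demo/` contains the per-subject ventilation,
category, and change maps (NIfTI), per-subject summaries, pooled tables,
and the contrast CSVs. Replace `--truth-fields` with `--registration` to
exercise the built-in deformable registration instead of the injected
ground truth, and use `ventmap phantom / register / ventilate / analyze`
for the individual stages on your own NIfTI volumes.

Library use mirrors the CLI:

```python
from ventmap import PhantomSpec, generate_phantom
from ventmap.pipeline import PipelineConfig, run_subject

insp, exp, followup, truth = generate_phantom(PhantomSpec.default(seed=1))
result = run_subject(PipelineConfig(), insp, exp, followup)
print(result.summary.table)
```

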