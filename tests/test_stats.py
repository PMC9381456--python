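import numpy as np
import pandas as pd
import pytest
from scipy import special

from ventmap.deformation import JacobianMap
from ventmap.image import TissueClass, TissueClassMap
from ventmap.longitudinal import ChangeMaps
from ventmap.stats import (
    SubjectSummary,
    build_report,
    frequency_distribution,
    paired_contrast,
    pool_study,
    run_study,
    summarize_subject,
)
from ventmap.ventilation import VentilationMap, categorize


def _make_maps(vvals, tissue_labels, dhu, dvol):
    shape = vvals.shape
    vm = VentilationMap(values=vvals.astype(float), valid=np.isfinite(vvals), spacing=(1, 1, 1))
    categorize(vm)
    tm = TissueClassMap(tissue_labels.astype(np.int8), (1, 1, 1), (0, 0, 0), np.eye(3))
    cm = ChangeMaps(
        density_change_hu=dhu.astype(float),
        volume_change_pct=dvol.astype(float),
        valid=np.ones(shape, bool),
    )
    return vm, tm, cm


def _summary_from_cells(sid, cells):
    """Build a SubjectSummary directly from {(tissue, cat): mean} values."""
    rows = []
    for tis in ("NAA", "HAA"):
        for cat in ("C1", "C2", "C3", "C4"):
            mean = cells.get((tis, cat), np.nan)
            rows.append(
                {"tissue": tis, "category": cat, "voxel_count": 0 if np.isnan(mean) else 10,
                 "volume_fraction": 0.25, "mean_density_change_hu": mean,
                 "mean_volume_change_pct": mean}
            )
    return SubjectSummary(sid, pd.DataFrame(rows).set_index(["tissue", "category"]))


def brute_force_paired_t(a, b):
    """Independent textbook oracle: explicit formulas, no stats library."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    mean = d.sum() / n
    sd = np.sqrt(((d - mean) ** 2).sum() / (n - 1))
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * (1.0 - special.stdtr(n - 1, abs(t)))  # regularized t CDF
    return t, p


class TestSummarizeSubject:
    def test_uniform_ventilation_and_change(self):
        shape = (6, 6, 6)
        vm, tm, cm = _make_maps(
            np.full(shape, 0.6),
            np.full(shape, TissueClass.NAA),
            np.full(shape, 20.0),
            np.full(shape, -1.0),
        )
        s = summarize_subject(vm, tm, cm)
        assert s.cell_mean("NAA", "C3", "density") == pytest.approx(20.0)
        assert s.table.loc[("NAA", "C3"), "volume_fraction"] == pytest.approx(1.0)
        assert s.table.loc[("NAA", "C2"), "voxel_count"] == 0
        assert np.isnan(s.cell_mean("NAA", "C2", "density"))  # missing, not zero

    def test_hand_built_four_voxel_case(self):
        vvals = np.array([0.1, 0.3, 0.6, 0.8]).reshape(4, 1, 1)
        dhu = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        vm, tm, cm = _make_maps(
            vvals, np.full((4, 1, 1), TissueClass.NAA), dhu, np.zeros((4, 1, 1))
        )
        s = summarize_subject(vm, tm, cm)
        for cat, expect in (("C1", 1.0), ("C2", 2.0), ("C3", 3.0), ("C4", 4.0)):
            assert s.cell_mean("NAA", cat, "density") == pytest.approx(expect)

    def test_matches_brute_force_double_loop_on_phantom(self, small_phantom):
        from ventmap.pipeline import PipelineConfig, run_subject

        spec, (insp, exp, fu, truth) = small_phantom
        res = run_subject(PipelineConfig(use_truth_fields=True), insp, exp, fu, truth=truth)
        vm, cm = res.ventilation, res.changes
        tm_labels = res.tissue
        # brute-force voxel loop over the flattened grid
        sums = {}
        counts = {}
        valid = vm.valid & (vm.category_labels >= 1) & cm.merged_valid()
        for idx in np.argwhere(valid):
            i, j, k = idx
            lab = tm_labels[i, j, k]
            if lab == TissueClass.NAA:
                tis = "NAA"
            elif lab == TissueClass.HAA:
                tis = "HAA"
            else:
                continue
            cat = f"C{vm.category_labels[i, j, k]}"
            key = (tis, cat)
            counts[key] = counts.get(key, 0) + 1
            sums[key] = sums.get(key, 0.0) + cm.density_change_hu[i, j, k]
        s = res.summary
        for key, n in counts.items():
            assert s.table.loc[key, "voxel_count"] == n
            assert s.cell_mean(key[0], key[1], "density") == pytest.approx(
                sums[key] / n, rel=1e-12
            )


class TestPairedContrast:
    def test_zero_variance_is_degenerate_not_an_error(self):
        summaries = [
            _summary_from_cells(f"s{i}", {("NAA", "C4"): 5.0, ("NAA", "C2"): 3.0})
            for i in range(4)
        ]
        res = paired_contrast(summaries, "NAA", ("C4", "C2"), "density")
        assert res.mean_difference == pytest.approx(2.0)
        assert "zero variance" in res.note
        assert np.isnan(res.p_value)

    def test_textbook_example(self):
        # differences {1, 2, 3}: t = 2/(1/sqrt(3)) ≈ 3.464, p ≈ 0.0742
        summaries = [
            _summary_from_cells(f"s{i}", {("NAA", "C4"): 10.0 + d, ("NAA", "C2"): 10.0})
            for i, d in enumerate((1.0, 2.0, 3.0))
        ]
        res = paired_contrast(summaries, "NAA", ("C4", "C2"), "density")
        assert res.t_statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.p_value == pytest.approx(0.07417990022744862, abs=1e-6)

    def test_equals_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a = rng.normal(5, 3, n)
            b = rng.normal(4, 3, n)
            summaries = [
                _summary_from_cells(f"s{i}", {("HAA", "C4"): a[i], ("HAA", "C3"): b[i]})
                for i in range(n)
            ]
            res = paired_contrast(summaries, "HAA", ("C4", "C3"), "density")
            t, p = brute_force_paired_t(a, b)
            assert res.t_statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_missing_cells_dropped_pairwise(self):
        summaries = [
            _summary_from_cells(f"s{i}", {("NAA", "C4"): 4.0 + i, ("NAA", "C2"): 1.0})
            for i in range(4)
        ]
        summaries.append(_summary_from_cells("s4", {("NAA", "C4"): 9.0}))  # C2 missing
        res = paired_contrast(summaries, "NAA", ("C4", "C2"), "density")
        assert res.n_pairs == 4 and res.n_dropped == 1

    def test_too_few_pairs_rejected(self):
        summaries = [
            _summary_from_cells(f"s{i}", {("NAA", "C4"): 1.0, ("NAA", "C2"): 0.0})
            for i in range(2)
        ]
        with pytest.raises(ValueError, match="pairs"):
            paired_contrast(summaries, "NAA", ("C4", "C2"), "density")


class TestFrequencyDistribution:
    def test_equal_quarters(self):
        s = _summary_from_cells("s0", {})
        out = frequency_distribution([s])
        np.testing.assert_allclose(out.values, 25.0)

    def test_rows_sum_to_hundred(self, small_phantom):
        from ventmap.pipeline import PipelineConfig, run_subject

        spec, (insp, exp, fu, truth) = small_phantom
        res = run_subject(PipelineConfig(use_truth_fields=True), insp, exp, fu, truth=truth)
        out = frequency_distribution([res.summary])
        np.testing.assert_allclose(out.sum(axis=1).values, 100.0, atol=1e-6)


class TestReport:
    def _study(self):
        rng = np.random.default_rng(1)
        summaries = []
        for i in range(6):
            cells = {
                (tis, cat): rng.normal(10, 3)
                for tis in ("NAA", "HAA")
                for cat in ("C1", "C2", "C3", "C4")
            }
            summaries.append(_summary_from_cells(f"s{i}", cells))
        return run_study(summaries)

    def test_report_regeneration_is_byte_identical(self, tmp_path):
        study = self._study()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = build_report(study, d1, config_repr="cfg")
        p2 = build_report(study, d2, config_repr="cfg")
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_pooled_table_shape(self):
        study = self._study()
        # 2 tissue classes × 3 ventilation rows × 2 metrics
        assert len(study.pooled) == 12
        assert {"mean", "sd", "n"} <= set(study.pooled.columns)

    def test_ci_brackets_mean_and_p_in_unit_interval(self):
        study = self._study()
        for c in study.contrasts:
            assert c.ci95_low <= c.mean_difference <= c.ci95_high
            assert 0.0 <= c.p_value <= 1.0

    def test_excluded_subjects_listed_in_run_log(self, tmp_path):
        import json

        summaries = [
            _summary_from_cells(f"s{i}", {(t, c): 1.0 * i for t in ("NAA", "HAA")
                                          for c in ("C1", "C2", "C3", "C4")})
            for i in range(5)
        ]
        summaries[0].excluded = True
        summaries[0].misalignment_mm = 2.7
        study = run_study(summaries)
        paths = build_report(study, tmp_path / "r")
        log = json.load(open(paths["run_log"]))
        assert log["n_excluded"] == 1
        assert log["excluded_subjects"][0]["misalignment_mm"] == pytest.approx(2.7)
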