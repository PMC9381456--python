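"""Cohort statistics: per-subject cross-tabulation of longitudinal change by
baseline-ventilation category and tissue class, pooled summaries, and paired
contrasts.

The pairing unit is the subject: each subject contributes one mean density
change (HU) and one mean volume change (%) per (tissue class, ventilation
category) cell, and contrasts (C4 vs C2, C4 vs C3) are two-sided paired
t-tests across subjects' cell means.  Pooling voxels across subjects would
pseudo-replicate; per-subject means keep n equal to the cohort size.  C1
(ventilation < 0.25) is reported in the frequency distribution but treated
as non-ventilating and excluded from contrasts.  Raw p-values are reported
without multiplicity correction (a handful of pre-specified contrasts).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image import TissueClass, TissueClassMap
from .longitudinal import ChangeMaps
from .ventilation import VentilationMap

__all__ = [
    "SubjectSummary",
    "ContrastResult",
    "StudyResult",
    "summarize_subject",
    "paired_contrast",
    "frequency_distribution",
    "pool_study",
    "run_study",
    "build_report",
    "export_voxel_table",
]

_TISSUES = ("NAA", "HAA")
_CATEGORIES = ("C1", "C2", "C3", "C4")
_CONTRAST_CATEGORIES = ("C2", "C3", "C4")


@dataclass
class SubjectSummary:
    """Per-subject cross-tabulation over (tissue class × ventilation category).

    ``table`` is indexed by (tissue, category) with columns ``voxel_count``,
    ``volume_fraction`` (within tissue class, over C1–C4),
    ``mean_density_change_hu`` and ``mean_volume_change_pct``; empty cells
    hold NaN means (missing, not zero).
    """

    subject_id: str
    table: pd.DataFrame
    misalignment_mm: float = float("nan")
    excluded: bool = False

    def cell_mean(self, tissue: str, category: str, metric: str) -> float:
        col = _metric_column(metric)
        return float(self.table.loc[(tissue, category), col])


@dataclass
class ContrastResult:
    """One paired contrast row (e.g. C4 vs C2 density change in NAA)."""

    tissue: str
    contrast: str
    metric: str
    mean_difference: float
    sd_difference: float
    ci95_low: float
    ci95_high: float
    t_statistic: float
    p_value: float
    n_pairs: int
    n_dropped: int
    note: str = ""


@dataclass
class StudyResult:
    """Pooled per-category summaries plus paired contrasts."""

    pooled: pd.DataFrame  # (tissue, category) × mean/sd per metric
    contrasts: list[ContrastResult]
    frequencies: pd.DataFrame  # tissue × category volume fractions (%)
    n_subjects: int
    n_excluded: int
    excluded_subjects: list[tuple[str, float]] = dataclass_field(default_factory=list)


def _metric_column(metric: str) -> str:
    if metric in ("density", "dhu", "density_change"):
        return "mean_density_change_hu"
    if metric in ("volume", "dvol", "volume_change"):
        return "mean_volume_change_pct"
    raise ValueError(f"unknown metric: {metric!r}")


def summarize_subject(
    vent: VentilationMap,
    tissue: TissueClassMap,
    changes: ChangeMaps,
    subject_id: str = "subject",
    misalignment_mm: float = float("nan"),
) -> SubjectSummary:
    """Cross-tabulate voxelwise change maps by tissue class and category."""
    if vent.category_labels is None:
        raise ValueError("ventilation map has no categories; run categorize() first")
    if not (vent.shape == tissue.shape):
        raise ValueError("ventilation and tissue maps must share a grid")

    valid = vent.valid & (vent.category_labels >= 1)
    if changes.valid is not None:
        valid = valid & changes.valid

    lab = tissue.labels
    tis_idx = np.full(lab.shape, -1, dtype=np.int8)
    tis_idx[lab == TissueClass.NAA] = 0
    tis_idx[lab == TissueClass.HAA] = 1
    valid = valid & (tis_idx >= 0)

    code = (tis_idx[valid].astype(np.int64) * 4) + (vent.category_labels[valid].astype(np.int64) - 1)
    counts = np.bincount(code, minlength=8).astype(float)

    def _cell_means(grid: np.ndarray | None) -> np.ndarray:
        if grid is None:
            return np.full(8, np.nan)
        sums = np.bincount(code, weights=grid[valid], minlength=8)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / counts, np.nan)

    mean_dhu = _cell_means(changes.density_change_hu)
    mean_dvol = _cell_means(changes.volume_change_pct)

    rows = []
    for ti, tname in enumerate(_TISSUES):
        class_total = counts[ti * 4 : ti * 4 + 4].sum()
        for ci, cname in enumerate(_CATEGORIES):
            k = ti * 4 + ci
            rows.append(
                {
                    "tissue": tname,
                    "category": cname,
                    "voxel_count": int(counts[k]),
                    "volume_fraction": counts[k] / class_total if class_total > 0 else np.nan,
                    "mean_density_change_hu": mean_dhu[k],
                    "mean_volume_change_pct": mean_dvol[k],
                }
            )
    table = pd.DataFrame(rows).set_index(["tissue", "category"])
    return SubjectSummary(subject_id=subject_id, table=table, misalignment_mm=misalignment_mm)


def paired_contrast(
    summaries: list[SubjectSummary],
    tissue: str,
    contrast: tuple[str, str] = ("C4", "C2"),
    metric: str = "density",
) -> ContrastResult:
    """Two-sided paired t-test on per-subject category means.

    Subjects missing either cell are dropped pairwise and counted; fewer
    than 3 complete pairs is an error; zero variance of the differences is
    reported as a degenerate-case diagnostic (NaN t/p), not an error.
    """
    hi, lo = contrast
    if hi not in _CONTRAST_CATEGORIES or lo not in _CONTRAST_CATEGORIES:
        raise ValueError(f"contrast categories must be among {_CONTRAST_CATEGORIES}")
    col = _metric_column(metric)
    a, b = [], []
    n_dropped = 0
    for s in summaries:
        if s.excluded:
            n_dropped += 1
            continue
        va = s.table.loc[(tissue, hi), col]
        vb = s.table.loc[(tissue, lo), col]
        if np.isnan(va) or np.isnan(vb):
            n_dropped += 1
            continue
        a.append(va)
        b.append(vb)
    d = np.asarray(a) - np.asarray(b)
    n = d.size
    if n < 3:
        raise ValueError(f"need ≥ 3 complete pairs for {tissue} {hi}-{lo}, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    base = dict(
        tissue=tissue, contrast=f"{hi} vs {lo}", metric=metric,
        mean_difference=mean, sd_difference=sd, n_pairs=n, n_dropped=n_dropped,
    )
    if sd == 0.0:
        return ContrastResult(
            **base, ci95_low=mean, ci95_high=mean,
            t_statistic=float("nan"), p_value=float("nan"),
            note="degenerate: zero variance of paired differences",
        )
    se = sd / np.sqrt(n)
    t_res = sps.ttest_rel(a, b)
    tcrit = sps.t.ppf(0.975, n - 1)
    return ContrastResult(
        **base,
        ci95_low=mean - tcrit * se,
        ci95_high=mean + tcrit * se,
        t_statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
    )


def frequency_distribution(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """Cohort category volume fractions (%) per tissue class.

    Averages per-subject fractions across non-excluded subjects (each
    subject weighted equally, matching the subject-level pairing unit).
    """
    use = [s for s in summaries if not s.excluded]
    if not use:
        raise ValueError("no non-excluded subjects")
    fracs = pd.concat([s.table["volume_fraction"] for s in use], axis=1)
    out = (fracs.mean(axis=1) * 100.0).unstack(level="category")
    return out.reindex(index=list(_TISSUES), columns=list(_CATEGORIES))


def pool_study(summaries: list[SubjectSummary], across: str = "subjects") -> pd.DataFrame:
    """Pooled mean ± SD of density and volume change per (tissue, category).

    ``across='subjects'`` (default) takes statistics over subjects' cell
    means; ``across='voxels'`` weights each subject's mean by its voxel
    count (an approximation to voxel pooling from summary data).
    """
    use = [s for s in summaries if not s.excluded]
    if not use:
        raise ValueError("no non-excluded subjects")
    rows = []
    for tis in _TISSUES:
        for cat in _CONTRAST_CATEGORIES:  # C1 excluded from pooled change stats
            for metric in ("density", "volume"):
                col = _metric_column(metric)
                vals = np.asarray([s.table.loc[(tis, cat), col] for s in use], dtype=float)
                wts = np.asarray(
                    [s.table.loc[(tis, cat), "voxel_count"] for s in use], dtype=float
                )
                ok = ~np.isnan(vals)
                vals, wts = vals[ok], wts[ok]
                if vals.size == 0:
                    mean = sd = np.nan
                elif across == "subjects":
                    mean = vals.mean()
                    sd = vals.std(ddof=1) if vals.size > 1 else np.nan
                elif across == "voxels":
                    mean = np.average(vals, weights=wts)
                    sd = np.sqrt(np.average((vals - mean) ** 2, weights=wts))
                else:
                    raise ValueError(f"unknown pooling mode: {across!r}")
                rows.append(
                    {"tissue": tis, "category": cat, "metric": metric,
                     "mean": mean, "sd": sd, "n": int(vals.size)}
                )
    return pd.DataFrame(rows).set_index(["tissue", "category", "metric"])


def run_study(summaries: list[SubjectSummary], across: str = "subjects") -> StudyResult:
    """Full statistical analysis: pooled table, frequency table and the four
    paired contrasts (C4 vs C2 and C4 vs C3, density and volume) per class."""
    excluded = [(s.subject_id, s.misalignment_mm) for s in summaries if s.excluded]
    contrasts = []
    for tis in _TISSUES:
        for lo in ("C2", "C3"):
            for metric in ("density", "volume"):
                try:
                    contrasts.append(paired_contrast(summaries, tis, ("C4", lo), metric))
                except ValueError:
                    # a whole class can be absent (e.g. no HAA voxels);
                    # record the contrast as missing rather than failing
                    contrasts.append(ContrastResult(
                        tissue=tis, contrast=f"C4 vs {lo}", metric=metric,
                        mean_difference=float("nan"), sd_difference=float("nan"),
                        ci95_low=float("nan"), ci95_high=float("nan"),
                        t_statistic=float("nan"), p_value=float("nan"),
                        n_pairs=0, n_dropped=len(summaries),
                        note="insufficient complete pairs",
                    ))
    return StudyResult(
        pooled=pool_study(summaries, across=across),
        contrasts=contrasts,
        frequencies=frequency_distribution(summaries),
        n_subjects=len(summaries) - len(excluded),
        n_excluded=len(excluded),
        excluded_subjects=excluded,
    )


def build_report(result: StudyResult, out_dir: str | os.PathLike,
                 config_repr: str = "") -> dict[str, str]:
    """Write CSV tables (pooled changes, contrasts per metric, frequencies)
    plus a JSON run log; regeneration from the same result is byte-identical."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    pooled = result.pooled.reset_index()
    p = os.path.join(out_dir, "pooled_change_by_category.csv")
    pooled.to_csv(p, index=False, float_format="%.6g")
    paths["pooled"] = p

    cdf = pd.DataFrame([vars(c) for c in result.contrasts])
    for metric, name in (("density", "contrasts_density.csv"), ("volume", "contrasts_volume.csv")):
        p = os.path.join(out_dir, name)
        cdf[cdf["metric"] == metric].to_csv(p, index=False, float_format="%.6g")
        paths[name.split(".")[0]] = p

    p = os.path.join(out_dir, "frequency_distribution.csv")
    result.frequencies.to_csv(p, float_format="%.6g")
    paths["frequencies"] = p

    log = {
        "n_subjects": result.n_subjects,
        "n_excluded": result.n_excluded,
        "excluded_subjects": [
            {"subject": sid, "misalignment_mm": round(m, 4) if np.isfinite(m) else None}
            for sid, m in result.excluded_subjects
        ],
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
    }
    p = os.path.join(out_dir, "run_log.json")
    with open(p, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    paths["run_log"] = p
    return paths


def export_voxel_table(
    vent: VentilationMap,
    tissue: TissueClassMap,
    changes: ChangeMaps,
    path: str | os.PathLike,
    stride: int = 1,
) -> None:
    """Per-voxel (ventilation, category, tissue class, ΔHU, ΔV%) CSV for
    scatterplot-style analyses; ``stride`` subsamples the grid."""
    if vent.category_labels is None:
        raise ValueError("run categorize() first")
    valid = vent.valid & (vent.category_labels >= 1)
    if changes.valid is not None:
        valid = valid & changes.valid
    sl = (slice(None, None, stride),) * 3
    sel = valid[sl]
    df = pd.DataFrame(
        {
            "ventilation": vent.values[sl][sel],
            "category": vent.category_labels[sl][sel],
            "tissue_class": tissue.labels[sl][sel],
            "density_change_hu": (
                changes.density_change_hu[sl][sel]
                if changes.density_change_hu is not None else np.nan
            ),
            "volume_change_pct": (
                changes.volume_change_pct[sl][sel]
                if changes.volume_change_pct is not None else np.nan
            ),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
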