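"""End-to-end synthetic study: generate -> tensor fit -> ALPS -> EPVS
morphometrics -> rater agreement -> group statistics.

Everything here is a thin composition of the other modules; it exists so
the whole analysis is reproducible from one seed and one configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alps as alps_mod
from . import epvs as epvs_mod
from . import phantom as phantom_mod
from . import stats as stats_mod
from .dti import fit_tensor


@dataclass
class StudyConfig:
    spec: phantom_mod.PhantomSpec = field(default_factory=phantom_mod.PhantomSpec)
    groups: list[phantom_mod.GroupConfig] = field(default_factory=phantom_mod.default_groups)
    roi_spec: alps_mod.AlpsRoiSpec = field(default_factory=alps_mod.AlpsRoiSpec)
    seed: int = 0
    min_length_mm: float = 2.0
    fraction_scale: float = epvs_mod.DEFAULT_FRACTION_SCALE
    include_dwi: bool = True
    run_segmentation: bool = True
    rater_rate: float = 0.05  # boundary-revision rate of the simulated raters


def process_subject(
    bundle: phantom_mod.SubjectBundle,
    *,
    roi_spec: alps_mod.AlpsRoiSpec | None = None,
    min_length_mm: float = 2.0,
    fraction_scale: float = epvs_mod.DEFAULT_FRACTION_SCALE,
    run_segmentation: bool = False,
    rater_rate: float = 0.05,
    rater_seed: int = 0,
) -> dict:
    """Measure one subject: ALPS from its DWI (if present) and EPVS
    morphometrics from its ground-truth mask; optionally the rule-based
    segmenter and simulated-rater agreement."""
    t = bundle.truth
    row: dict = {
        "subject_id": t.subject_id,
        "group": t.group,
        "age": t.age,
        "sex": t.sex,
        "education": t.education,
        "total_brain_volume_mm3": t.total_brain_volume_mm3,
        "mmse": t.mmse,
        "moca": t.moca,
        "true_alps": t.alps,
        "true_lesion_count": t.lesion_count,
        "true_lesion_volume_mm3": t.lesion_total_volume_mm3,
    }

    if bundle.dwi is not None:
        tf = fit_tensor(bundle.dwi)
        res = alps_mod.alps_for_subject(
            tf, bundle.affine_template_to_subject, bundle.atlas, roi_spec
        )
        row.update(
            alps_left=res.alps_left, alps_right=res.alps_right, alps_mean=res.alps_mean
        )
        row.update({f"roi_n_{k}": v for k, v in res.roi_voxel_counts.items()})

    ls = epvs_mod.label_lesions(bundle.gt_epvs_mask, bundle.atlas)
    ls = epvs_mod.filter_by_length(ls, min_length_mm)
    metrics = epvs_mod.lesion_metrics(ls, bundle.atlas, fraction_scale)
    row.update(
        epvs_total_volume=metrics.total_volume_mm3,
        epvs_total_number=metrics.total_number,
        bg_fraction=metrics.bg_fraction,
        cso_fraction=metrics.cso_fraction,
    )

    if run_segmentation:
        pred = epvs_mod.segment_epvs_rulebased(
            bundle.t1_like, bundle.t2_like, bundle.atlas
        )
        gt = np.asarray(bundle.gt_epvs_mask.data).astype(bool)
        brain = np.asarray(bundle.atlas.data) != epvs_mod.LABEL_BACKGROUND
        rater1 = phantom_mod.simulate_rater(gt, "add_only", rater_rate, rater_seed, brain)
        rater2 = phantom_mod.simulate_rater(gt, "add_only", rater_rate, rater_seed + 1, brain)
        for label, ref, mode in (
            ("rater1", [rater1], "single"),
            ("rater2", [rater2], "single"),
            ("union", [rater1, rater2], "union"),
            ("intersection", [rater1, rater2], "intersection"),
        ):
            ev = epvs_mod.seg_eval(pred, ref, mode)
            row[f"dsc_{label}"] = ev.dsc
            row[f"recall_{label}"] = ev.recall
            row[f"precision_{label}"] = ev.precision
    return row


def run_study(config: StudyConfig) -> dict:
    """Run the full synthetic study and return the per-subject table,
    group summaries and the statistical battery results."""
    table = pd.DataFrame(
        [
            process_subject(
                b,
                roi_spec=config.roi_spec,
                min_length_mm=config.min_length_mm,
                fraction_scale=config.fraction_scale,
                run_segmentation=config.run_segmentation,
                rater_rate=config.rater_rate,
                rater_seed=config.seed * 1000 + i,
            )
            for i, b in enumerate(
                phantom_mod.iter_cohort(
                    config.spec, config.groups, config.seed,
                    include_dwi=config.include_dwi,
                )
            )
        ]
    )
    analysis = stats_mod.cohort_analysis(table)
    return {
        "table": table,
        "group_summary": group_summary(table),
        "seg_eval_summary": seg_eval_summary(table) if config.run_segmentation else None,
        "analysis": analysis,
    }


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean +/- SEM for ALPS and median (IQR) for EPVS metrics,
    mirroring how such results are conventionally tabulated."""
    rows = []
    for g, sub in table.groupby("group", sort=False):
        row = {"group": g, "n": len(sub)}
        for m in ("alps_left", "alps_right", "alps_mean"):
            if m in sub.columns:
                row[f"{m}_mean"] = sub[m].mean()
                row[f"{m}_sem"] = sub[m].std(ddof=1) / np.sqrt(len(sub))
        for m in ("epvs_total_volume", "epvs_total_number", "bg_fraction", "cso_fraction"):
            if m in sub.columns:
                row[f"{m}_median"] = sub[m].median()
                row[f"{m}_q1"] = sub[m].quantile(0.25)
                row[f"{m}_q3"] = sub[m].quantile(0.75)
        rows.append(row)
    return pd.DataFrame(rows)


def seg_eval_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) of DSC/recall/precision per reference mode."""
    rows = []
    for metric in ("dsc", "recall", "precision"):
        for ref in ("rater1", "rater2", "union", "intersection"):
            col = f"{metric}_{ref}"
            if col in table.columns:
                rows.append(
                    {
                        "metric": metric,
                        "reference": ref,
                        "median": table[col].median(),
                        "q1": table[col].quantile(0.25),
                        "q3": table[col].quantile(0.75),
                    }
                )
    return pd.DataFrame(rows)


def analysis_to_json(analysis: dict) -> dict:
    """Flatten cohort_analysis output into JSON-serialisable form."""
    out: dict = {"group_tests": {}, "partial_correlations": {},
                 "spearman_alps_epvs": {}}
    for m, res in analysis["group_tests"].items():
        out["group_tests"][m] = {
            "method": res.method,
            "statistic": res.statistic,
            "p_overall": res.p_overall,
            "pairwise": {f"{a}_vs_{b}": p for (a, b), p in res.pairwise.items()},
            "adjustment": res.adjustment,
        }
    for (m, score), res in analysis["partial_correlations"].items():
        out["partial_correlations"][f"{m}__{score}"] = {
            "r": res.r, "r_squared": res.r_squared, "p": res.p, "n": res.n_effective,
        }
    for m, res in analysis["spearman_alps_epvs"].items():
        out["spearman_alps_epvs"][m] = {"r": res.r, "p": res.p}
    if analysis.get("sex_chi_square") is not None:
        stat, p = analysis["sex_chi_square"]
        out["sex_chi_square"] = {"statistic": stat, "p": p}
    return out
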