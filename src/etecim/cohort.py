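"""Cohort-level driver: per-patient metrics plus pooled and per-fold stats.

Mirrors a typical segmentation-validation results layout: a per-patient
table of overlap metrics and both GTV estimates, then statistic blocks —
Pearson correlation and paired t-test between predicted and ground-truth
GTVs (for both estimators), a paired t-test between the two directions of
the degree of inclusion, one-sample t-tests of the signed LR/AP/CC
displacements against zero, descriptive summaries of DSC/HD/MSD/CI/MV,
and the OLS calibration line that maps a predicted GTV back to a
ground-truth estimate.

Rows whose masks cannot be read or compared are excluded and reported,
never silently dropped.  Degenerate statistical tests (zero variance,
e.g. when predictions equal ground truth) are flagged in place.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd

from .errors import DegenerateVarianceError, EtecimError
from .io import CohortManifest, load_mask
from .metrics import compare_masks
from .stats import (
    PairedSeries,
    calibrate,
    one_sample_t,
    paired_t,
    pearson,
    summarize,
)
from .volume import estimate_gtv

__all__ = ["CohortReport", "cohort_report", "per_patient_table"]


@dataclass(frozen=True)
class CohortReport:
    """Structured cohort results: per-patient rows + stat blocks."""

    per_patient: pd.DataFrame = field(repr=False)
    overall: dict = field(default_factory=dict)
    per_fold: dict = field(default_factory=dict)
    excluded: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_patients": int(len(self.per_patient)),
            "n_excluded": len(self.excluded),
            "excluded": self.excluded,
            "overall": self.overall,
            "per_fold": self.per_fold,
            "per_patient": self.per_patient.to_dict(orient="records"),
        }


def _patient_row(pid: str, pred_path: str, gt_path: str, fold) -> dict:
    pred = load_mask(pred_path)
    gt = load_mask(gt_path)
    rep = compare_masks(pred, gt)
    row = {"patient_id": pid, "fold": None if pd.isna(fold) else int(fold)}
    row.update(asdict(rep))
    row["gtv_etecim_pred"] = estimate_gtv(pred, "etecim").volume if pred.voxels.any() else None
    row["gtv_etecim_gt"] = estimate_gtv(gt, "etecim").volume
    row["gtv_voxel_pred"] = estimate_gtv(pred, "voxel_sum").volume
    row["gtv_voxel_gt"] = estimate_gtv(gt, "voxel_sum").volume
    return row


def per_patient_table(manifest: CohortManifest) -> tuple[pd.DataFrame, list[dict]]:
    """Evaluate every manifest row; returns (table, excluded-row records)."""
    rows, excluded = [], []
    for rec in manifest:
        fold = getattr(rec, "fold", None)
        try:
            rows.append(
                _patient_row(rec.patient_id, rec.predicted_mask_path, rec.ground_truth_mask_path, fold)
            )
        except (EtecimError, OSError) as exc:
            excluded.append({"patient_id": rec.patient_id, "error": str(exc)})
    return pd.DataFrame(rows), excluded


def _flagged(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except DegenerateVarianceError as exc:
        return {"degenerate": str(exc)}
    except ValueError as exc:
        return {"invalid": str(exc)}


def _gtv_block(df: pd.DataFrame, pred_col: str, gt_col: str) -> dict:
    sub = df[[pred_col, gt_col, "patient_id"]].dropna()
    series = PairedSeries(labels=sub["patient_id"].tolist(), x=sub[gt_col].to_numpy(),
                          y=sub[pred_col].to_numpy())

    def _pearson():
        r, r2, p = pearson(series)
        return {"r": r, "r_squared": r2, "p": p}

    def _paired():
        t, p = paired_t(series)
        return {"t": t, "p": p}

    def _calib():
        line = calibrate(series)
        return {"slope": line.slope, "intercept": line.intercept,
                "fit_direction": line.fit_direction}

    return {
        "n": len(series),
        "pearson": _flagged(_pearson),
        "paired_t": _flagged(_paired),
        "calibration": _flagged(_calib),
        "predicted_summary": asdict(summarize(series.y)),
        "ground_truth_summary": asdict(summarize(series.x)),
    }


def _displacement_block(df: pd.DataFrame, col: str) -> dict:
    vals = df[col].dropna().to_numpy()

    def _test():
        t, p = one_sample_t(vals, mu0=0.0)
        return {"t": t, "p": p}

    return {"n": len(vals), "one_sample_t_vs_0": _flagged(_test),
            "summary": asdict(summarize(vals)) if len(vals) else None}


def _summary_block(df: pd.DataFrame, col: str) -> dict:
    vals = df[col].dropna().to_numpy()
    return {"n": len(vals), "summary": asdict(summarize(vals)) if len(vals) else None}


def _di_block(df: pd.DataFrame) -> dict:
    sub = df[["di_pred_in_gt", "di_gt_in_pred", "patient_id"]].dropna()
    series = PairedSeries(labels=sub["patient_id"].tolist(),
                          x=sub["di_gt_in_pred"].to_numpy(),
                          y=sub["di_pred_in_gt"].to_numpy())

    def _paired():
        t, p = paired_t(series)
        return {"t": t, "p": p}

    return {
        "n": len(series),
        "paired_t": _flagged(_paired) if len(series) >= 2 else {"invalid": "n < 2"},
        "di_pred_in_gt_summary": asdict(summarize(series.y)) if len(series) else None,
        "di_gt_in_pred_summary": asdict(summarize(series.x)) if len(series) else None,
    }


def _stats_blocks(df: pd.DataFrame) -> dict:
    return {
        "gtv_etecim": _gtv_block(df, "gtv_etecim_pred", "gtv_etecim_gt"),
        "gtv_voxel_sum": _gtv_block(df, "gtv_voxel_pred", "gtv_voxel_gt"),
        "degree_of_inclusion": _di_block(df),
        "lr": _displacement_block(df, "lr"),
        "ap": _displacement_block(df, "ap"),
        "cc": _displacement_block(df, "cc"),
        "dsc": _summary_block(df, "dsc"),
        "ci": _summary_block(df, "ci"),
        "hd": _summary_block(df, "hd"),
        "msd": _summary_block(df, "msd"),
        "mv": _summary_block(df, "mv"),
    }


def cohort_report(manifest: CohortManifest) -> CohortReport:
    """Run the full comparative assessment over a manifest.

    Deterministic given the manifest and mask files.  Statistics are
    computed pooled ("overall") and per fold when fold labels are present.
    """
    table, excluded = per_patient_table(manifest)
    if table.empty:
        return CohortReport(per_patient=table, overall={}, per_fold={}, excluded=excluded)
    overall = _stats_blocks(table)
    per_fold: dict = {}
    if "fold" in table.columns and table["fold"].notna().all():
        for fold, sub in table.groupby("fold", sort=True):
            per_fold[f"fold_{int(fold)}"] = _stats_blocks(sub)
    return CohortReport(per_patient=table, overall=overall, per_fold=per_fold, excluded=excluded)
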