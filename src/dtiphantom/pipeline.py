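"""End-to-end study analysis: segmentation -> tensor fit -> QA -> agreement.

``analyse_study`` runs the central processing pipeline over a
:class:`~dtiphantom.io.StudySet`: per-stack tube ROIs, tensor fits on the
chosen b-value combination, the tidy QA table (MD/FA ROI summaries, per-tube
precision CV, SNR, tube-1 drift and stability), accuracy against the water
reference and against the PGSE cross-site consensus, grouped CVs, per-tube
Bland--Altman and bootstrap repeatability, and (optionally) the b-value
combination RMSD sweep on the custom-sequence arms.

Every number in the rendered report is taken from the tables assembled
here; the report never recomputes anything ad hoc.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import (
    BlandAltmanResult,
    BootstrapResult,
    GroupedCV,
    bland_altman,
    bootstrap_diff,
    grouped_cv,
)
from .io import DWIStack, StudySet
from .qa import (
    BComboResult,
    STANDARD_BCOMBOS,
    accuracy,
    bcombo_sweep,
    drift,
    precision_cv,
    roi_summary,
    snr_map,
    snr_roi_mean,
    stability_sd,
    summaries_to_frame,
)
from .reference import ReferenceDiffusivity, water_reference
from .segment import ROISet, circular_rois, detect_tube_centres
from .tensor import fit_tensor_lls, repetition_series, select_bvalues

log = logging.getLogger("dtiphantom")

__all__ = ["StudyAnalysis", "build_rois", "analyse_study", "render_report", "write_outputs"]


@dataclass
class StudyAnalysis:
    qatable: pd.DataFrame
    accuracy_table: pd.DataFrame
    grouped_cvs: list[GroupedCV]
    bland_altman_table: pd.DataFrame
    bootstrap_table: pd.DataFrame
    bcombo_results: list[BComboResult] | None
    reference: ReferenceDiffusivity
    params: dict = field(default_factory=dict)


def build_rois(stack: DWIStack, radius_mm: float = 8.0, centres=None) -> ROISet:
    """Tube ROIs for one stack: configured centres, layout centres carried in
    the stack metadata, or automatic detection from the mean low-b image."""
    if centres is None:
        centres = stack.meta.get("tube_centres_mm")
    if centres is None:
        lowb = stack.scheme.volumes_matching(stack.scheme.b_low)
        mid = stack.grid_shape[2] // 2
        mean_img = stack.signal[:, :, mid, lowb].mean(axis=-1)
        centres = detect_tube_centres(mean_img, 7, stack.voxel_size[:2])
    return circular_rois(
        centres, radius_mm, stack.grid_shape, stack.voxel_size, tube_indices=None
    )


def _stack_records(stack: DWIStack, rois: ROISet, combo) -> list[dict]:
    """QA rows for one stack: MD/FA summaries, CV (scan 1), SNR, tube-1
    drift and stability."""
    sub = select_bvalues(stack, combo)
    union = np.zeros(stack.grid_shape, dtype=bool)
    for tube in rois.tube_indices:
        union |= rois[tube]
    fieldfit = fit_tensor_lls(sub, roi_mask=union)
    records = [r.__dict__ for r in roi_summary(fieldfit, rois, stack.meta)]
    meta = stack.meta
    base = {
        "site": str(meta.get("site", "?")),
        "sequence_class": str(meta.get("sequence_class", "?")),
        "scan": int(meta.get("scan", 1)),
    }
    if base["scan"] == 1:
        for tube in rois.tube_indices:
            records.append(
                dict(
                    base,
                    tube=tube,
                    metric="CV_MD",
                    roi_mean=precision_cv(fieldfit, rois[tube], "MD"),
                    roi_sd=np.nan,
                    n_voxels=int((rois[tube] & fieldfit.valid).sum()),
                )
            )
    try:
        snr = snr_map(stack)
        for tube in rois.tube_indices:
            values = snr[rois[tube]]
            finite = values[np.isfinite(values)]
            if finite.size:
                records.append(
                    dict(
                        base,
                        tube=tube,
                        metric="SNR",
                        roi_mean=float(finite.mean()),
                        roi_sd=float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0,
                        n_voxels=int(finite.size),
                    )
                )
    except ValueError:
        log.info("SNR skipped for %s (insufficient repetitions)", base)
    try:
        md_series, fa_series = repetition_series(stack, combo, rois[1])
        d_abs, d_pct = drift(md_series)
        records.append(
            dict(base, tube=1, metric="MD_drift_pct", roi_mean=d_pct, roi_sd=np.nan, n_voxels=md_series.size)
        )
        records.append(
            dict(base, tube=1, metric="MD_stability_sd", roi_mean=stability_sd(md_series), roi_sd=np.nan, n_voxels=md_series.size)
        )
    except ValueError:
        log.info("drift/stability skipped for %s (too few repetitions)", base)
    return records


def _scan_avg_md(qatable: pd.DataFrame) -> pd.DataFrame:
    md = qatable[qatable["metric"] == "MD"]
    return md.groupby(["site", "sequence_class", "tube"], as_index=False)["roi_mean"].mean()


def analyse_study(
    study: StudySet,
    roi_radius_mm: float = 8.0,
    combo: Sequence = (100, 450),
    reference: str = "water",
    bootstrap_n: int = 1000,
    seed: int = 0,
    sweep: bool = False,
    sweep_sequences: tuple[str, ...] = ("SE", "STEAM"),
) -> StudyAnalysis:
    """Run the full central analysis over a study set."""
    records: list[dict] = []
    roi_cache: dict[tuple[str, str, int], ROISet] = {}
    for key, stack in study.items():
        rois = build_rois(stack, radius_mm=roi_radius_mm)
        roi_cache[key] = rois
        records.extend(_stack_records(stack, rois, combo))
        log.info("analysed %s: %d rows", key, len(records))
    qatable = pd.DataFrame(records)

    ref = water_reference(0.0)
    avg = _scan_avg_md(qatable)

    acc_rows = []
    for _, row in avg[avg["tube"] == 1].iterrows():
        res = accuracy(row["roi_mean"], ref.d_ref, tube=1, site=row["site"], reference_kind="water_dref")
        acc_rows.append(
            {
                "site": row["site"],
                "sequence_class": row["sequence_class"],
                "tube": 1,
                "accuracy_pct": res.accuracy_pct,
                "reference_kind": "water_dref",
            }
        )
    pgse = avg[avg["sequence_class"] == "PGSE"]
    if not pgse.empty:
        consensus = pgse.groupby("tube")["roi_mean"].mean()
        for _, row in avg.iterrows():
            res = accuracy(
                row["roi_mean"],
                float(consensus[row["tube"]]),
                tube=int(row["tube"]),
                site=row["site"],
                reference_kind="pgse_consensus",
            )
            acc_rows.append(
                {
                    "site": row["site"],
                    "sequence_class": row["sequence_class"],
                    "tube": int(row["tube"]),
                    "accuracy_pct": res.accuracy_pct,
                    "reference_kind": "pgse_consensus",
                }
            )
    accuracy_table = pd.DataFrame(acc_rows)

    sequences = sorted(qatable["sequence_class"].unique())
    n_sites = qatable["site"].nunique()
    grouped: list[GroupedCV] = []
    both_scans = qatable.groupby(["site", "sequence_class"])["scan"].nunique().max() == 2
    if both_scans:
        grouped.append(grouped_cv(qatable, "scans"))
    if n_sites >= 2:
        for seq in sequences:
            seq_sites = qatable[qatable["sequence_class"] == seq]["site"].nunique()
            if seq_sites < 2:
                log.info("sequence %s acquired at a single site; intersite CV skipped", seq)
                continue
            grouped.append(grouped_cv(qatable, "sites", context=seq))
        for pair in (("PGSE", "SE"), ("PGSE", "STEAM"), ("SE", "STEAM")):
            if set(pair) <= set(sequences):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    grouped.append(grouped_cv(qatable, "sequences", context=pair))
    else:
        log.info("single-site study: intersite and intersequence CVs not computed")

    ba_rows, boot_rows = [], []
    md = qatable[qatable["metric"].isin(["MD", "FA"])]
    pivot = md.pivot_table(
        index=["sequence_class", "tube", "site", "metric"], columns="scan", values="roi_mean"
    )
    if both_scans and {1, 2} <= set(pivot.columns):
        for (seq, tube, metric), grp in pivot.groupby(["sequence_class", "tube", "metric"]):
            pairs = grp[[1, 2]].dropna().to_numpy()
            if pairs.shape[0] < 2:
                continue
            ba = bland_altman(pairs)
            ba_rows.append(
                {
                    "sequence_class": seq,
                    "tube": int(tube),
                    "metric": metric,
                    "mean_diff": ba.mean_diff,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "regression_slope": ba.regression_slope,
                    "regression_r2": ba.regression_r2,
                    "n_pairs": ba.n_pairs,
                }
            )
            boot = bootstrap_diff(pairs[:, 1] - pairs[:, 0], n=bootstrap_n, seed=seed)
            boot_rows.append(
                {
                    "sequence_class": seq,
                    "tube": int(tube),
                    "metric": metric,
                    "median": boot.median,
                    "ci_low": boot.ci_low,
                    "ci_high": boot.ci_high,
                    "n_resamples": boot.n_resamples,
                }
            )
    else:
        warnings.warn("scan 2 missing for every arm; repeatability sections skipped")
    bland_altman_table = pd.DataFrame(ba_rows)
    bootstrap_table = pd.DataFrame(boot_rows)

    bcombo_results = None
    if sweep:
        scan_pairs = []
        for site, seq in study.site_sequences():
            if seq not in sweep_sequences:
                continue
            if (site, seq, 2) not in study:
                continue
            s1, s2 = study.scan_pair(site, seq)
            scan_pairs.append((s1, s2, roi_cache[(site, seq, 1)][1]))
        if scan_pairs:
            bcombo_results = bcombo_sweep(scan_pairs, STANDARD_BCOMBOS)

    return StudyAnalysis(
        qatable=qatable,
        accuracy_table=accuracy_table,
        grouped_cvs=grouped,
        bland_altman_table=bland_altman_table,
        bootstrap_table=bootstrap_table,
        bcombo_results=bcombo_results,
        reference=ref,
        params={
            "roi_radius_mm": roi_radius_mm,
            "combo": list(combo),
            "reference": reference,
            "bootstrap_n": bootstrap_n,
            "seed": seed,
        },
    )


def _fmt_md(v: float) -> str:
    return f"{v * 1e3:.3f}"


def render_report(analysis: StudyAnalysis) -> str:
    """Human-readable summary, generated entirely from the result tables.

    MD is printed to 3 decimals in 1e-3 mm^2/s, FA to 3 decimals, CV and
    accuracy to 1 decimal.
    """
    out = []
    qa = analysis.qatable
    out.append("Multicentre diffusion phantom QA report")
    out.append(f"b-value combination: {analysis.params['combo']}; ROI radius "
               f"{analysis.params['roi_radius_mm']} mm")
    out.append(f"Water reference diffusivity at 0 degC: {_fmt_md(analysis.reference.d_ref)} x10-3 mm2/s")
    out.append("")
    out.append("MD and FA by tube and sequence (mean +/- SD across sites and scans)")
    md = qa[qa["metric"].isin(["MD", "FA"])]
    for metric in ("MD", "FA"):
        sub = md[md["metric"] == metric]
        for tube, tube_grp in sub.groupby("tube"):
            cells = []
            for seq, seq_grp in tube_grp.groupby("sequence_class"):
                vals = seq_grp["roi_mean"].to_numpy()
                sd = np.std(vals, ddof=1) if vals.size > 1 else 0.0
                if metric == "MD":
                    cells.append(f"{seq}: {_fmt_md(vals.mean())} +/- {_fmt_md(sd)}")
                else:
                    cells.append(f"{seq}: {vals.mean():.3f} +/- {sd:.3f}")
            out.append(f"  {metric} tube {tube}: " + "; ".join(cells))
    out.append("")
    acc = analysis.accuracy_table
    water = acc[acc["reference_kind"] == "water_dref"]
    if not water.empty:
        out.append("Tube-1 MD accuracy vs water reference (percent, mean across sites)")
        for seq, grp in water.groupby("sequence_class"):
            out.append(f"  {seq}: {grp['accuracy_pct'].mean():+.1f}%")
        out.append("")
    cv1 = qa[qa["metric"] == "CV_MD"]
    if not cv1.empty:
        out.append("Within-ROI precision CV (scan 1, percent, mean across sites)")
        for seq, grp in cv1.groupby("sequence_class"):
            by_tube = ", ".join(
                f"T{int(t)}: {g['roi_mean'].mean():.1f}" for t, g in grp.groupby("tube")
            )
            out.append(f"  {seq}: {by_tube}")
        out.append("")
    if analysis.grouped_cvs:
        out.append("Grouped coefficients of variation of MD (percent)")
        for g in analysis.grouped_cvs:
            if g.n_groups == 0:
                continue
            ctx = f", {g.context}" if g.context else ""
            out.append(f"  CV({g.grouping}{ctx}) = {g.cv_pct:.1f}% over {g.n_groups} groups")
        out.append("")
    ba = analysis.bland_altman_table
    if not ba.empty:
        out.append("Bland-Altman tube-1 MD (scan 2 - scan 1, 1e-5 mm2/s)")
        t1 = ba[(ba["tube"] == 1) & (ba["metric"] == "MD")]
        for _, row in t1.iterrows():
            half = (row["loa_high"] - row["loa_low"]) / 2.0
            out.append(
                f"  {row['sequence_class']}: {row['mean_diff'] * 1e5:.2f} +/- {half * 1e5:.2f}"
                f" (R2 {row['regression_r2']:.2f}, n={int(row['n_pairs'])})"
            )
        out.append("")
    if analysis.bcombo_results:
        out.append("b-value combination sweep (tube-1 MD RMSD between scans, 1e-3 mm2/s)")
        for res in analysis.bcombo_results:
            mark = "  <- selected" if res.is_selected else ""
            out.append(f"  {res.combo}: RMSD {_fmt_md(res.rmsd)}{mark}")
        out.append("")
    return "\n".join(out)


def write_outputs(analysis: StudyAnalysis, outdir: str | Path) -> dict:
    """Write tidy CSVs, a JSON summary and the text report; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    analysis.qatable.to_csv(outdir / "qatable.csv", index=False)
    paths["qatable"] = str(outdir / "qatable.csv")
    analysis.accuracy_table.to_csv(outdir / "accuracy.csv", index=False)
    paths["accuracy"] = str(outdir / "accuracy.csv")
    if not analysis.bland_altman_table.empty:
        analysis.bland_altman_table.to_csv(outdir / "bland_altman.csv", index=False)
        paths["bland_altman"] = str(outdir / "bland_altman.csv")
    if not analysis.bootstrap_table.empty:
        analysis.bootstrap_table.to_csv(outdir / "bootstrap.csv", index=False)
        paths["bootstrap"] = str(outdir / "bootstrap.csv")
    grouped = [
        {"grouping": g.grouping, "context": g.context, "cv_pct": g.cv_pct,
         "n_groups": g.n_groups, "per_tube": {str(k): v for k, v in g.per_tube.items()}}
        for g in analysis.grouped_cvs
    ]
    summary = {
        "params": analysis.params,
        "reference_d0_mm2_per_s": analysis.reference.d_ref,
        "grouped_cv": grouped,
    }
    if analysis.bcombo_results:
        summary["bcombo"] = [
            {"combo": [str(b) for b in r.combo], "rmsd": r.rmsd, "selected": r.is_selected}
            for r in analysis.bcombo_results
        ]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    paths["summary"] = str(outdir / "summary.json")
    report = render_report(analysis)
    (outdir / "report.txt").write_text(report)
    paths["report"] = str(outdir / "report.txt")
    return paths
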