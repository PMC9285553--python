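"""Per-scan QA statistics for the multicentre phantom study.

Covers the per-tube ROI summaries, accuracy against a reference diffusivity,
within-ROI precision (coefficient of variation), the temporal SNR map,
signal drift and stability across repetitions, scan-1 vs scan-2 root mean
squared differences, the b-value-combination RMSD sweep used to choose the
reconstruction b-values, and the thermal-equilibration check.

Conventions: all standard deviations are sample SDs (ddof = 1); accuracy and
CV are percentages; MD values are mm^2/s throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DWIStack
from .segment import ROISet
from .tensor import TensorField, fit_tensor_lls, resolve_combo, select_bvalues

__all__ = [
    "ROISummary",
    "AccuracyResult",
    "BComboResult",
    "STANDARD_BCOMBOS",
    "roi_summary",
    "accuracy",
    "precision_cv",
    "snr_map",
    "snr_roi_mean",
    "drift",
    "stability_sd",
    "rmsd",
    "bcombo_sweep",
    "equilibration_check",
]

#: The seven b-value combinations assessed for the reconstruction choice.
STANDARD_BCOMBOS = (
    ("b_low", 100),
    ("b_low", 300),
    ("b_low", 450),
    (100, 300),
    (100, 450),
    (300, 450),
    ("b_low", 100, 300, 450),
)


@dataclass(frozen=True)
class ROISummary:
    """Mean / sample-SD of one metric over one tube ROI of one scan."""

    site: str
    sequence_class: str
    scan: int
    tube: int
    metric: str
    roi_mean: float
    roi_sd: float
    n_voxels: int


@dataclass(frozen=True)
class AccuracyResult:
    """Relative MD error of one tube at one site, percent."""

    tube: int
    site: str
    accuracy_pct: float
    reference_kind: str  # "water_dref" or "pgse_consensus"


@dataclass(frozen=True)
class BComboResult:
    """Scan-1/scan-2 agreement of one b-value combination."""

    combo: tuple
    md_mean_scan1: float
    md_mean_scan2: float
    rmsd: float
    is_selected: bool = False


def roi_summary(
    field: TensorField,
    roiset: ROISet,
    meta: Mapping,
    metrics: Sequence[str] = ("MD", "FA"),
) -> list[ROISummary]:
    """Per-tube mean and sample SD of tensor metrics over valid ROI voxels."""
    records = []
    for tube in roiset.tube_indices:
        for metric in metrics:
            values = field.roi_values(roiset[tube], metric)
            values = values[np.isfinite(values)]
            if values.size < 1:
                raise ValueError(f"no valid voxels in tube {tube} ROI")
            sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
            records.append(
                ROISummary(
                    site=str(meta.get("site", "?")),
                    sequence_class=str(meta.get("sequence_class", "?")),
                    scan=int(meta.get("scan", 1)),
                    tube=tube,
                    metric=metric,
                    roi_mean=float(values.mean()),
                    roi_sd=sd,
                    n_voxels=int(values.size),
                )
            )
    return records


def summaries_to_frame(records: Sequence[ROISummary]) -> pd.DataFrame:
    """Tidy QA table: one row per (site, sequence, scan, tube, metric)."""
    return pd.DataFrame([r.__dict__ for r in records])


def accuracy(
    md_mean: float, md_ref: float, tube: int = 1, site: str = "?", reference_kind: str = "water_dref"
) -> AccuracyResult:
    """Relative MD error, percent: (MD_mean - MD_ref) / MD_ref * 100.

    ``md_mean`` should be the ROI mean averaged over both scans; ``md_ref``
    is either the water reference diffusivity (tube 1) or the PGSE
    cross-site consensus for the tube.
    """
    if md_ref <= 0:
        raise ValueError("reference MD must be > 0")
    pct = (md_mean - md_ref) / md_ref * 100.0
    return AccuracyResult(tube=tube, site=site, accuracy_pct=float(pct), reference_kind=reference_kind)


def precision_cv(field: TensorField, roi_mask: np.ndarray, metric: str = "MD") -> float:
    """Within-ROI coefficient of variation, percent (scan-1 precision)."""
    values = field.roi_values(roi_mask, metric)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("at least two valid voxels required")
    mean = values.mean()
    if mean == 0:
        raise ValueError("ROI mean is zero; CV undefined")
    return float(np.std(values, ddof=1) / mean * 100.0)


def snr_map(stack: DWIStack) -> np.ndarray:
    """Temporal SNR of the b = 100 s/mm^2 data, per voxel.

    Within each repetition the six DW direction images at b = 100 are
    averaged; the SNR is the mean over repetitions divided by the sample SD
    over repetitions of that per-repetition average.  Voxels with zero SD
    (noise-free input) are flagged infinite.
    """
    scheme = stack.scheme
    if scheme.repetition_index is None:
        raise ValueError("scheme has no repetition structure")
    b100 = scheme.volumes_matching(100.0)
    if not np.any(b100):
        raise ValueError("no b = 100 s/mm^2 volumes")
    per_rep = []
    for rep_mask in scheme.repetition_masks():
        sel = rep_mask & b100
        if not sel.any():
            continue
        per_rep.append(stack.signal[..., sel].mean(axis=-1))
    if len(per_rep) < 2:
        raise ValueError("at least two repetitions of the b = 100 shell required")
    series = np.stack(per_rep, axis=-1)
    mean = series.mean(axis=-1)
    sd = series.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = mean / sd
    snr[sd == 0] = np.inf
    return snr


def snr_roi_mean(snr: np.ndarray, roi_mask: np.ndarray) -> float:
    """ROI-mean SNR, excluding flagged (non-finite) voxels."""
    values = snr[roi_mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite SNR values in ROI (noise-free data?)")
    return float(values.mean())


def drift(series: np.ndarray, window: int = 5) -> tuple[float, float]:
    """Drift of a per-repetition series after sliding-window smoothing.

    The series is smoothed with a moving average over ``window`` repetitions
    (valid windows only, no edge padding); drift is the last smoothed value
    minus the first, also expressed as a percentage of the first.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1D")
    if series.size < window:
        raise ValueError(f"series length {series.size} shorter than window {window}")
    smoothed = np.convolve(series, np.ones(window) / window, mode="valid")
    absolute = float(smoothed[-1] - smoothed[0])
    percent = float(absolute / smoothed[0] * 100.0) if smoothed[0] != 0 else np.nan
    return absolute, percent


def stability_sd(series: np.ndarray) -> float:
    """Sample SD of the raw (unsmoothed) per-repetition series."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("at least two repetitions required")
    return float(np.std(series, ddof=1))


def rmsd(values_scan1: np.ndarray, values_scan2: np.ndarray) -> float:
    """Root mean squared difference between paired scan-1/scan-2 values."""
    a = np.asarray(values_scan1, dtype=float)
    b = np.asarray(values_scan2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value arrays must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _combo_sort_key(result: BComboResult):
    combo = result.combo
    has_blow = any(isinstance(b, str) for b in combo)
    numeric = [b for b in combo if not isinstance(b, str)]
    span = (max(numeric) - min(numeric)) if len(numeric) >= 2 else 0.0
    # prefer low RMSD; on ties prefer combos without the unreliable low-b
    # volumes, then the larger b-range, then the higher top b
    return (result.rmsd, has_blow, -span, -max(numeric, default=0.0))


def bcombo_sweep(
    scan_pairs: Sequence[tuple[DWIStack, DWIStack, np.ndarray]],
    combos: Sequence[tuple] = STANDARD_BCOMBOS,
) -> list[BComboResult]:
    """RMSD of tube-1 mean MD between scans, per b-value combination.

    ``scan_pairs`` holds one (scan-1 stack, scan-2 stack, tube-1 ROI mask)
    triple per site.  For each combination the tensors are refit from the
    selected volumes, the tube-1 ROI-mean MD is computed per scan, and the
    RMSD is taken across sites.  Exactly one combination is selected: the
    minimum-RMSD one, ties resolved away from low-b-containing combos and
    towards the larger b-range.
    """
    if not scan_pairs:
        raise ValueError("at least one scan pair required")
    results = []
    for combo in combos:
        md1, md2 = [], []
        for stack1, stack2, roi in scan_pairs:
            for stack, out in ((stack1, md1), (stack2, md2)):
                field = fit_tensor_lls(select_bvalues(stack, combo), roi_mask=roi)
                out.append(float(np.nanmean(field.md[roi & field.valid])))
        results.append(
            BComboResult(
                combo=tuple(combo),
                md_mean_scan1=float(np.mean(md1)),
                md_mean_scan2=float(np.mean(md2)),
                rmsd=rmsd(np.array(md1), np.array(md2)),
            )
        )
    best = min(range(len(results)), key=lambda i: _combo_sort_key(results[i]))
    results[best] = BComboResult(
        combo=results[best].combo,
        md_mean_scan1=results[best].md_mean_scan1,
        md_mean_scan2=results[best].md_mean_scan2,
        rmsd=results[best].rmsd,
        is_selected=True,
    )
    return results


def equilibration_check(adc_consecutive: Sequence[float], tolerance_pct: float = 3.0) -> tuple[bool, float]:
    """Thermal equilibration rule: consecutive scout ADCs within 3%.

    Compares the last scout ADC mean with the previous one; passes when the
    relative change is within ``tolerance_pct``.
    """
    adc = np.asarray(adc_consecutive, dtype=float)
    if adc.size < 2:
        raise ValueError("need at least two consecutive scout ADC means")
    previous, last = adc[-2], adc[-1]
    change_pct = abs(last - previous) / previous * 100.0
    return bool(change_pct <= tolerance_pct), float(change_pct)
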