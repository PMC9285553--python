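"""Repeatability and reproducibility statistics.

Intrasite repeatability: Bland--Altman mean difference and 95% limits of
agreement (mean +/- 1.96 sample SD of the scan-2 minus scan-1 differences),
with a difference-on-average regression as the proportional-bias check.
Between-scan differences are additionally summarised by a bootstrap
(resampling the differences with replacement, the mean of each resample,
median and 2.5/97.5-percentile CI over resamples); two bootstrap results
whose 95% CIs do not overlap are deemed significantly different.

Intersite / intersequence reproducibility: grouped coefficients of
variation of the ROI- and scan-averaged mean diffusivity -- across scans
within a site, across sites within a sequence group, and across sequence
pairs within a site.

A small hypothesis-test battery mirrors the study's statistics: one-sample
t-tests against a reference, Shapiro--Wilk normality tests, Welch
two-sample t-tests, and Wilcoxon rank-sum tests using midranks for ties
with exact enumeration of the permutation distribution for combined n <= 20
(normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "BootstrapResult",
    "GroupedCV",
    "TestResult",
    "bland_altman",
    "bootstrap_diff",
    "ci_overlap_significant",
    "grouped_cv",
    "cv_percent",
    "bootstrap_cv_ci",
    "test_battery",
    "exact_rank_sum",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    regression_slope: float
    regression_r2: float
    n_pairs: int


@dataclass(frozen=True)
class BootstrapResult:
    median: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int


@dataclass(frozen=True)
class GroupedCV:
    grouping: str  # "scans" | "sites" | "sequences"
    context: str | None
    cv_pct: float
    n_groups: int
    per_tube: dict


@dataclass(frozen=True)
class TestResult:
    mode: str
    statistic: float
    pvalue: float
    n: int


def bland_altman(paired_values: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Bland--Altman agreement of paired (scan 1, scan 2) measurements.

    Differences are scan 2 minus scan 1; limits of agreement are
    mean +/- 1.96 sample SD.  The regression of difference on pair average
    yields the proportional-bias slope and R^2 (NaN when degenerate, e.g.
    identical pairs).
    """
    pairs = np.atleast_2d(np.asarray(paired_values, dtype=float))
    if pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need at least two (scan1, scan2) pairs")
    diffs = pairs[:, 1] - pairs[:, 0]
    means = pairs.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    if np.std(means) == 0 or sd == 0:
        slope, r2 = np.nan, np.nan
    else:
        slope, intercept = np.polyfit(means, diffs, 1)
        pred = slope * means + intercept
        ss_res = float(np.sum((diffs - pred) ** 2))
        ss_tot = float(np.sum((diffs - diffs.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
    return BlandAltmanResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        regression_slope=float(slope),
        regression_r2=float(r2),
        n_pairs=pairs.shape[0],
    )


def bootstrap_diff(diffs: Sequence[float], n: int = 1000, seed: int = 0) -> BootstrapResult:
    """Bootstrap the mean of between-scan differences.

    Resamples the differences with replacement at the original size ``n``
    times; the statistic is the mean of each resample.  Reports the median
    and the percentile 95% CI over resamples.  Deterministic under ``seed``.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least two differences")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diffs.size, size=(n, diffs.size))
    means = diffs[idx].mean(axis=1)
    lo, med, hi = np.percentile(means, [2.5, 50.0, 97.5])
    return BootstrapResult(
        median=float(med), ci_low=float(lo), ci_high=float(hi), n_resamples=n, seed=seed
    )


def ci_overlap_significant(a: BootstrapResult, b: BootstrapResult) -> bool:
    """True when the two 95% CIs are disjoint (the study's significance rule)."""
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


def cv_percent(values: np.ndarray) -> float:
    """Sample coefficient of variation, percent."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least two values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(np.std(values, ddof=1) / mean * 100.0)


def bootstrap_cv_ci(
    values: Sequence[float], n: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Percentile bootstrap CI for the CV of a set of group means."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    rng = np.random.default_rng(seed)
    cvs = []
    for _ in range(n):
        sample = values[rng.integers(0, values.size, size=values.size)]
        if sample.mean() == 0 or np.all(sample == sample[0]):
            cvs.append(0.0)
        else:
            cvs.append(np.std(sample, ddof=1) / sample.mean() * 100.0)
    lo, med, hi = np.percentile(cvs, [2.5, 50.0, 97.5])
    return BootstrapResult(median=float(med), ci_low=float(lo), ci_high=float(hi), n_resamples=n, seed=seed)


def _scan_averaged_md(qatable: pd.DataFrame) -> pd.DataFrame:
    """MD per (site, sequence, tube), averaged over scans."""
    md = qatable[qatable["metric"] == "MD"]
    return (
        md.groupby(["site", "sequence_class", "tube"], as_index=False)["roi_mean"].mean()
    )


def grouped_cv(
    qatable: pd.DataFrame,
    grouping: str,
    context: str | tuple[str, str] | None = None,
) -> GroupedCV:
    """Grouped coefficient of variation of mean diffusivity.

    ``qatable`` is the tidy QA table with one MD row per
    (site, sequence_class, scan, tube): columns ``site``,
    ``sequence_class``, ``scan``, ``tube``, ``metric``, ``roi_mean``.

    grouping="scans"
        CV across the two scans per (site, sequence, tube), then averaged
        over all such groups.
    grouping="sites" (context = sequence class)
        CV across sites of the scan-averaged MD, per tube, then averaged
        over tubes.
    grouping="sequences" (context = (seq_a, seq_b))
        CV across the two sequences' scan-averaged MD per (site, tube)
        where both are present, then averaged.  When no site acquired both
        sequences (e.g. the two custom sequence groups), the comparison is
        necessarily across sites as well: the per-tube CV is then computed
        over the pooled site values of either sequence (the combined
        intersite/intersequence CV).

    Groups with fewer than two members are skipped with a warning.
    """
    md = qatable[qatable["metric"] == "MD"]
    per_tube: dict[int, float] = {}
    if grouping == "scans":
        group_cvs: dict[int, list[float]] = {}
        n_groups = 0
        for (site, seq, tube), grp in md.groupby(["site", "sequence_class", "tube"]):
            if grp.shape[0] < 2:
                warnings.warn(f"scans group ({site}, {seq}, tube {tube}) has <2 members; skipped")
                continue
            group_cvs.setdefault(tube, []).append(cv_percent(grp["roi_mean"].to_numpy()))
            n_groups += 1
        per_tube = {t: float(np.mean(v)) for t, v in group_cvs.items()}
        label = None
    elif grouping == "sites":
        if context is None:
            raise ValueError("grouping='sites' needs a sequence-class context")
        avg = _scan_averaged_md(md)
        avg = avg[avg["sequence_class"] == context]
        n_groups = 0
        for tube, grp in avg.groupby("tube"):
            if grp.shape[0] < 2:
                warnings.warn(f"sites group (tube {tube}, {context}) has <2 members; skipped")
                continue
            per_tube[int(tube)] = cv_percent(grp["roi_mean"].to_numpy())
            n_groups += 1
        label = str(context)
    elif grouping == "sequences":
        if not isinstance(context, (tuple, list)) or len(context) != 2:
            raise ValueError("grouping='sequences' needs a (seq_a, seq_b) context")
        avg = _scan_averaged_md(md)
        pivot = avg.pivot_table(index=["site", "tube"], columns="sequence_class", values="roi_mean")
        group_cvs: dict[int, list[float]] = {}
        n_groups = 0
        for (site, tube), row in pivot.iterrows():
            pair = row.reindex(list(context)).to_numpy()
            if np.any(~np.isfinite(pair)):
                continue
            group_cvs.setdefault(int(tube), []).append(cv_percent(pair))
            n_groups += 1
        if n_groups == 0:
            # the sequence groups live at disjoint sites: pool site values
            # of both sequences per tube (combined intersite/sequence CV)
            pooled = avg[avg["sequence_class"].isin(list(context))]
            for tube, grp in pooled.groupby("tube"):
                if grp.shape[0] < 2:
                    warnings.warn(f"sequence pair {context}, tube {tube}: <2 values; skipped")
                    continue
                group_cvs.setdefault(int(tube), []).append(cv_percent(grp["roi_mean"].to_numpy()))
                n_groups += 1
            if n_groups == 0:
                warnings.warn(f"no data for sequence pair {context}")
        per_tube = {t: float(np.mean(v)) for t, v in group_cvs.items()}
        label = f"{context[0]} vs {context[1]}"
    else:
        raise ValueError("grouping must be 'scans', 'sites' or 'sequences'")
    overall = float(np.mean(list(per_tube.values()))) if per_tube else np.nan
    return GroupedCV(grouping=grouping, context=label, cv_pct=overall, n_groups=n_groups, per_tube=per_tube)


def exact_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum test by exhaustive permutation enumeration.

    Uses midranks for ties.  The p-value is the fraction of the C(n, n1)
    rank assignments whose rank-sum deviates from its expectation at least
    as much as the observed one.  Intended for combined n <= 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    expect = n1 * (n + 1) / 2.0
    dev = abs(w_obs - expect)
    count = 0
    for idx in combinations(range(n), n1):
        if abs(ranks[list(idx)].sum() - expect) >= dev - 1e-12:
            count += 1
    total = comb(n, n1)
    return TestResult(mode="rank_sum_exact", statistic=float(w_obs), pvalue=count / total, n=n)


def _rank_sum_normal(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Normal approximation with midranks and tie-corrected variance."""
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    expect = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return TestResult(mode="rank_sum_normal", statistic=float(w), pvalue=1.0, n=n)
    z = (w - expect) / sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(mode="rank_sum_normal", statistic=float(z), pvalue=float(min(p, 1.0)), n=n)


def test_battery(
    samples: Sequence[float],
    mode: str,
    other: Sequence[float] | None = None,
    reference: float | None = None,
) -> TestResult:
    """The study's hypothesis tests, two-sided at alpha = 0.05.

    mode="one_sample_t"  -- ``samples`` against ``reference``.
    mode="shapiro_wilk"  -- normality of ``samples``.
    mode="rank_sum"      -- ``samples`` vs ``other``; exact enumeration when
                            combined n <= 20, normal approximation otherwise.
    mode="welch_t"       -- ``samples`` vs ``other``, unequal variances
                            (Welch--Satterthwaite degrees of freedom).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("at least three observations required")
    if mode == "one_sample_t":
        if reference is None:
            raise ValueError("one_sample_t needs a reference value")
        if np.all(x == reference):
            return TestResult(mode=mode, statistic=0.0, pvalue=1.0, n=x.size)
        res = stats.ttest_1samp(x, reference)
        return TestResult(mode=mode, statistic=float(res.statistic), pvalue=float(res.pvalue), n=x.size)
    if mode == "shapiro_wilk":
        res = stats.shapiro(x)
        return TestResult(mode=mode, statistic=float(res.statistic), pvalue=float(res.pvalue), n=x.size)
    if mode in ("rank_sum", "welch_t"):
        if other is None:
            raise ValueError(f"{mode} needs a second group")
        y = np.asarray(other, dtype=float)
        if y.size < 3:
            raise ValueError("at least three observations required per group")
        if mode == "welch_t":
            res = stats.ttest_ind(x, y, equal_var=False)
            return TestResult(
                mode=mode, statistic=float(res.statistic), pvalue=float(res.pvalue), n=x.size + y.size
            )
        if x.size + y.size <= 20:
            return exact_rank_sum(x, y)
        return _rank_sum_normal(x, y)
    raise ValueError(f"unknown mode {mode!r}")
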