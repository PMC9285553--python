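"""Optional diagnostic plots (Bland--Altman, bootstrap histograms)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import BlandAltmanResult, BootstrapResult

__all__ = ["plot_bland_altman", "plot_bootstrap_hist"]


def plot_bland_altman(
    paired_values: Sequence[tuple[float, float]],
    result: BlandAltmanResult,
    path: str | Path,
    title: str = "Bland-Altman",
    unit: str = "mm$^2$/s",
) -> Path:
    """Scatter of difference vs average with mean and 1.96-SD limit lines."""
    pairs = np.atleast_2d(np.asarray(paired_values, dtype=float))
    means = pairs.mean(axis=1)
    diffs = pairs[:, 1] - pairs[:, 0]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, c="tab:blue", s=25)
    ax.axhline(result.mean_diff, color="k", label="mean")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="r", linestyle="--")
    ax.set_xlabel(f"average of scans ({unit})")
    ax.set_ylabel(f"scan 2 - scan 1 ({unit})")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_bootstrap_hist(
    resampled_means: Sequence[float],
    result: BootstrapResult,
    path: str | Path,
    title: str = "Bootstrapped mean differences",
) -> Path:
    """Normalised histogram with median (solid) and 95% CI (dashed) lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(np.asarray(resampled_means, dtype=float), bins=40, density=True, color="0.7")
    ax.axvline(result.median, color="k")
    for x in (result.ci_low, result.ci_high):
        ax.axvline(x, color="k", linestyle="--")
    ax.set_title(title)
    ax.set_ylabel("density")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
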