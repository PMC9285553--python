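"""Study configuration: schema, YAML loading and the default study design.

A :class:`StudyConfig` describes everything needed to simulate and analyse a
multicentre phantom study: the phantom layout, one entry per
(site, sequence) acquisition arm (protocol low-b, repetitions, noise level,
systematic site effects), the ROI settings and the analysis settings.

``default_study_config`` reproduces the design of the multicentre study the
synthetic generator emulates: ten sites, each scanning the product PGSE
sequence plus one custom cardiac sequence (five motion-compensated SE sites,
five STEAM sites), two scans per arm, 30 repetitions, sequence-group SNR
levels of 23.3 / 19.9 / 20.8 (PGSE / SE / STEAM), per-arm low-b values as
used by the participating scanners, STEAM sites acquiring a single slice.
Per-arm MD biases are drawn from N(0, 2%) and scan-2 diffusivity shifts
from N(0, 1%) -- the scale of the intersite and interscan variation the
study reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .phantom import (
    NoiseModel,
    PhantomLayout,
    SiteAcquisition,
    SiteEffect,
    TABLE_PGSE_MD,
    default_layout,
)

__all__ = ["StudyConfig", "load_config", "default_study_config", "SEQUENCE_SNR"]

#: Tube-1 SNR by sequence group, as the QA pipeline measures it.
SEQUENCE_SNR = {"PGSE": 23.3, "SE": 19.9, "STEAM": 20.8}

#: Low-b values (s/mm^2) of the custom sequences per site; the product PGSE
#: protocol uses a true b = 0 non-DW image everywhere.
CUSTOM_SEQUENCES = {
    "A": ("SE", 5.0),
    "B": ("SE", 2.0),
    "C": ("SE", 2.0),
    "D": ("SE", 0.0),
    "E": ("SE", 5.0),
    "F": ("STEAM", 42.0),
    "G": ("STEAM", 76.0),
    "H": ("STEAM", 39.0),
    "I": ("STEAM", 20.0),
    "J": ("STEAM", 16.0),
}


@dataclass
class StudyConfig:
    layout: PhantomLayout
    sites: list[SiteAcquisition]
    roi_radius_mm: float = 8.0
    combo: tuple = (100, 450)
    reference: str = "water"
    bootstrap_n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("config lists no site acquisitions")
        if self.reference not in ("water", "pgse"):
            raise ValueError("reference must be 'water' or 'pgse'")
        if self.roi_radius_mm <= 0:
            raise ValueError("roi radius must be > 0")

    def to_dict(self) -> dict:
        return {
            "layout": {
                "grid_shape": list(self.layout.grid_shape),
                "voxel_size": list(self.layout.voxel_size),
                "tubes": [
                    {
                        "tube_index": t.tube_index,
                        "pvp_fraction": t.pvp_fraction,
                        "centre_xy": list(t.centre_xy),
                        "radius_mm": t.radius_mm,
                        "true_md": t.true_md,
                        "true_fa": t.true_fa,
                    }
                    for t in self.layout.tubes
                ],
            },
            "sites": [
                {
                    "site": s.site,
                    "sequence_class": s.sequence_class,
                    "b_low": s.b_low,
                    "n_repetitions": s.n_repetitions,
                    "noise": {"kind": s.noise.kind, "target_snr": s.noise.target_snr},
                    "effects": {
                        "md_bias_fraction": s.effects.md_bias_fraction,
                        "drift_per_repetition": s.effects.drift_per_repetition,
                        "scan2_shift_fraction": s.effects.scan2_shift_fraction,
                    },
                    "n_slices": s.n_slices,
                    "s0": s.s0,
                }
                for s in self.sites
            ],
            "roi": {"radius_mm": self.roi_radius_mm},
            "analysis": {
                "combo": list(self.combo),
                "reference": self.reference,
                "bootstrap_n": self.bootstrap_n,
            },
            "seed": self.seed,
        }


def _site_from_dict(entry: dict) -> SiteAcquisition:
    for key in ("site", "sequence_class"):
        if key not in entry:
            raise ValueError(f"site entry missing required key '{key}': {entry}")
    noise_spec = entry.get("noise", {})
    if isinstance(noise_spec, (int, float)):
        noise_spec = {"kind": "rician", "target_snr": float(noise_spec)}
    noise = NoiseModel(
        kind=noise_spec.get("kind", "rician" if "snr" in entry else "none"),
        target_snr=float(noise_spec.get("target_snr", entry.get("snr", 20.0))),
    )
    eff = entry.get("effects", {})
    effects = SiteEffect(
        md_bias_fraction=float(eff.get("md_bias_fraction", 0.0)),
        drift_per_repetition=float(eff.get("drift_per_repetition", 0.0)),
        scan2_shift_fraction=float(eff.get("scan2_shift_fraction", 0.0)),
    )
    return SiteAcquisition(
        site=str(entry["site"]),
        sequence_class=str(entry["sequence_class"]),
        b_low=float(entry.get("b_low", 0.0)),
        n_repetitions=int(entry.get("n_repetitions", 30)),
        noise=noise,
        effects=effects,
        n_slices=entry.get("n_slices"),
        s0=float(entry.get("s0", 1000.0)),
    )


def _layout_from_dict(spec: dict | None) -> PhantomLayout:
    if spec is None:
        return default_layout()
    if "tubes" in spec:
        from .phantom import TubeSpec

        tubes = tuple(
            TubeSpec(
                tube_index=int(t["tube_index"]),
                pvp_fraction=float(t.get("pvp_fraction", 0.0)),
                centre_xy=tuple(t["centre_xy"]),
                radius_mm=float(t["radius_mm"]),
                true_md=float(t["true_md"]),
                true_fa=float(t.get("true_fa", 0.0)),
            )
            for t in spec["tubes"]
        )
        return PhantomLayout(
            tubes=tubes,
            grid_shape=tuple(spec.get("grid_shape", (48, 48, 3))),
            voxel_size=tuple(spec.get("voxel_size", (2.5, 2.5, 8.0))),
        )
    return default_layout(
        grid_shape=tuple(spec.get("grid_shape", (48, 48, 3))),
        voxel_size=tuple(spec.get("voxel_size", (2.5, 2.5, 8.0))),
        tube_radius_mm=float(spec.get("tube_radius_mm", 13.0)),
        ring_radius_mm=float(spec.get("ring_radius_mm", 32.0)),
        true_mds=spec.get("true_mds", TABLE_PGSE_MD),
    )


def load_config(path_or_dict: str | Path | dict) -> StudyConfig:
    """Load and validate a study config from YAML (path) or a parsed dict."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        raw = dict(path_or_dict)
    if "sites" not in raw or not raw["sites"]:
        raise ValueError("config must list at least one site acquisition")
    layout = _layout_from_dict(raw.get("layout"))
    sites = [_site_from_dict(e) for e in raw["sites"]]
    analysis = raw.get("analysis", {})
    return StudyConfig(
        layout=layout,
        sites=sites,
        roi_radius_mm=float(raw.get("roi", {}).get("radius_mm", 8.0)),
        combo=tuple(analysis.get("combo", (100, 450))),
        reference=analysis.get("reference", "water"),
        bootstrap_n=int(analysis.get("bootstrap_n", 1000)),
        seed=int(raw.get("seed", 0)),
    )


def default_study_config(
    seed: int = 0,
    intersite_md_sd: float = 0.02,
    scan_shift_sd: float = 0.01,
    with_noise: bool = True,
    n_repetitions: int = 30,
) -> StudyConfig:
    """The paper-style ten-site, two-sequence-per-site study design."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD7]))
    sites: list[SiteAcquisition] = []
    for site in sorted(CUSTOM_SEQUENCES):
        custom_class, custom_blow = CUSTOM_SEQUENCES[site]
        for seq_class, b_low in (("PGSE", 0.0), (custom_class, custom_blow)):
            effects = SiteEffect(
                md_bias_fraction=float(rng.normal(0.0, intersite_md_sd)),
                drift_per_repetition=0.0,
                scan2_shift_fraction=float(rng.normal(0.0, scan_shift_sd)),
            )
            noise = (
                NoiseModel(kind="rician", target_snr=SEQUENCE_SNR[seq_class])
                if with_noise
                else NoiseModel(kind="none")
            )
            sites.append(
                SiteAcquisition(
                    site=site,
                    sequence_class=seq_class,
                    b_low=b_low,
                    n_repetitions=n_repetitions,
                    noise=noise,
                    effects=effects,
                    n_slices=1 if seq_class == "STEAM" else None,
                )
            )
    return StudyConfig(layout=default_layout(), sites=sites, seed=seed)
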