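"""Synthetic multi-tube PVP phantom DWI generation.

Emulates the study design the analysis pipeline assumes: seven 50-ml tubes
of 0--20% polyvinylpyrrolidone (PVP) in an ice-water bath at 0 degC, each an
isotropic Gaussian diffusion standard with known diffusivity, scanned with
the standardised icosahedral 6-direction scheme at b = 100/300/450 s/mm^2
plus one low-b volume, 30 repetitions, two scans per site, sites split into
PGSE / motion-compensated SE / STEAM sequence groups.

The forward model is the monoexponential tensor signal
``S = S0 * exp(-b * g^T D g)``; for the isotropic tubes D = MD * I so signal
depends on b only.  Magnitude noise is Rician: each voxel becomes
``sqrt((S + n1)^2 + n2^2)`` with n1, n2 independent zero-mean Gaussians.
The noise scale is calibrated so that the QA pipeline's SNR definition
(temporal mean/SD of the six-direction-averaged b = 100 images) matches the
requested ``target_snr``: averaging six independent images reduces the noise
SD by sqrt(6), so ``sigma = sqrt(6) * S_ref / target_snr`` with S_ref the
mean noise-free b = 100 tube-1 signal.

Per-site systematic effects (relative MD bias, per-repetition signal drift,
a scan-2 diffusivity shift) model the between-site and between-scan
variation a multicentre study exhibits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import (
    AcquisitionScheme,
    DWIStack,
    StudySet,
    protocol_scheme,
)

__all__ = [
    "TubeSpec",
    "PhantomLayout",
    "NoiseModel",
    "SiteEffect",
    "SiteAcquisition",
    "TABLE_PGSE_MD",
    "WATER_MD_0C",
    "PVP_FRACTIONS",
    "default_layout",
    "tube_masks",
    "simulate_signal",
    "add_rician_noise",
    "simulate_study",
    "tensor_forward_signal",
    "axisymmetric_eigenvalues",
]

#: Consensus tube mean diffusivities for the PGSE product sequence,
#: tubes 1-7 (0, 2.5, 5, 7.5, 10, 15, 20 % PVP), mm^2/s.  These are the
#: default ground truths of the synthetic phantom.
TABLE_PGSE_MD = tuple(
    v * 1e-3 for v in (1.124, 1.046, 0.953, 0.899, 0.839, 0.713, 0.607)
)

#: Reference self-diffusion of water at 0 degC (quadratic extrapolation of
#: literature data), mm^2/s -- the "ideal water" alternative for tube 1.
WATER_MD_0C = 1.113e-3

PVP_FRACTIONS = (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class TubeSpec:
    """One PVP tube: position, size and ground-truth diffusion properties."""

    tube_index: int
    pvp_fraction: float
    centre_xy: tuple[float, float]  # mm
    radius_mm: float
    true_md: float  # mm^2/s
    true_fa: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.tube_index <= 7:
            raise ValueError("tube_index must be 1..7")
        if self.true_md <= 0:
            raise ValueError("true_md must be > 0")
        if not 0.0 <= self.true_fa < 1.0:
            raise ValueError("true_fa must be in [0, 1)")
        if self.radius_mm <= 0:
            raise ValueError("tube radius must be > 0")


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry and ground truth of the multi-tube phantom.

    ``bath_radius_mm`` is optional: when set, voxels inside that circle but
    outside every tube carry ``outer_bath_diffusivity``; background voxels
    are zero signal either way.
    """

    tubes: tuple[TubeSpec, ...]
    grid_shape: tuple[int, int, int] = (48, 48, 3)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 8.0)
    outer_bath_diffusivity: float = WATER_MD_0C
    bath_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if len(self.tubes) < 1:
            raise ValueError("layout needs at least one tube")
        object.__setattr__(self, "tubes", tuple(self.tubes))
        fov = (self.grid_shape[0] * self.voxel_size[0], self.grid_shape[1] * self.voxel_size[1])
        for t in self.tubes:
            if not (
                t.radius_mm <= t.centre_xy[0] <= fov[0] - t.radius_mm
                and t.radius_mm <= t.centre_xy[1] <= fov[1] - t.radius_mm
            ):
                raise ValueError(f"tube {t.tube_index} footprint outside the grid")

    @property
    def centres_xy(self) -> np.ndarray:
        return np.array([t.centre_xy for t in self.tubes])

    def true_md_by_tube(self) -> dict[int, float]:
        return {t.tube_index: t.true_md for t in self.tubes}

    def with_md_scale(self, factor: float) -> "PhantomLayout":
        """Layout with every tube's (and the bath's) diffusivity scaled."""
        tubes = tuple(replace(t, true_md=t.true_md * factor) for t in self.tubes)
        return replace(
            self, tubes=tubes, outer_bath_diffusivity=self.outer_bath_diffusivity * factor
        )

    def with_slices(self, n_slices: int) -> "PhantomLayout":
        return replace(self, grid_shape=(self.grid_shape[0], self.grid_shape[1], int(n_slices)))


def default_layout(
    grid_shape: tuple[int, int, int] = (48, 48, 3),
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 8.0),
    tube_radius_mm: float = 13.0,
    ring_radius_mm: float = 32.0,
    true_mds: Sequence[float] = TABLE_PGSE_MD,
) -> PhantomLayout:
    """Seven-tube layout: tube 1 (0% PVP) at the centre, tubes 2-7 on a ring.

    Tube axes run along z (the tubes stand vertically in the bath), so the
    footprints are circles in-plane, constant across slices.
    """
    if len(true_mds) != 7:
        raise ValueError("seven tube diffusivities required")
    cx = grid_shape[0] * voxel_size[0] / 2.0
    cy = grid_shape[1] * voxel_size[1] / 2.0
    tubes = [
        TubeSpec(1, PVP_FRACTIONS[0], (cx, cy), tube_radius_mm, float(true_mds[0]))
    ]
    for j in range(6):
        theta = j * math.pi / 3.0
        centre = (cx + ring_radius_mm * math.cos(theta), cy + ring_radius_mm * math.sin(theta))
        tubes.append(
            TubeSpec(j + 2, PVP_FRACTIONS[j + 1], centre, tube_radius_mm, float(true_mds[j + 1]))
        )
    return PhantomLayout(tubes=tuple(tubes), grid_shape=grid_shape, voxel_size=voxel_size)


@dataclass(frozen=True)
class NoiseModel:
    """Rician magnitude-noise description.

    ``target_snr`` is the SNR the QA pipeline would measure on the b = 100
    s/mm^2 tube-1 data (temporal mean/SD of the direction-averaged images).
    """

    kind: str = "rician"
    target_snr: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "rician"):
            raise ValueError("noise kind must be 'none' or 'rician'")
        if self.kind == "rician" and not self.target_snr > 0:
            raise ValueError("target_snr must be > 0 for rician noise")


@dataclass(frozen=True)
class SiteEffect:
    """Systematic per-site deviations from the shared ground truth."""

    md_bias_fraction: float = 0.0
    drift_per_repetition: float = 0.0
    scan2_shift_fraction: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.md_bias_fraction, self.drift_per_repetition, self.scan2_shift_fraction):
            if not math.isfinite(v):
                raise ValueError("site effects must be finite")


@dataclass(frozen=True)
class SiteAcquisition:
    """One (site, sequence) arm of the study: protocol + noise + effects."""

    site: str
    sequence_class: str
    b_low: float = 0.0
    n_repetitions: int = 30
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(kind="none"))
    effects: SiteEffect = field(default_factory=SiteEffect)
    n_slices: int | None = None
    s0: float = 1000.0


def _voxel_centres(grid_shape, voxel_size):
    """In-plane voxel-centre coordinates in mm; centres at (i + 0.5) * size."""
    xs = (np.arange(grid_shape[0]) + 0.5) * voxel_size[0]
    ys = (np.arange(grid_shape[1]) + 0.5) * voxel_size[1]
    return np.meshgrid(xs, ys, indexing="ij")


def tube_masks(layout: PhantomLayout) -> dict[int, np.ndarray]:
    """3D boolean footprint per tube (voxel centre inside the circle).

    No sub-voxel partial-volume mixing: a voxel belongs to a tube iff its
    centre is inside the circle.  Overlapping tubes are an error.
    """
    gx, gy = _voxel_centres(layout.grid_shape, layout.voxel_size)
    masks: dict[int, np.ndarray] = {}
    claimed = np.zeros(layout.grid_shape[:2], dtype=bool)
    for tube in layout.tubes:
        inside = (gx - tube.centre_xy[0]) ** 2 + (gy - tube.centre_xy[1]) ** 2 <= tube.radius_mm**2
        if np.any(inside & claimed):
            raise ValueError(f"tube {tube.tube_index} overlaps another tube")
        claimed |= inside
        masks[tube.tube_index] = np.repeat(
            inside[:, :, None], layout.grid_shape[2], axis=2
        )
    return masks


def axisymmetric_eigenvalues(md: float, fa: float) -> tuple[float, float, float]:
    """Eigenvalues of an axially symmetric (prolate) tensor with given MD/FA."""
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must be in [0, 1)")
    delta = fa * math.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    return md * (1 + 2 * delta), md * (1 - delta), md * (1 - delta)


def tensor_forward_signal(
    tensor: np.ndarray, scheme: AcquisitionScheme, s0: float = 1000.0
) -> np.ndarray:
    """Noise-free monoexponential signal of one tensor over a scheme."""
    tensor = np.asarray(tensor, dtype=float)
    g = scheme.directions
    adc = np.einsum("vi,ij,vj->v", g, tensor, g)
    return s0 * np.exp(-scheme.bvalues * adc)


def simulate_signal(
    layout: PhantomLayout,
    scheme: AcquisitionScheme,
    s0: float = 1000.0,
    s0_per_tube: dict[int, float] | None = None,
) -> DWIStack:
    """Noise-free phantom stack on the layout's grid.

    Inside tube j every voxel follows ``s0 * exp(-b * d_j)`` (isotropic
    D = d_j I; for tubes with ``true_fa > 0`` an axially symmetric tensor
    oriented along z with the requested MD/FA is used instead).  Bath voxels
    (when a bath radius is set) use the bath diffusivity; background is 0.
    ``s0_per_tube`` optionally overrides the flat proton density per tube,
    e.g. to emulate T1/T2 weighting differences.
    """
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    masks = tube_masks(layout)
    signal = np.zeros(layout.grid_shape + (len(scheme),), dtype=float)
    for tube in layout.tubes:
        amp = (s0_per_tube or {}).get(tube.tube_index, s0)
        if tube.true_fa > 0:
            lam = axisymmetric_eigenvalues(tube.true_md, tube.true_fa)
            tensor = np.diag([lam[1], lam[2], lam[0]])  # principal axis along z
            decay = tensor_forward_signal(tensor, scheme, 1.0)
        else:
            decay = np.exp(-scheme.bvalues * tube.true_md)
        signal[masks[tube.tube_index]] = amp * decay
    if layout.bath_radius_mm is not None:
        gx, gy = _voxel_centres(layout.grid_shape, layout.voxel_size)
        cx = layout.grid_shape[0] * layout.voxel_size[0] / 2.0
        cy = layout.grid_shape[1] * layout.voxel_size[1] / 2.0
        bath2d = (gx - cx) ** 2 + (gy - cy) ** 2 <= layout.bath_radius_mm**2
        bath = np.repeat(bath2d[:, :, None], layout.grid_shape[2], axis=2)
        for m in masks.values():
            bath &= ~m
        signal[bath] = s0 * np.exp(-scheme.bvalues * layout.outer_bath_diffusivity)
    return DWIStack(signal=signal, voxel_size=layout.voxel_size, scheme=scheme)


def rician_sigma(stack: DWIStack, target_snr: float, reference_mask: np.ndarray | None) -> float:
    """Gaussian noise SD calibrated to the temporal-SNR definition.

    S_ref is the mean noise-free b = 100 s/mm^2 signal over the reference
    region (tube 1 in the study); the six-direction average behind the SNR
    definition reduces the noise SD by sqrt(6).
    """
    b100 = stack.scheme.volumes_matching(100.0)
    if not np.any(b100):
        raise ValueError("scheme has no b = 100 s/mm^2 volumes to calibrate noise against")
    vols = stack.signal[..., b100]
    if reference_mask is None:
        reference_mask = np.any(vols > 0, axis=-1)
    s_ref = float(vols[reference_mask].mean())
    return math.sqrt(stack.scheme.n_directions) * s_ref / target_snr


def add_rician_noise(
    stack: DWIStack,
    noise_model: NoiseModel,
    reference_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> DWIStack:
    """Replace each voxel value S by sqrt((S + n1)^2 + n2^2).

    n1, n2 are independent zero-mean Gaussians with the calibrated sigma.
    Deterministic under a fixed seed.  ``reference_mask`` should be the
    tube-1 footprint; without one, all voxels with nonzero b = 100 signal
    calibrate the noise level.
    """
    if noise_model.kind == "none":
        return stack.copy()
    sigma = rician_sigma(stack, noise_model.target_snr, reference_mask)
    if rng is None:
        rng = np.random.default_rng(noise_model.seed)
    n1 = rng.normal(0.0, sigma, size=stack.signal.shape)
    n2 = rng.normal(0.0, sigma, size=stack.signal.shape)
    noisy = np.sqrt((stack.signal + n1) ** 2 + n2**2)
    return stack.with_signal(noisy)


def _apply_drift(stack: DWIStack, drift_per_repetition: float) -> DWIStack:
    """Multiplicative drift (1 + d)^(rep - 1) on all volumes of a repetition."""
    if drift_per_repetition == 0.0:
        return stack
    rep = stack.scheme.repetition_index
    if rep is None:
        raise ValueError("scheme has no repetition structure to apply drift over")
    factors = (1.0 + drift_per_repetition) ** rep.astype(float)
    return stack.with_signal(stack.signal * factors)


def simulate_study(
    layout: PhantomLayout,
    site_configs: Sequence[SiteAcquisition],
    seed: int = 0,
) -> StudySet:
    """Simulate the full two-scan multicentre study.

    One stack per (site, sequence, scan).  Scan 2 is regenerated with
    independent noise and with ``scan2_shift_fraction`` applied to the true
    diffusivities.  Per-arm noise seeds are derived deterministically from
    the master seed via ``numpy.random.SeedSequence`` so every arm is
    reproducible in isolation.
    """
    keys = [(c.site, c.sequence_class) for c in site_configs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (site, sequence_class) entries in site_configs")
    study = StudySet(layout=layout)
    for idx, cfg in enumerate(site_configs):
        site_layout = layout.with_md_scale(1.0 + cfg.effects.md_bias_fraction)
        if cfg.n_slices is not None:
            site_layout = site_layout.with_slices(cfg.n_slices)
        scheme = protocol_scheme(cfg.b_low, cfg.n_repetitions, cfg.sequence_class)
        masks = tube_masks(site_layout)
        for scan in (1, 2):
            scan_layout = site_layout
            if scan == 2 and cfg.effects.scan2_shift_fraction != 0.0:
                scan_layout = site_layout.with_md_scale(1.0 + cfg.effects.scan2_shift_fraction)
            stack = simulate_signal(scan_layout, scheme, s0=cfg.s0)
            stack = _apply_drift(stack, cfg.effects.drift_per_repetition)
            if cfg.noise.kind != "none":
                rng = np.random.default_rng(np.random.SeedSequence([seed, idx, scan]))
                stack = add_rician_noise(stack, cfg.noise, reference_mask=masks[1], rng=rng)
            stack.meta.update(
                {
                    "site": cfg.site,
                    "sequence_class": cfg.sequence_class,
                    "scan": scan,
                    "tube_centres_mm": [list(t.centre_xy) for t in site_layout.tubes],
                }
            )
            study.add(stack)
    return study
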