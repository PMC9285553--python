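"""Core data model for diffusion-weighted image stacks and acquisition schemes.

The containers here mirror what a phantom QA pipeline needs to carry around:
an :class:`AcquisitionScheme` (per-volume b-values and unit gradient
directions, with the repetition structure of the protocol), a
:class:`DWIStack` (a 4D signal array on a voxel grid plus its scheme and
site/sequence/scan provenance), and a :class:`StudySet` collecting stacks
over a multicentre test--retest study.

Interchange is via NIfTI-1 images with FSL-dialect ``.bval``/``.bvec``
gradient tables (one whitespace-separated row of b-values; three rows of
direction components in the image coordinate frame) and an optional JSON
metadata sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionScheme",
    "DWIStack",
    "StudySet",
    "ICOSAHEDRAL_DIRECTIONS",
    "PROTOCOL_SHELLS",
    "LOW_B_PLACEHOLDER_DIRECTION",
    "SEQUENCE_CLASSES",
    "protocol_scheme",
    "read_dwi",
    "write_dwi",
]

SEQUENCE_CLASSES = ("PGSE", "SE", "STEAM")

#: Diffusion-weighting shells of the standardised DTI protocol (s/mm^2).
PROTOCOL_SHELLS = (100.0, 300.0, 450.0)

#: The prescribed icosahedral six-direction set, as printed in the protocol.
#: Norms are ~1.00004; they are renormalised before use so that the b-matrix
#: trace equals the nominal b-value.
ICOSAHEDRAL_DIRECTIONS = np.array(
    [
        [0.5257, 0.8507, 0.0],
        [0.5257, -0.8507, 0.0],
        [0.0, 0.5257, 0.8507],
        [0.0, 0.5257, -0.8507],
        [0.8507, 0.0, 0.5257],
        [-0.8507, 0.0, 0.5257],
    ]
)

#: Direction recorded for low-b volumes.  For the isotropic media this
#: package targets the choice is immaterial (the diffusion attenuation does
#: not depend on direction); real scanners may record something else.
LOW_B_PLACEHOLDER_DIRECTION = np.array([0.0, 0.0, 1.0])

_UNIT_TOL = 1e-6


def _normalise_directions(directions: np.ndarray, bvalues: np.ndarray) -> np.ndarray:
    """Renormalise nonzero direction vectors to unit length.

    Zero vectors are preserved for b = 0 volumes; a zero vector paired with
    b > 0 is a contract violation.
    """
    directions = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(directions, axis=1)
    zero = norms < 1e-12
    if np.any(zero & (bvalues > 0)):
        raise ValueError("zero gradient direction on a diffusion-weighted (b > 0) volume")
    out = directions.copy()
    out[~zero] /= norms[~zero, None]
    return out


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values and unit gradient directions for one acquisition.

    Parameters
    ----------
    bvalues : (N,) array
        Diffusion weighting per volume, s/mm^2.
    directions : (N, 3) array
        Unit gradient directions in the image frame.  Low-b volumes carry
        ``LOW_B_PLACEHOLDER_DIRECTION`` (or a zero vector when b = 0 on read).
    b_low : float
        The protocol's low-b value, s/mm^2 (0--76 across sequences; STEAM
        sequences have intrinsically higher b_low from crusher gradients).
    n_directions : int
        Number of distinct DW directions (6 for the icosahedral protocol).
    n_repetitions : int
        Number of repetitions of the volume block.
    sequence_class : str
        One of ``PGSE``, ``SE``, ``STEAM``.
    repetition_index : (N,) int array, optional
        Which repetition each volume belongs to; inferred as contiguous
        equal-sized blocks when omitted and the volume count divides evenly.
    """

    bvalues: np.ndarray
    directions: np.ndarray
    b_low: float = 0.0
    n_directions: int = 6
    n_repetitions: int = 1
    sequence_class: str = "PGSE"
    repetition_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        bvalues = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        directions = np.asarray(self.directions, dtype=float)
        if directions.shape != (bvalues.size, 3):
            raise ValueError(
                f"directions shape {directions.shape} does not match {bvalues.size} volumes"
            )
        if not np.all(np.isfinite(bvalues)):
            raise ValueError("non-finite b-values")
        if np.any(bvalues < 0):
            raise ValueError("negative b-values")
        norms = np.linalg.norm(directions, axis=1)
        bad = (np.abs(norms - 1.0) > _UNIT_TOL) & ~((norms < 1e-12) & (bvalues == 0))
        if np.any(bad):
            raise ValueError("gradient directions must be unit-norm (within 1e-6)")
        if self.sequence_class not in SEQUENCE_CLASSES:
            raise ValueError(f"sequence_class must be one of {SEQUENCE_CLASSES}")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        rep = self.repetition_index
        if rep is None and bvalues.size % self.n_repetitions == 0:
            per = bvalues.size // self.n_repetitions
            rep = np.repeat(np.arange(self.n_repetitions), per)
        if rep is not None:
            rep = np.asarray(rep, dtype=int)
            if rep.shape != bvalues.shape:
                raise ValueError("repetition_index length mismatch")
        object.__setattr__(self, "bvalues", bvalues)
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "repetition_index", rep)

    def __len__(self) -> int:
        return int(self.bvalues.size)

    @property
    def shells(self) -> tuple[float, ...]:
        """Distinct DW b-values, excluding the low-b value."""
        uniq = np.unique(self.bvalues)
        return tuple(float(b) for b in uniq if not math.isclose(b, self.b_low, abs_tol=1e-6))

    def volumes_matching(self, bvalue: float, atol: float = 1e-6) -> np.ndarray:
        """Boolean mask of volumes whose b-value equals ``bvalue``."""
        return np.isclose(self.bvalues, bvalue, atol=atol)

    def subset(self, index: np.ndarray) -> "AcquisitionScheme":
        """Scheme restricted to the given volume index (bool mask or ints)."""
        index = np.asarray(index)
        rep = None if self.repetition_index is None else self.repetition_index[index]
        return AcquisitionScheme(
            bvalues=self.bvalues[index],
            directions=self.directions[index],
            b_low=self.b_low,
            n_directions=self.n_directions,
            n_repetitions=self.n_repetitions,
            sequence_class=self.sequence_class,
            repetition_index=rep,
        )

    def repetition_masks(self) -> list[np.ndarray]:
        """Boolean volume masks, one per repetition, in acquisition order."""
        if self.repetition_index is None:
            raise ValueError("scheme has no repetition structure")
        return [self.repetition_index == r for r in np.unique(self.repetition_index)]


def protocol_scheme(
    b_low: float = 0.0,
    n_repetitions: int = 30,
    sequence_class: str = "PGSE",
) -> AcquisitionScheme:
    """Build the standardised multicentre DTI scheme.

    Each repetition holds one low-b volume followed by the six icosahedral
    directions at b = 100, 300 and 450 s/mm^2 (19 volumes per repetition;
    570 for the default 30 repetitions).  The printed direction set is
    renormalised to unit length.
    """
    if b_low < 0:
        raise ValueError("b_low must be >= 0")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    dirs = ICOSAHEDRAL_DIRECTIONS / np.linalg.norm(ICOSAHEDRAL_DIRECTIONS, axis=1, keepdims=True)
    b_rep = [float(b_low)]
    g_rep = [LOW_B_PLACEHOLDER_DIRECTION]
    for shell in PROTOCOL_SHELLS:
        b_rep.extend([shell] * len(dirs))
        g_rep.extend(dirs)
    bvalues = np.tile(b_rep, n_repetitions)
    directions = np.vstack([np.asarray(g_rep)] * n_repetitions)
    return AcquisitionScheme(
        bvalues=bvalues,
        directions=directions,
        b_low=float(b_low),
        n_directions=len(dirs),
        n_repetitions=n_repetitions,
        sequence_class=sequence_class,
    )


@dataclass
class DWIStack:
    """A 4D diffusion-weighted signal array with its scheme and provenance.

    ``signal`` is indexed (x, y, z, volume); ``voxel_size`` is in mm.
    ``meta`` carries site id, sequence class, scan index (1 or 2) and, when
    known, tube-centre coordinates in mm.
    """

    signal: np.ndarray
    voxel_size: tuple[float, float, float]
    scheme: AcquisitionScheme
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError(
                f"volume axis ({self.signal.shape[-1]}) does not match scheme "
                f"({len(self.scheme)} volumes)"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative (magnitude data)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive values (mm)")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def copy(self) -> "DWIStack":
        return DWIStack(self.signal.copy(), self.voxel_size, self.scheme, dict(self.meta))

    def with_signal(self, signal: np.ndarray) -> "DWIStack":
        return DWIStack(signal, self.voxel_size, self.scheme, dict(self.meta))


class StudySet:
    """Stacks of a multicentre study, keyed (site, sequence_class, scan)."""

    def __init__(self, layout=None) -> None:
        self._stacks: dict[tuple[str, str, int], DWIStack] = {}
        self.layout = layout

    def add(self, stack: DWIStack) -> None:
        site = stack.meta.get("site")
        seq = stack.meta.get("sequence_class", stack.scheme.sequence_class)
        scan = int(stack.meta.get("scan", 1))
        if site is None:
            raise ValueError("stack meta must carry a 'site' id")
        if scan not in (1, 2):
            raise ValueError("scan index must be 1 or 2")
        key = (str(site), str(seq), scan)
        if key in self._stacks:
            raise ValueError(f"duplicate study key {key}")
        self._stacks[key] = stack

    def __getitem__(self, key: tuple[str, str, int]) -> DWIStack:
        return self._stacks[key]

    def __contains__(self, key: tuple[str, str, int]) -> bool:
        return key in self._stacks

    def __len__(self) -> int:
        return len(self._stacks)

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        return iter(self._stacks)

    def items(self):
        return self._stacks.items()

    def keys(self):
        return self._stacks.keys()

    def site_sequences(self) -> list[tuple[str, str]]:
        """Distinct (site, sequence_class) pairs present."""
        return sorted({(s, q) for (s, q, _) in self._stacks})

    def scan_pair(self, site: str, sequence_class: str) -> tuple[DWIStack, DWIStack]:
        """The (scan 1, scan 2) stacks for one site/sequence."""
        return self[(site, sequence_class, 1)], self[(site, sequence_class, 2)]


def read_dwi(
    image_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    meta: Mapping | None = None,
) -> DWIStack:
    """Read a NIfTI-1 4D image with FSL-style gradient tables.

    Directions are renormalised to unit length; zero vectors are preserved
    for b = 0 volumes.  A JSON sidecar next to the image (same stem, ``.json``)
    is merged into ``meta`` when present (explicit ``meta`` wins).
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D NIfTI image")
    bvalues = np.atleast_1d(np.loadtxt(str(bval_path), dtype=float))
    bvecs = np.atleast_2d(np.loadtxt(str(bvec_path), dtype=float))
    if bvecs.shape[0] != 3:
        raise ValueError(".bvec must have three rows (x, y, z components)")
    if bvalues.size != data.shape[-1] or bvecs.shape[1] != data.shape[-1]:
        raise ValueError(
            f"gradient table ({bvalues.size} b-values, {bvecs.shape[1]} directions) "
            f"does not match image volume count ({data.shape[-1]})"
        )
    if not np.all(np.isfinite(bvalues)):
        raise ValueError("non-finite b-values")
    directions = _normalise_directions(bvecs.T, bvalues)

    merged: dict = {}
    sidecar = _sidecar_path(image_path)
    if sidecar.exists():
        merged.update(json.loads(sidecar.read_text()))
    if meta:
        merged.update(meta)

    b_low = float(merged.get("b_low", bvalues.min()))
    n_reps = merged.get("n_repetitions")
    if n_reps is None:
        occurrences = int(np.sum(np.isclose(bvalues, b_low, atol=1e-6)))
        n_reps = occurrences if occurrences and bvalues.size % occurrences == 0 else 1
    scheme = AcquisitionScheme(
        bvalues=bvalues,
        directions=directions,
        b_low=b_low,
        n_repetitions=int(n_reps),
        sequence_class=merged.get("sequence_class", "PGSE"),
    )
    zooms = img.header.get_zooms()[:3]
    return DWIStack(signal=data, voxel_size=tuple(zooms), scheme=scheme, meta=merged)


def write_dwi(
    stack: DWIStack,
    image_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
) -> tuple[Path, Path, Path]:
    """Write a stack as NIfTI-1 (float32) + FSL .bval/.bvec + JSON sidecar.

    The .bval file is a single whitespace-separated row; the .bvec file has
    three rows.  Lossless for float32 signal.
    """
    image_path, bval_path, bvec_path = Path(image_path), Path(bval_path), Path(bvec_path)
    affine = np.diag(list(stack.voxel_size) + [1.0])
    img = nib.Nifti1Image(stack.signal.astype(np.float32), affine)
    img.header.set_zooms(stack.voxel_size + (1.0,))
    nib.save(img, str(image_path))
    np.savetxt(str(bval_path), stack.scheme.bvalues[None, :], fmt="%.8g")
    np.savetxt(str(bvec_path), stack.scheme.directions.T, fmt="%.10g")
    sidecar = _sidecar_path(image_path)
    meta = {
        k: v for k, v in stack.meta.items() if isinstance(v, (str, int, float, bool, list))
    }
    meta.setdefault("sequence_class", stack.scheme.sequence_class)
    meta["b_low"] = stack.scheme.b_low
    meta["n_repetitions"] = stack.scheme.n_repetitions
    sidecar.write_text(json.dumps(meta, indent=1))
    return image_path, bval_path, bvec_path


def write_scalar_nifti(
    array: np.ndarray, voxel_size: tuple[float, float, float], path: str | Path
) -> Path:
    """Write a 3D map (float32, or int16 for integer data) as NIfTI-1."""
    path = Path(path)
    arr = np.asarray(array)
    dtype = np.int16 if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool else np.float32
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(arr.astype(dtype), affine), str(path))
    return path


def _sidecar_path(image_path: str | Path) -> Path:
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")
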