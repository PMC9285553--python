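"""Tube ROI construction.

The QA analysis samples each tube with a fixed-radius circular region of
interest centred on the tube, well inside the tube wall so that the edge
band (where Gibbs ringing dominates in real data) is excluded.  Centres can
be supplied from a config / layout, or detected automatically from the mean
low-b image for synthetic or well-behaved data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = ["ROISet", "circular_rois", "detect_tube_centres", "DEFAULT_ROI_RADIUS_MM"]

#: Default ROI radius (mm): comfortably inside a ~13 mm-radius 50-ml tube.
DEFAULT_ROI_RADIUS_MM = 8.0


@dataclass
class ROISet:
    """Per-tube boolean voxel masks with their tube indices."""

    masks: dict[int, np.ndarray]
    radius_mm: float
    slice_selection: tuple[int, ...]

    def __post_init__(self) -> None:
        stacked = None
        for tube, mask in self.masks.items():
            if not mask.any():
                raise ValueError(f"ROI for tube {tube} is empty")
            stacked = mask.astype(int) if stacked is None else stacked + mask.astype(int)
        if stacked is not None and stacked.max() > 1:
            raise ValueError("ROIs overlap")

    @property
    def tube_indices(self) -> tuple[int, ...]:
        return tuple(sorted(self.masks))

    def __getitem__(self, tube_index: int) -> np.ndarray:
        return self.masks[tube_index]

    def label_map(self) -> np.ndarray:
        """Integer label volume (0 background, tube index elsewhere)."""
        first = next(iter(self.masks.values()))
        labels = np.zeros(first.shape, dtype=np.int16)
        for tube, mask in self.masks.items():
            labels[mask] = tube
        return labels


def circular_rois(
    centres_xy: Sequence[tuple[float, float]] | np.ndarray,
    radius_mm: float,
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    slices: Sequence[int] | None = None,
    tube_indices: Sequence[int] | None = None,
) -> ROISet:
    """Circular in-plane ROIs of a fixed radius around each centre.

    A voxel is included when its in-plane centre lies within ``radius_mm``
    of the ROI centre; the voxel containing the centre is always included,
    so ROIs are never empty.  Centres closer than twice the radius are an
    error (prevents cross-contamination between tubes).
    """
    centres = np.atleast_2d(np.asarray(centres_xy, dtype=float))
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    fov = (grid_shape[0] * voxel_size[0], grid_shape[1] * voxel_size[1])
    if np.any(centres < 0) or np.any(centres[:, 0] > fov[0]) or np.any(centres[:, 1] > fov[1]):
        raise ValueError("ROI centre outside the grid")
    for a in range(len(centres)):
        for b in range(a + 1, len(centres)):
            if np.linalg.norm(centres[a] - centres[b]) < 2 * radius_mm:
                raise ValueError(
                    f"ROI centres {a} and {b} are closer than twice the radius; "
                    "ROIs would overlap"
                )
    if slices is None:
        slices = tuple(range(grid_shape[2]))
    slices = tuple(int(s) for s in slices)
    if any(s < 0 or s >= grid_shape[2] for s in slices):
        raise ValueError("slice selection outside the grid")
    if tube_indices is None:
        tube_indices = tuple(range(1, len(centres) + 1))

    xs = (np.arange(grid_shape[0]) + 0.5) * voxel_size[0]
    ys = (np.arange(grid_shape[1]) + 0.5) * voxel_size[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    masks: dict[int, np.ndarray] = {}
    for tube, (cx, cy) in zip(tube_indices, centres):
        inplane = (gx - cx) ** 2 + (gy - cy) ** 2 <= radius_mm**2
        # guarantee the voxel containing the centre
        ci = min(int(cx / voxel_size[0]), grid_shape[0] - 1)
        cj = min(int(cy / voxel_size[1]), grid_shape[1] - 1)
        inplane[ci, cj] = True
        mask = np.zeros(grid_shape, dtype=bool)
        for s in slices:
            mask[:, :, s] = inplane
        masks[int(tube)] = mask
    return ROISet(masks=masks, radius_mm=float(radius_mm), slice_selection=slices)


def detect_tube_centres(
    mean_lowb_image: np.ndarray,
    expected_n: int,
    voxel_size: tuple[float, float],
    expected_centres: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Detect bright-disc centres on a dark background (mm coordinates).

    Otsu threshold -> connected components -> centroids of the
    ``expected_n`` largest components.  When ``expected_centres`` is given
    (e.g. from a phantom layout), the detections are re-ordered to match it
    by optimal nearest-neighbour assignment; otherwise they are returned in
    raster order.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(mean_lowb_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D in-plane image")
    thresh = threshold_otsu(img)
    labels, n_found = ndimage.label(img > thresh)
    if n_found < expected_n:
        raise ValueError(f"found {n_found} components, expected {expected_n}")
    sizes = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n_found + 1))
    keep = np.argsort(sizes)[::-1][:expected_n] + 1
    coms = ndimage.center_of_mass(img, labels, index=keep)
    centres = np.array([[(c[0] + 0.5) * voxel_size[0], (c[1] + 0.5) * voxel_size[1]] for c in coms])
    if expected_centres is not None:
        expected = np.atleast_2d(np.asarray(expected_centres, dtype=float))
        if expected.shape[0] != expected_n:
            raise ValueError("expected_centres length mismatch")
        cost = np.linalg.norm(centres[:, None, :] - expected[None, :, :], axis=-1)
        row, col = linear_sum_assignment(cost)
        ordered = np.empty_like(centres)
        ordered[col] = centres[row]
        return ordered
    order = np.lexsort((centres[:, 1], centres[:, 0]))
    return centres[order]
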