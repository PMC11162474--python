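"""Segmentation quality metrics: DSC, mean surface distance, 95% Hausdorff.

Surface voxels are foreground voxels with at least one 6-neighbor that is
background or outside the grid.  Distances are Euclidean between voxel
centers in physical millimeters (``index * spacing``); the 95th percentile
uses linear interpolation between order statistics (numpy's default), a
convention pinned by the test oracle because toolkits differ here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import BinaryMask

__all__ = [
    "SurfaceVoxelSet",
    "MetricTriple",
    "EmptyMaskError",
    "extract_surface",
    "dsc",
    "msd",
    "hd95",
    "evaluate_masks",
]

# 6-connectivity structuring element (face neighbors only)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class EmptyMaskError(ValueError):
    """Raised when a surface-distance metric receives an empty mask."""


@dataclass(frozen=True)
class SurfaceVoxelSet:
    """Set of surface voxel indices of a mask, with its spacing."""

    voxels: frozenset
    spacing: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.voxels)

    def coordinates_mm(self) -> np.ndarray:
        """(n, 3) array of surface voxel center positions in mm."""
        if not self.voxels:
            return np.empty((0, 3))
        idx = np.array(sorted(self.voxels), dtype=float)
        return idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class MetricTriple:
    """DSC (unitless), MSD (mm) and 95HD (mm) for one mask pair."""

    dsc: float
    msd: float
    hd95: float


def _surface_grid(mask: np.ndarray) -> np.ndarray:
    # border_value=0 makes out-of-grid count as background, so foreground
    # voxels on the grid boundary are surface voxels.
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return mask & ~eroded


def extract_surface(m: BinaryMask) -> SurfaceVoxelSet:
    """Extract surface voxels (6-connectivity; grid border counts as outside)."""
    surf = _surface_grid(m.grid)
    voxels = frozenset(map(tuple, np.argwhere(surf)))
    return SurfaceVoxelSet(voxels=voxels, spacing=m.spacing)


def _check_pair(y: BinaryMask, yhat: BinaryMask) -> None:
    if y.shape != yhat.shape:
        raise ValueError(f"mask shapes differ: {y.shape} vs {yhat.shape}")
    if not np.allclose(y.spacing, yhat.spacing):
        raise ValueError(f"mask spacings differ: {y.spacing} vs {yhat.spacing}")


def dsc(y: BinaryMask, yhat: BinaryMask) -> float:
    """Dice similarity coefficient ``2|y ∩ ŷ| / (|y| + |ŷ|)``.

    Both masks empty returns 1.0 (perfect agreement on absence); exactly
    one empty returns 0.0.
    """
    _check_pair(y, yhat)
    a, b = y.grid, yhat.grid
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _directed_distances(src_mm: np.ndarray, dst_mm: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distance from each src surface point to dst surface."""
    tree = cKDTree(dst_mm)
    d, _ = tree.query(src_mm, k=1)
    return np.atleast_1d(d)


def _surfaces_mm(y: BinaryMask, yhat: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    _check_pair(y, yhat)
    if y.volume_voxels == 0 or yhat.volume_voxels == 0:
        raise EmptyMaskError("surface distances are undefined for empty masks")
    sp = np.asarray(y.spacing)
    sy = np.argwhere(_surface_grid(y.grid)) * sp
    syh = np.argwhere(_surface_grid(yhat.grid)) * sp
    return sy, syh


def msd(y: BinaryMask, yhat: BinaryMask) -> float:
    """Symmetric mean surface distance in mm.

    Average of the two directed mean nearest-surface distances:
    ``(mean_a min_b ||a-b|| + mean_b min_a ||b-a||) / 2``.
    """
    sy, syh = _surfaces_mm(y, yhat)
    d_pred = _directed_distances(syh, sy).mean()
    d_true = _directed_distances(sy, syh).mean()
    return float(0.5 * (d_pred + d_true))


def hd95(y: BinaryMask, yhat: BinaryMask) -> float:
    """95th-percentile Hausdorff distance in mm.

    Max over both directions of the 95th percentile of directed
    nearest-surface distances (linear-interpolation percentile).
    """
    sy, syh = _surfaces_mm(y, yhat)
    p_pred = np.percentile(_directed_distances(syh, sy), 95)
    p_true = np.percentile(_directed_distances(sy, syh), 95)
    return float(max(p_pred, p_true))


def evaluate_masks(y: BinaryMask, yhat: BinaryMask) -> MetricTriple:
    """All three metrics for one ground-truth/prediction pair.

    MSD and 95HD are reported as ``inf`` when either mask is empty while
    the other is not, and 0 when both are empty.
    """
    d = dsc(y, yhat)
    if y.volume_voxels == 0 and yhat.volume_voxels == 0:
        return MetricTriple(dsc=d, msd=0.0, hd95=0.0)
    if y.volume_voxels == 0 or yhat.volume_voxels == 0:
        return MetricTriple(dsc=d, msd=float("inf"), hd95=float("inf"))
    return MetricTriple(dsc=d, msd=msd(y, yhat), hd95=hd95(y, yhat))
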