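"""Volumetric containers, NIfTI I/O and preprocessing.

Conventions used throughout the package
---------------------------------------
* Grids are 3D numpy arrays indexed ``grid[i, j, k]`` with 0-based voxel
  indices in the order stored in the NIfTI file (no reorientation; RAS is
  assumed on read and orientation metadata is carried but not applied).
* The physical position of a voxel center is ``origin + index * spacing``
  (mm).  Surface distances and crops use this convention.
* Resampling treats voxels as cells of extent ``spacing`` so that the total
  physical extent ``shape * spacing`` is preserved; see :func:`resample`.
* Masks are written to disk as unsigned 8-bit integers, probability and
  intensity volumes as 32-bit floats.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "VolumeError",
    "MissingVolumeFileError",
    "NonVolumetricImageError",
    "HeaderReadError",
    "ConstantGridError",
    "read_volume",
    "read_mask",
    "write_volume",
    "window_ct",
    "znormalize",
    "resample",
    "crop_centered",
    "threshold_mask",
]

Modality = Literal["CT", "PET", "PROB", "OTHER"]


class VolumeError(Exception):
    """Base class for volume handling errors."""


class MissingVolumeFileError(VolumeError, FileNotFoundError):
    """Raised when a volume path does not exist."""


class NonVolumetricImageError(VolumeError):
    """Raised when a file does not contain a 3D image."""


class HeaderReadError(VolumeError):
    """Raised when a file cannot be parsed as NIfTI."""


class ConstantGridError(VolumeError):
    """Raised when an operation requires nonzero intensity variance."""


def _check_grid(grid: np.ndarray) -> None:
    if grid.ndim != 3:
        raise NonVolumetricImageError(
            f"expected a 3D grid, got {grid.ndim} dimensions"
        )
    if min(grid.shape) < 1:
        raise NonVolumetricImageError(f"degenerate grid shape {grid.shape}")


def _check_spacing(spacing: tuple[float, ...]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing}")
    return spacing  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar field with voxel spacing, physical origin and a modality tag.

    ``PROB`` volumes must hold values in [0, 1].
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = "OTHER"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        _check_grid(self.grid)
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if self.modality == "PROB":
            lo, hi = float(self.grid.min()), float(self.grid.max())
            if lo < 0.0 or hi > 1.0:
                raise ValueError(
                    f"PROB volume values must lie in [0, 1], got [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A 3D boolean field with voxel spacing (values exactly 0 or 1)."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        _check_grid(grid)
        if grid.dtype != bool:
            uniq = np.unique(grid)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
            grid = grid.astype(bool)
        self.grid = grid
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def volume_voxels(self) -> int:
        return int(self.grid.sum())


def _affine(spacing: tuple[float, ...], origin: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, modality: Modality = "OTHER") -> ImageVolume:
    """Read a NIfTI-1/NIfTI-2 file into an :class:`ImageVolume`.

    The stored voxel order is preserved (no reorientation).  Spacing comes
    from the header zooms, origin from the affine translation.
    """
    path = Path(path)
    if not path.exists():
        raise MissingVolumeFileError(str(path))
    try:
        img = nib.load(path)
        header_zooms = img.header.get_zooms()
        data = np.asanyarray(img.dataobj)
    except MissingVolumeFileError:
        raise
    except Exception as exc:  # pragma: no cover - nibabel error variety
        raise HeaderReadError(f"cannot parse {path} as NIfTI: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NonVolumetricImageError(
            f"{path} holds a {data.ndim}D image, expected 3D"
        )
    spacing = tuple(float(z) for z in header_zooms[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(grid=data, spacing=spacing, origin=origin, modality=modality)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI file holding a binary (0/1) mask."""
    v = read_volume(path)
    return BinaryMask(grid=v.grid, spacing=v.spacing, origin=v.origin)


def write_volume(v: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask to NIfTI.

    Masks are stored as uint8, everything else as float32.  Spacing and
    origin are encoded in a diagonal affine.
    """
    path = Path(path)
    if isinstance(v, BinaryMask):
        data = v.grid.astype(np.uint8)
    else:
        data = np.asarray(v.grid, dtype=np.float32)
    img = nib.Nifti1Image(data, _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, path)


def window_ct(v: ImageVolume, lo: float = -200.0, hi: float = 200.0) -> ImageVolume:
    """Clip CT intensities to ``[lo, hi]`` HU and rescale linearly to [-1, 1].

    The default window is [-200, 200] HU.  Applying the function to data
    already living in the rescaled [-1, 1] space is a no-op only for the
    default-like symmetric windows wider than the data range; in general the
    function re-interprets its input as raw HU.
    """
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    clipped = np.clip(np.asarray(v.grid, dtype=float), lo, hi)
    scaled = 2.0 * (clipped - lo) / (hi - lo) - 1.0
    return dataclasses.replace(v, grid=scaled)


def znormalize(v: ImageVolume) -> ImageVolume:
    """Z-score normalize intensities to zero mean, unit population SD."""
    grid = np.asarray(v.grid, dtype=float)
    if grid.size < 2:
        raise ConstantGridError("z-normalization needs more than one voxel")
    sd = float(grid.std())  # population convention (ddof=0)
    if sd == 0.0:
        raise ConstantGridError("z-normalization undefined for a constant grid")
    return dataclasses.replace(v, grid=(grid - grid.mean()) / sd)


def resample(
    v: ImageVolume | BinaryMask,
    new_spacing: tuple[float, float, float],
    mode: Literal["linear", "nearest"] = "linear",
):
    """Resample onto an isotropic-or-not grid with the given spacing.

    Voxels are treated as cells: the output covers the same physical extent
    ``shape * spacing`` and output voxel ``i`` samples input coordinate
    ``(i + 0.5) * new / old - 0.5`` per axis.  Masks must use ``nearest``
    and remain strictly binary.
    """
    new_spacing = _check_spacing(new_spacing)
    is_mask = isinstance(v, BinaryMask)
    if is_mask and mode != "nearest":
        raise ValueError("binary masks must be resampled with mode='nearest'")
    old_spacing = v.spacing
    old_shape = v.shape
    new_shape = tuple(
        max(1, int(round(n * so / sn)))
        for n, so, sn in zip(old_shape, old_spacing, new_spacing)
    )
    if new_shape == old_shape and new_spacing == old_spacing:
        return dataclasses.replace(v, grid=v.grid.copy())
    coords = np.meshgrid(
        *[
            (np.arange(ns) + 0.5) * sn / so - 0.5
            for ns, sn, so in zip(new_shape, new_spacing, old_spacing)
        ],
        indexing="ij",
    )
    src = v.grid.astype(float)
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(src, np.stack(coords), order=order, mode="nearest")
    if is_mask:
        return dataclasses.replace(v, grid=out > 0.5, spacing=new_spacing)
    return dataclasses.replace(v, grid=out, spacing=new_spacing)


def crop_centered(
    v: ImageVolume | BinaryMask,
    center: tuple[int, int, int],
    size: int = 144,
    pad_value: float = 0.0,
):
    """Extract a ``size**3`` cube centered on a voxel index.

    The voxel at ``center`` maps to output index ``size // 2`` on every axis
    (floor convention for even sizes).  Out-of-bounds regions are filled
    with ``pad_value`` (0, the post-normalization background, by default).
    """
    if size < 1:
        raise ValueError("crop size must be >= 1")
    is_mask = isinstance(v, BinaryMask)
    half = size // 2
    if is_mask:
        out = np.zeros((size,) * 3, dtype=bool)
    else:
        out = np.full((size,) * 3, pad_value, dtype=float)
    src = v.grid
    starts = [int(c) - half for c in center]
    src_lo = [max(0, s) for s in starts]
    src_hi = [min(n, s + size) for s, n in zip(starts, src.shape)]
    if all(lo < hi for lo, hi in zip(src_lo, src_hi)):
        out_lo = [sl - s for sl, s in zip(src_lo, starts)]
        out_hi = [ol + (hi - lo) for ol, lo, hi in zip(out_lo, src_lo, src_hi)]
        out[tuple(slice(a, b) for a, b in zip(out_lo, out_hi))] = src[
            tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
        ]
    return dataclasses.replace(v, grid=out)


def threshold_mask(p: ImageVolume, t: float = 0.5) -> BinaryMask:
    """Binarize a probability volume: foreground iff ``p >= t``.

    Ties at the threshold are foreground ("0.5 and higher" convention).
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    grid = np.asarray(p.grid, dtype=float)
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValueError("probability volume values must lie in [0, 1]")
    return BinaryMask(grid=grid >= t, spacing=p.spacing, origin=p.origin)
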