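"""Volumetric image containers and NIfTI I/O.

Three grid types carry all image math in this package:

``Volume``
    a 3D scalar image with per-axis physical spacing (mm/voxel),
``Mask``
    a binary segmentation label on the same grid (values exactly 0/1),
``ProbMap``
    a predicted foreground-probability map with values in [0, 1].

Axes follow a fixed (row, column, slice) convention, where the slice axis is
the acquisition (axial) axis.  Coordinates are voxel-indexed and 0-based;
physical coordinates are ``index * spacing``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "Mask",
    "ProbMap",
    "read_volume",
    "read_mask",
    "read_probmap",
    "write_volume",
    "binarize",
    "GridError",
    "GridMismatchError",
    "DimensionalityError",
]


class GridError(ValueError):
    """Invalid grid contents (non-finite data, bad spacing, bad values)."""


class GridMismatchError(GridError):
    """Two grids that must share shape/spacing do not."""


class DimensionalityError(GridError):
    """The data does not have three spatial dimensions."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise GridError(f"spacing must have 3 entries, got {spacing}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise GridError(f"spacings must be positive and finite, got {spacing}")
    return spacing


@dataclass(frozen=True)
class _Grid:
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D array, got shape {data.shape}"
            )
        if any(n < 1 for n in data.shape):
            raise GridError(f"all dimensions must be >= 1, got {data.shape}")
        object.__setattr__(self, "data", self._coerce(data))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    def _coerce(self, data: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, spacing=None):
        return type(self)(data, self.spacing if spacing is None else spacing)


class Volume(_Grid):
    """3D scalar intensity image (arbitrary units)."""

    def _coerce(self, data):
        data = data.astype(np.float32, copy=False)
        if not np.isfinite(data).all():
            raise GridError("volume intensities must be finite (no NaN/Inf)")
        return data


class Mask(_Grid):
    """Binary segmentation mask; values exactly 0 or 1."""

    def _coerce(self, data):
        if data.dtype != np.uint8:
            vals = np.unique(data)
            if not np.isin(vals, (0, 1)).all():
                raise GridError(
                    f"mask values must be exactly 0 or 1, got {vals[:10]}"
                )
            data = data.astype(np.uint8)
        elif data.max(initial=0) > 1:
            raise GridError("mask values must be exactly 0 or 1")
        return data


class ProbMap(_Grid):
    """Predicted foreground probability per voxel, in [0, 1]."""

    def _coerce(self, data):
        data = data.astype(np.float32, copy=False)
        if not np.isfinite(data).all():
            raise GridError("probabilities must be finite")
        if data.min() < 0.0 or data.max() > 1.0:
            raise GridError(
                f"probabilities must lie in [0, 1], got range "
                f"[{data.min()}, {data.max()}]"
            )
        return data


def _load(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = os.fspath(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - report the offending path
        raise IOError(f"could not read NIfTI image {path!r}: {exc}") from exc
    zooms = img.header.get_zooms()
    # squeeze singleton trailing dimensions (e.g. shape (X, Y, Z, 1))
    data = np.squeeze(data)
    if data.ndim < 3:
        raise DimensionalityError(
            f"{path!r} has shape {data.shape}; a 3D image is required"
        )
    if data.ndim > 3:
        raise DimensionalityError(
            f"{path!r} has {data.ndim} non-singleton dimensions"
        )
    return data, _check_spacing(zooms[:3])


def read_volume(path) -> Volume:
    """Read a NIfTI image as a :class:`Volume` (spacing from the header)."""
    data, spacing = _load(path)
    return Volume(data, spacing)


def read_mask(path) -> Mask:
    """Read a NIfTI label image as a :class:`Mask`."""
    data, spacing = _load(path)
    return Mask(data, spacing)


def read_probmap(path) -> ProbMap:
    """Read a NIfTI probability image as a :class:`ProbMap`."""
    data, spacing = _load(path)
    return ProbMap(data, spacing)


def write_volume(v: _Grid, path) -> None:
    """Write any grid type to NIfTI, preserving spacing.

    Masks are stored as unsigned 8-bit integers, volumes and probability
    maps as 32-bit floats, so a write/read round trip preserves mask values
    exactly and float data to storage precision.
    """
    path = os.fspath(path)
    dtype = np.uint8 if isinstance(v, Mask) else np.float32
    affine = np.diag((*v.spacing, 1.0))
    img = nib.Nifti1Image(v.data.astype(dtype, copy=False), affine)
    img.header.set_zooms(v.spacing)
    try:
        nib.save(img, path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not write NIfTI image {path!r}: {exc}") from exc


def binarize(p: ProbMap, threshold: float = 0.5) -> Mask:
    """Threshold a probability map: voxel = 1 iff probability >= threshold.

    ``threshold`` must lie strictly inside (0, 1).  The >= tie rule makes
    ``binarize`` monotone: raising the threshold never adds foreground.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return Mask((p.data >= threshold).astype(np.uint8), p.spacing)
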