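"""Deterministic cropping, interleaved slicing and intensity normalization.

The preprocessing pipeline for a 512x512x248 acquisition removes the first
112 rows and columns (no bone lies there at the scanner's field of view) and
splits the volume into two interleaved half-volumes of every other slice, so
a 3D network can be trained at full in-plane resolution: one 512x512x248
volume becomes two 400x400x124 volumes.

Three intensity-normalization schemes are provided:

``train3d``
    divide by one value drawn uniformly from [max-1000, max+1000];
``train2d``
    as above with a +-500 half-width (more stable for per-slice models);
``validation``
    divide by the maximum, then divide by the 85th percentile of the
    already-divided values (robust to outlier intensities).

The random divisor doubles as intensity augmentation and makes the model
robust to multiplicative coil-gain artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import GridMismatchError, Volume, _Grid

__all__ = [
    "CropSpec",
    "NormalizationSpec",
    "crop_volume",
    "interleave_split",
    "interleave_merge",
    "normalize",
]

_MODE_JITTER = {"train3d": 1000.0, "train2d": 500.0, "validation": 0.0}


@dataclass(frozen=True)
class CropSpec:
    """Number of leading rows/columns removed from the in-plane axes."""

    n_rows: int = 112
    n_cols: int = 112

    def __post_init__(self):
        if self.n_rows < 0 or self.n_cols < 0:
            raise ValueError("crop counts must be non-negative")


@dataclass(frozen=True)
class NormalizationSpec:
    """Which intensity-normalization scheme to apply.

    ``jitter`` is the half-width (in intensity units) of the uniform range
    around the volume maximum from which the divisor is drawn; it defaults to
    1000 for ``train3d``, 500 for ``train2d`` and 0 for ``validation``.
    ``percentile_divide`` (validation only) enables the second division by
    the 85th percentile.
    """

    mode: str = "validation"
    jitter: float | None = None
    percentile_divide: bool | None = None
    percentile: float = 85.0
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self):
        if self.mode not in _MODE_JITTER:
            raise ValueError(
                f"mode must be one of {sorted(_MODE_JITTER)}, got {self.mode!r}"
            )
        if self.jitter is None:
            object.__setattr__(self, "jitter", _MODE_JITTER[self.mode])
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.percentile_divide is None:
            object.__setattr__(
                self, "percentile_divide", self.mode == "validation"
            )
        if self.percentile_divide and self.mode != "validation":
            raise ValueError("percentile_divide is valid only for validation")


def crop_volume(v: _Grid, spec: CropSpec):
    """Remove the first ``n_rows`` rows and ``n_cols`` columns.

    Works on any grid type (masks pass through untouched apart from the
    crop); spacing is unchanged.
    """
    rows, cols, _ = v.shape
    if spec.n_rows >= rows or spec.n_cols >= cols:
        raise ValueError(
            f"crop ({spec.n_rows}, {spec.n_cols}) >= in-plane shape "
            f"({rows}, {cols})"
        )
    return v.with_data(v.data[spec.n_rows:, spec.n_cols:, :])


def interleave_split(v: _Grid):
    """Split into (even slices, odd slices); slice spacing doubles.

    For an odd slice count the first half holds one more slice than the
    second (floor/ceil split).
    """
    if v.shape[2] < 2:
        raise ValueError("interleave_split requires at least 2 slices")
    spacing = (v.spacing[0], v.spacing[1], 2.0 * v.spacing[2])
    return (
        v.with_data(v.data[:, :, 0::2], spacing),
        v.with_data(v.data[:, :, 1::2], spacing),
    )


def interleave_merge(a: _Grid, b: _Grid):
    """Inverse of :func:`interleave_split`: re-interleave two half-volumes.

    ``a`` supplies even output slices and ``b`` odd ones; ``a`` may hold one
    extra slice (odd total).  Slice spacing is halved.
    """
    if type(a) is not type(b):
        raise GridMismatchError("both halves must have the same grid type")
    if a.shape[:2] != b.shape[:2] or a.spacing != b.spacing:
        raise GridMismatchError(
            f"in-plane shapes/spacings differ: {a.shape}/{a.spacing} vs "
            f"{b.shape}/{b.spacing}"
        )
    na, nb = a.shape[2], b.shape[2]
    if na not in (nb, nb + 1):
        raise GridMismatchError(
            f"slice counts {na} and {nb} cannot be interleaved"
        )
    out = np.empty((*a.shape[:2], na + nb), dtype=a.data.dtype)
    out[:, :, 0::2] = a.data
    out[:, :, 1::2] = b.data
    spacing = (a.spacing[0], a.spacing[1], a.spacing[2] / 2.0)
    return a.with_data(out, spacing)


def normalize(
    v: Volume, spec: NormalizationSpec, rng: np.random.Generator | None = None
) -> Volume:
    """Apply one of the three intensity-normalization schemes.

    In the training modes a single divisor is drawn uniformly from
    [max-jitter, max+jitter]; the draw consumes exactly one value from the
    stream.  A non-positive draw is redrawn up to ``spec.max_retries`` times
    (the divisor must be strictly positive).  Validation mode is
    deterministic and scale-invariant.
    """
    vmax = float(v.data.max())
    if vmax <= 0:
        raise ValueError("normalize requires at least one positive intensity")
    if spec.mode == "validation":
        out = v.data / vmax
        if spec.percentile_divide:
            p = float(np.percentile(out, spec.percentile))
            if p <= 0:
                raise ValueError(
                    f"{spec.percentile}th percentile is non-positive"
                )
            out = out / p
        return Volume(out, v.spacing)

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    divisor = -1.0
    for _ in range(spec.max_retries):
        divisor = vmax + spec.jitter * rng.uniform(-1.0, 1.0)
        if divisor > 0:
            break
    if divisor <= 0:
        raise ValueError(
            f"could not draw a positive divisor from "
            f"[{vmax - spec.jitter}, {vmax + spec.jitter}] "
            f"after {spec.max_retries} tries"
        )
    return Volume(v.data / divisor, v.spacing)
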