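"""Stochastic dataset expansion for image/mask pairs.

Four transform families are supported, each applied independently with a
configurable probability (default 30%): random affine (rotation, isotropic
scale, translation), elastic deformation, Gaussian blur and additive
Gaussian noise.  Spatial transforms use identical parameters for image and
mask; the mask is resampled nearest-neighbour so it stays strictly binary;
intensity transforms touch the image only.  A dataset is expanded by
retaining the originals and appending ``copies_per_original`` augmented
copies of each (default 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import GridMismatchError, Mask, Volume

__all__ = ["AugmentSpec", "affine_pair", "elastic_pair", "augment_pair",
           "augment_dataset"]


@dataclass(frozen=True)
class AugmentSpec:
    """Parameter ranges for the four transform families.

    Defaults are deliberately gentle so the thin scapular blade survives:
    rotations up to +-15 degrees, scale 0.9-1.1, translations up to
    +-10 voxels, elastic displacement up to 4 voxels smoothed over 8 voxels,
    blur sigma 0.5-1.5 voxels and noise s.d. 1-5% of the image maximum.
    """

    per_transform_prob: float = 0.30
    copies_per_original: int = 8
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_vox: float = 10.0
    elastic_amplitude_vox: float = 4.0
    elastic_smoothness_vox: float = 8.0
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    noise_sd_range: tuple[float, float] = (0.01, 0.05)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.per_transform_prob <= 1.0:
            raise ValueError("per_transform_prob must lie in [0, 1]")
        if self.copies_per_original < 0:
            raise ValueError("copies_per_original must be >= 0")
        for name in ("rotation_deg", "translation_vox",
                     "elastic_amplitude_vox", "elastic_smoothness_vox"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _rotation_matrix(angles_deg) -> np.ndarray:
    a, b, c = np.deg2rad(angles_deg)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _apply_affine(data, angles_deg, scale, translation_vox, order):
    rot = _rotation_matrix(angles_deg) * scale
    inv = np.linalg.inv(rot)
    center = (np.asarray(data.shape) - 1) / 2.0
    offset = center - inv @ (center + np.asarray(translation_vox, float))
    return ndimage.affine_transform(
        data, inv, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=order > 1,
    )


def affine_pair(
    v: Volume,
    m: Mask,
    angles_deg=(0.0, 0.0, 0.0),
    scale: float = 1.0,
    translation_vox=(0.0, 0.0, 0.0),
) -> tuple[Volume, Mask]:
    """Apply one affine transform (about the grid centre) to both grids.

    The image is resampled with trilinear interpolation, the mask with
    nearest neighbour.  Right-angle rotations of an even-sized grid permute
    the voxel lattice exactly, so they conserve foreground volume exactly.
    """
    _check_pair(v, m)
    vd = _apply_affine(v.data, angles_deg, scale, translation_vox, order=1)
    md = _apply_affine(m.data, angles_deg, scale, translation_vox, order=0)
    return Volume(vd, v.spacing), Mask(md, m.spacing)


def elastic_pair(
    v: Volume,
    m: Mask,
    amplitude_vox: float,
    smoothness_vox: float,
    rng: np.random.Generator,
) -> tuple[Volume, Mask]:
    """Apply one random smooth elastic deformation to both grids."""
    _check_pair(v, m)
    if amplitude_vox == 0:
        return v, m
    coords = np.indices(v.shape, dtype=np.float32)
    for axis in range(3):
        disp = ndimage.gaussian_filter(
            rng.standard_normal(v.shape).astype(np.float32),
            sigma=max(smoothness_vox, 1e-6),
        )
        peak = float(np.abs(disp).max())
        if peak > 0:
            disp *= amplitude_vox / peak
        coords[axis] += disp
    vd = ndimage.map_coordinates(v.data, coords, order=1, mode="nearest")
    md = ndimage.map_coordinates(m.data, coords, order=0, mode="nearest")
    return Volume(vd, v.spacing), Mask(md, m.spacing)


def _check_pair(v: Volume, m: Mask) -> None:
    if v.shape != m.shape or v.spacing != m.spacing:
        raise GridMismatchError(
            f"image and mask must share shape and spacing, got "
            f"{v.shape}/{v.spacing} vs {m.shape}/{m.spacing}"
        )


def augment_pair(
    v: Volume, m: Mask, spec: AugmentSpec, rng: np.random.Generator
) -> tuple[Volume, Mask]:
    """Produce one augmented copy of an image/mask pair.

    Each of the four transform families is applied independently with
    probability ``spec.per_transform_prob`` (the gate draws always consume
    four values from the stream, so seeded runs are reproducible).  Output
    shape equals input shape.
    """
    _check_pair(v, m)
    apply_affine, apply_elastic, apply_blur, apply_noise = (
        rng.uniform(size=4) < spec.per_transform_prob
    )
    if apply_affine:
        angles = rng.uniform(-spec.rotation_deg, spec.rotation_deg, size=3)
        scale = rng.uniform(*spec.scale_range)
        trans = rng.uniform(-spec.translation_vox, spec.translation_vox, 3)
        v, m = affine_pair(v, m, angles, scale, trans)
    if apply_elastic:
        amp = rng.uniform(0.0, spec.elastic_amplitude_vox)
        v, m = elastic_pair(v, m, amp, spec.elastic_smoothness_vox, rng)
    if apply_blur:
        sigma = rng.uniform(*spec.blur_sigma_range)
        v = Volume(ndimage.gaussian_filter(v.data, sigma), v.spacing)
    if apply_noise:
        sd = rng.uniform(*spec.noise_sd_range) * float(v.data.max())
        noisy = v.data + sd * rng.standard_normal(v.shape).astype(np.float32)
        v = Volume(noisy, v.spacing)
    return v, m


def augment_dataset(
    pairs: list[tuple[Volume, Mask]], spec: AugmentSpec
) -> list[tuple[Volume, Mask]]:
    """Expand a dataset: originals plus ``copies_per_original`` copies each.

    Output order is deterministic (all originals first, then copies grouped
    by original); length is ``n * (1 + copies_per_original)``.
    """
    if not pairs:
        raise ValueError("augment_dataset requires a non-empty dataset")
    rng = np.random.default_rng(spec.seed)
    out = list(pairs)
    for v, m in pairs:
        for _ in range(spec.copies_per_original):
            out.append(augment_pair(v, m, spec, rng))
    return out
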