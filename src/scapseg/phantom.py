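"""Synthetic scapula phantoms with analytically known morphometry.

No segmentation data are deposited with this package, so every downstream
component (preprocessing, training, morphometry, statistics) is exercised
on parametric phantoms: a voxelized union of primitives that reproduces the
anatomical features the landmark detector relies on --

- an elliptical glenoid disc (semi-axes height/2 and width/2) whose face is
  rotated by a version angle about the superior axis and an inclination
  angle about the anterior-posterior axis;
- a thin triangular blade extending medially, with a uniquely defined most
  medial border point;
- a spine ridge with a sharp crest running along the supraspinatus fossa
  floor line, terminating laterally at the fossa point that realizes a
  requested RSA angle (closed form);
- an acromion sphere placed in closed form so the most lateral acromion
  point realizes a requested critical shoulder angle, offset posteriorly
  (the posterior offset lets the measurement code orient the
  anterior-posterior axis on either side);
- a connecting rod from ridge to acromion, routed a few millimetres below
  the ridge crest so it cannot masquerade as the fossa floor.

The phantom is geometric, not statistically learned: it validates landmark
and measurement recovery and pipeline mechanics, not anatomical realism.
Ground-truth landmarks are computed in continuous coordinates before
voxelization and the ground-truth measurements are derived from those
landmarks with the same formulas the morphometry module applies, so truth
is self-consistent to machine precision.

:func:`render_intensity` wraps a mask into an MRI-like volume at scanner
intensity scale (arbitrary units in the thousands): dark cortical bone
inside a bright soft-tissue shell over a near-zero background, with a
smooth multiplicative coil-gain bias field and additive Gaussian noise.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .imaging import Mask, Volume, write_volume
from .morphometry import LandmarkSet, measure_landmarks

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomGenerationError",
    "CohortRanges",
    "generate_phantom",
    "render_intensity",
    "threshold_bone",
    "generate_cohort",
    "save_cohort",
]

_X = np.array([1.0, 0.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


class PhantomGenerationError(RuntimeError):
    """The requested phantom could not be generated (e.g. disconnected)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric ground-truth geometry for one synthetic scapula.

    All lengths in mm, angles in degrees.  ``version`` follows the
    anatomical sign convention (negative = retroverted); ``inclination``
    positive tilts the glenoid face superiorly.  ``csa_target`` and
    ``rsa_target`` place the acromion and the lateral fossa point in closed
    form so those angles are exact by construction.
    """

    shape: tuple[int, int, int] = (200, 96, 176)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    glenoid_height: float = 38.0
    glenoid_width: float = 28.0
    version: float = -2.0
    inclination: float = 5.0
    glenoid_thickness: float = 5.0
    blade_length: float = 58.0
    blade_thickness: float = 3.0
    blade_inferior_drop: float = 38.0
    csa_target: float = 33.0
    rsa_target: float = 25.0
    fossa_distance: float = 50.0
    acromion_distance: float = 42.0
    acromion_radius: float = 6.0
    acromion_posterior_deg: float = 12.0
    side: str = "right"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(
            self, "spacing", tuple(float(s) for s in self.spacing)
        )
        if self.side not in ("right", "left"):
            raise ValueError("side must be 'right' or 'left'")
        sizes = (self.glenoid_height, self.glenoid_width,
                 self.glenoid_thickness, self.blade_length,
                 self.blade_thickness, self.blade_inferior_drop,
                 self.fossa_distance, self.acromion_distance,
                 self.acromion_radius)
        if min(sizes) <= 0:
            raise ValueError("all physical sizes must be positive")
        for name in ("version", "inclination", "csa_target", "rsa_target"):
            if not -45.0 < float(getattr(self, name)) < 45.0:
                raise ValueError(f"{name} must lie in (-45, 45) degrees")
        geo = _canonical_geometry(self)
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        margin = np.asarray(self.spacing)
        lo = geo["bound_lo"] + geo["origin"]
        hi = geo["bound_hi"] + geo["origin"]
        if (lo < margin).any() or (hi > extent - 2 * margin).any():
            raise ValueError(
                f"phantom geometry exceeds the grid: bounds {lo}..{hi} mm "
                f"inside extent {extent} mm"
            )
        if geo["A_lm"][0] < geo["disc_max_x"] + 3.0:
            raise ValueError(
                "acromion would not be the most lateral structure; "
                "increase csa_target or acromion_distance"
            )
        if geo["F"][0] > -11.0:
            raise ValueError(
                "lateral fossa point too close to the glenoid; increase "
                "rsa_target or fossa_distance"
            )


@dataclass(frozen=True)
class PhantomTruth:
    """Exact continuous landmarks and the implied measurements."""

    spec: PhantomSpec
    landmarks: LandmarkSet
    measurements: MeasurementSet


def _canonical_geometry(spec: PhantomSpec) -> dict:
    """All construction points in the canonical right-side frame
    (origin at the glenoid disc centre; x lateral, y anterior, z superior)."""
    a = spec.glenoid_height / 2.0
    b = spec.glenoid_width / 2.0
    t = spec.glenoid_thickness
    nu = math.radians(spec.version)
    io = math.radians(spec.inclination)
    n0 = np.array([math.cos(nu), math.sin(nu), 0.0])
    e2 = np.array([-math.sin(nu), math.cos(nu), 0.0])  # anterior-oriented
    e1 = math.cos(io) * _Z - math.sin(io) * n0  # superior-oriented
    n = math.cos(io) * n0 + math.sin(io) * _Z  # lateral face normal

    center = (t / 2.0) * n  # articular face centre
    sup = center + a * e1
    inf = center - a * e1
    ant = center + b * e2
    post = center - b * e2

    rho = math.radians(spec.rsa_target)
    S = spec.fossa_distance
    F = inf + S * math.cos(rho) * _Z - S * math.sin(rho) * _X
    f_dir = -_X  # fossa floor tangent, oriented medially

    beta = math.radians(spec.csa_target)
    phi = math.radians(spec.acromion_posterior_deg)
    lat = _X - (_X @ e1) * e1
    lat = lat / np.linalg.norm(lat)
    post_dir = np.cross(e1, lat)
    post_dir = post_dir / np.linalg.norm(post_dir)
    if post_dir[1] > 0:
        post_dir = -post_dir
    m_hat = math.cos(phi) * lat + math.sin(phi) * post_dir
    R = spec.acromion_distance
    A_lm = inf + R * (math.cos(beta) * e1 + math.sin(beta) * m_hat)
    A_c = A_lm - spec.acromion_radius * _X

    M = np.array([-spec.blade_length, 0.0, F[2] - 10.0])

    disc_max_x = math.sqrt((a * e1[0]) ** 2 + (b * e2[0]) ** 2) + (
        t / 2.0
    ) * abs(n[0])

    # the glenoid centre sits blade_length + 4 mm from the medial grid edge
    origin = np.array([
        spec.blade_length + 4.0,
        spec.shape[1] * spec.spacing[1] / 2.0,
        spec.blade_inferior_drop + 4.0,
    ])

    pts = np.stack([sup, inf, ant, post, center, M, F, A_lm, A_c])
    r_a = spec.acromion_radius
    bound_lo = pts.min(axis=0) - np.array([2.0, 6.0, r_a + 2.0])
    bound_lo[2] = min(bound_lo[2], -spec.blade_inferior_drop - 1.0)
    bound_hi = pts.max(axis=0) + np.array([r_a, 6.0, r_a + 2.0])

    return dict(
        e1=e1, e2=e2, n=n, center=center, sup=sup, inf=inf, ant=ant,
        post=post, F=F, f_dir=f_dir, A_lm=A_lm, A_c=A_c, M=M,
        disc_max_x=disc_max_x, origin=origin,
        bound_lo=bound_lo, bound_hi=bound_hi,
        a=a, b=b, t=t,
    )


def _segment_capsule(X, Y, Z, p0, p1, radius):
    """Boolean field: within ``radius`` of the segment p0-p1."""
    seg = p1 - p0
    L2 = float(seg @ seg)
    dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
    if L2 < 1e-12:
        d2 = dx * dx + dy * dy + dz * dz
    else:
        tt = np.clip((dx * seg[0] + dy * seg[1] + dz * seg[2]) / L2, 0.0, 1.0)
        d2 = ((dx - tt * seg[0]) ** 2 + (dy - tt * seg[1]) ** 2
              + (dz - tt * seg[2]) ** 2)
    return d2 <= radius * radius


def generate_phantom(spec: PhantomSpec) -> tuple[Mask, PhantomTruth]:
    """Voxelize one phantom and return it with its analytic truth.

    Raises :class:`PhantomGenerationError` if the voxelized result is not a
    single connected component (the spec is then rejected).
    """
    geo = _canonical_geometry(spec)
    s = np.asarray(spec.spacing)
    origin = geo["origin"]
    # canonical coordinates of every voxel centre (relative to disc centre)
    X = (np.arange(spec.shape[0]) * s[0] - origin[0])[:, None, None]
    Y = (np.arange(spec.shape[1]) * s[1] - origin[1])[None, :, None]
    Z = (np.arange(spec.shape[2]) * s[2] - origin[2])[None, None, :]

    e1, e2, n = geo["e1"], geo["e2"], geo["n"]
    a, b, t = geo["a"], geo["b"], geo["t"]
    d_n = X * n[0] + Y * n[1] + Z * n[2]
    d_1 = X * e1[0] + Y * e1[1] + Z * e1[2]
    d_2 = X * e2[0] + Y * e2[1] + Z * e2[2]
    disc = (np.abs(d_n) <= t / 2.0) & ((d_1 / a) ** 2 + (d_2 / b) ** 2 <= 1.0)

    neck = ((X >= -14.0) & (X <= 0.0) & (np.abs(Y) <= 4.0)
            & (np.abs(Z) <= 9.0))

    F, M = geo["F"], geo["M"]
    L = spec.blade_length
    drop = spec.blade_inferior_drop
    z_top = F[2] - 6.0
    frac = np.clip((-X - 10.0) / (L - 10.0), 0.0, 1.0)
    z_bot = -drop + (drop - 12.0) * frac
    x_med_cut = -L + 0.35 * np.abs(Z - M[2]) + 0.5 * np.abs(Y)
    blade = ((X <= -10.0) & (X >= x_med_cut)
             & (np.abs(Y) <= spec.blade_thickness / 2.0)
             & (Z >= z_bot) & (Z <= z_top))

    # spine ridge: rectangular base with a triangular roof whose sharp
    # crest is the fossa floor line (through F, horizontal, medial-lateral)
    dzc = Z - F[2]
    dyc = np.abs(Y - F[1])
    ridge_x = (X >= -L + 6.0) & (X <= F[0])
    ridge = ridge_x & (
        ((dzc >= -8.0) & (dzc <= -2.0) & (dyc <= 3.0))
        | ((dzc > -2.0) & (dzc <= 0.0) & (dyc <= 1.5 * (-dzc)))
    )

    A_c = geo["A_c"]
    sphere = ((X - A_c[0]) ** 2 + (Y - A_c[1]) ** 2
              + (Z - A_c[2]) ** 2) <= spec.acromion_radius ** 2

    # connector, routed 7 mm below the crest so it cannot be mistaken for
    # the fossa floor, then rising to the acromion outside the fossa window
    q0 = np.array([F[0], F[1], F[2] - 7.0])
    q1 = np.array([A_c[0], A_c[1], F[2] - 7.0])
    rod = (_segment_capsule(X, Y, Z, q0, q1, 3.0)
           | _segment_capsule(X, Y, Z, q1, A_c, 3.0))

    vox = disc | neck | blade | ridge | sphere | rod

    lab, ncomp = ndimage.label(vox, structure=np.ones((3, 3, 3), bool))
    if ncomp != 1:
        raise PhantomGenerationError(
            f"phantom voxelization produced {ncomp} components"
        )

    points = {
        "glenoid_superior": geo["sup"],
        "glenoid_inferior": geo["inf"],
        "glenoid_anterior": geo["ant"],
        "glenoid_posterior": geo["post"],
        "glenoid_center": geo["center"],
        "medial_scapula_edge": M,
        "lateral_supraspinatus_fossa": F,
        "fossa_floor_point": F.copy(),
        "lateral_acromion": geo["A_lm"],
    }
    f_dir = geo["f_dir"].copy()
    grid_points = {k: v + origin for k, v in points.items()}

    data = vox.astype(np.uint8)
    if spec.side == "left":
        data = data[:, ::-1, :].copy()
        y_max = (spec.shape[1] - 1) * s[1]
        for k, v in grid_points.items():
            grid_points[k] = np.array([v[0], y_max - v[1], v[2]])
        f_dir = np.array([f_dir[0], -f_dir[1], f_dir[2]])

    landmarks = LandmarkSet(fossa_floor_direction=f_dir, **grid_points)
    truth = PhantomTruth(
        spec=spec,
        landmarks=landmarks,
        measurements=measure_landmarks(landmarks),
    )
    return Mask(data, spec.spacing), truth


# ---------------------------------------------------------------------------
# intensity rendering


def render_intensity(
    m: Mask,
    noise_sd: float = 0.02,
    bias_amplitude: float = 0.10,
    seed: int = 0,
    shell_mm: float = 25.0,
    intensity_scale: float = 2000.0,
    bone_level: float = 0.30,
    shell_level: float = 1.00,
    background_level: float = 0.05,
) -> Volume:
    """Render a mask as an MRI-like volume (fat-saturated T2 contrast).

    Cortical bone is dark (``bone_level``) inside a bright soft-tissue
    region (``shell_level``, everything within ``shell_mm`` of bone) over a
    near-zero background, all scaled by ``intensity_scale`` to scanner-like
    arbitrary units.  The default tissue region is thick so that, as in a
    real shoulder scan, most of the field of view is tissue and
    percentile-based normalization lands in the tissue band.  ``noise_sd``
    and ``bias_amplitude`` are fractions of the scale: additive Gaussian
    noise and a smooth multiplicative coil-gain field.  Outputs are >= 0.
    """
    rng = np.random.default_rng(seed)
    bone = m.data.astype(bool)
    dist = ndimage.distance_transform_edt(~bone, sampling=m.spacing)
    shell = (dist > 0) & (dist <= shell_mm)
    out = np.full(m.shape, background_level, dtype=np.float32)
    out[shell] = shell_level
    out[bone] = bone_level
    out *= intensity_scale
    if bias_amplitude > 0:
        fieldv = ndimage.gaussian_filter(
            rng.standard_normal(m.shape).astype(np.float32), sigma=16.0
        )
        peak = float(np.abs(fieldv).max())
        if peak > 0:
            fieldv /= peak
        out *= 1.0 + bias_amplitude * fieldv
    if noise_sd > 0:
        out += (noise_sd * intensity_scale
                * rng.standard_normal(m.shape).astype(np.float32))
    return Volume(np.clip(out, 0.0, None), m.spacing)


def threshold_bone(
    v: Volume, lo_frac: float = 0.15, hi_frac: float = 0.60
) -> Mask:
    """Recover the bone band from a rendered volume.

    Bone occupies an intermediate intensity band between the near-zero
    background and the bright soft-tissue shell, so recovery selects voxels
    within ``[lo_frac, hi_frac]`` of a robust maximum (99.5th percentile).
    The rule is scale-invariant, so it works before or after any
    normalization.
    """
    ref = float(np.percentile(v.data, 99.5))
    if ref <= 0:
        raise ValueError("volume has no positive intensities")
    band = (v.data >= lo_frac * ref) & (v.data <= hi_frac * ref)
    return Mask(band.astype(np.uint8), v.spacing)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for cohort phantom specs (mm / degrees)."""

    glenoid_height: tuple[float, float] = (30.0, 50.0)
    glenoid_width: tuple[float, float] = (22.0, 34.0)
    version: tuple[float, float] = (-15.0, 5.0)
    inclination: tuple[float, float] = (-15.0, 15.0)
    csa_target: tuple[float, float] = (28.0, 36.0)
    rsa_target: tuple[float, float] = (22.0, 32.0)
    sides: tuple[str, ...] = ("right", "left")

    def draw(self, rng: np.random.Generator, **fixed) -> dict:
        out = {}
        for name in ("glenoid_height", "glenoid_width", "version",
                     "inclination", "csa_target", "rsa_target"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
            out[name] = float(rng.uniform(lo, hi))
        out["side"] = str(rng.choice(self.sides))
        out.update(fixed)
        return out


def generate_cohort(
    n: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (200, 96, 176),
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    noise_sd: float = 0.02,
    bias_amplitude: float = 0.10,
) -> list[tuple[Volume, Mask, PhantomTruth]]:
    """Generate ``n`` phantoms with specs drawn uniformly from ``ranges``.

    Reproducible under ``seed``; each item is (rendered intensity volume,
    ground-truth mask, analytic truth).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        params = ranges.draw(rng, shape=shape, spacing=spacing,
                             seed=seed + i)
        spec = PhantomSpec(**params)
        mask, truth = generate_phantom(spec)
        vol = render_intensity(mask, noise_sd=noise_sd,
                               bias_amplitude=bias_amplitude,
                               seed=int(rng.integers(2 ** 31)))
        out.append((vol, mask, truth))
    return out


def save_cohort(items, out_dir) -> None:
    """Write a cohort as NIfTI pairs plus a truth.json per phantom."""
    os.makedirs(out_dir, exist_ok=True)
    for i, (vol, mask, truth) in enumerate(items):
        stem = os.path.join(out_dir, f"phantom{i:03d}")
        write_volume(vol, stem + "_image.nii.gz")
        write_volume(mask, stem + "_mask.nii.gz")
        payload = {
            "spec": asdict(truth.spec),
            "landmarks": {
                k: list(map(float, getattr(truth.landmarks, k)))
                for k in (
                    "glenoid_superior", "glenoid_inferior",
                    "glenoid_anterior", "glenoid_posterior",
                    "glenoid_center", "medial_scapula_edge",
                    "lateral_supraspinatus_fossa", "fossa_floor_point",
                    "fossa_floor_direction", "lateral_acromion",
                )
            },
            "measurements": truth.measurements.as_dict(),
        }
        with open(stem + "_truth.json", "w") as fh:
            json.dump(payload, fh, indent=1)
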