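import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from scapseg.imaging import Mask
from scapseg.morphometry import (DegenerateGeometryError, LandmarkSet,
                                 LandmarkExtractionError, compare_measurements,
                                 critical_shoulder_angle, extract_landmarks,
                                 glenoid_height, glenoid_width,
                                 inclination_angle, measure_landmarks,
                                 measure_mask, retroversion,
                                 round_half_away, rsa_angle,
                                 surface_distance_map, export_surface_mesh)

# printed trial values for the two in-distribution subjects: MRI-derived
# model measurements vs CT, two observer trials each
MRI_056 = {
    "width": [27.52, 26.88], "height": [43.05, 40.94],
    "inclination": [97.48, 99.32], "retroversion": [0.74, -0.50],
    "csa": [30.45, 31.63], "rsa": [7.87, 11.30],
}
CT_056 = {
    "width": [28.37, 28.60], "height": [39.12, 37.96],
    "inclination": [95.73, 97.53], "retroversion": [4.69, 2.08],
    "csa": [27.43, 29.21], "rsa": [10.74, 12.93],
}
MRI_057 = {
    "width": [31.15, 31.23], "height": [48.89, 46.47],
    "inclination": [69.89, 69.25], "retroversion": [32.10, 35.50],
    "csa": [27.11, 26.65], "rsa": [14.18, 15.65],
}
CT_057 = {
    "width": [33.06, 32.97], "height": [46.70, 45.78],
    "inclination": [66.03, 66.49], "retroversion": [29.39, 31.45],
    "csa": [27.20, 26.66], "rsa": [16.33, 17.30],
}


class TestCompareMeasurements:
    def test_published_mean_differences_subject_056(self):
        out = compare_measurements(MRI_056, CT_056).rounded()
        assert out["width"] == 1.29
        assert out["height"] == 3.46
        assert out["inclination"] == 1.77
        assert out["retroversion"] == 3.27
        assert out["csa"] == 2.72

    def test_published_mean_differences_subject_057(self):
        out = compare_measurements(MRI_057, CT_057).rounded()
        assert out["width"] == 1.83
        assert out["height"] == 1.44
        assert out["inclination"] == 3.31
        assert out["retroversion"] == 3.38
        assert out["csa"] == 0.05
        assert out["rsa"] == 1.90

    def test_identical_trials_zero(self):
        out = compare_measurements(MRI_056, MRI_056)
        assert all(v == 0.0 for v in out.mean_difference.values())

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            compare_measurements({"w": []}, {"w": [1.0]})

    def test_mismatched_measurements_rejected(self):
        with pytest.raises(ValueError):
            compare_measurements({"w": [1.0]}, {"h": [1.0]})

    @pytest.mark.parametrize("x,expected", [
        (1.285, 1.29), (0.045, 0.05), (-1.285, -1.29), (2.0, 2.0),
    ])
    def test_round_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


def _sphere(center, r, shape=(24, 24, 24)):
    ii = np.indices(shape)
    d2 = sum((ii[k] - center[k]) ** 2 for k in range(3))
    return Mask((d2 <= r * r).astype(np.uint8), (1.0, 1.0, 1.0))


class TestSurfaceDistance:
    def test_identical_masks_zero(self):
        m = _sphere((12, 12, 12), 6)
        res = surface_distance_map(m, m)
        assert res.mean == 0.0 and res.max == 0.0

    def test_offset_spheres_match_bruteforce(self):
        a = _sphere((10, 12, 12), 5)
        b = _sphere((13, 12, 12), 5)
        res = surface_distance_map(a, b)

        def surf(m):
            fg = m.data.astype(bool)
            return np.argwhere(fg & ~ndimage.binary_erosion(fg))

        pa, pb = surf(a), surf(b)
        brute = cdist(pa, pb).min(axis=1)
        assert res.mean == pytest.approx(brute.mean(), abs=1e-9)
        assert res.max == pytest.approx(brute.max(), abs=1e-9)
        assert 0.0 <= res.mean <= 3.0
        assert res.max == pytest.approx(3.0, abs=1.0)

    def test_directed_distances_are_asymmetric(self):
        a = _sphere((12, 12, 12), 4)
        b = _sphere((12, 12, 12), 8)
        ab = surface_distance_map(a, b)
        ba = surface_distance_map(b, a)
        assert ab.mean != ba.mean

    def test_empty_mask_rejected(self):
        empty = Mask(np.zeros((8, 8, 8), np.uint8))
        with pytest.raises(ValueError):
            surface_distance_map(empty, _sphere((4, 4, 4), 2, (8, 8, 8)))


class TestLandmarkExtraction:
    def test_landmarks_close_to_analytic_truth(self, default_phantom):
        mask, truth = default_phantom
        lm = extract_landmarks(mask)
        for name in ("glenoid_superior", "glenoid_inferior",
                     "glenoid_anterior", "glenoid_posterior",
                     "glenoid_center", "lateral_acromion"):
            err = np.linalg.norm(getattr(lm, name)
                                 - getattr(truth.landmarks, name))
            assert err <= 2.0 * max(mask.spacing), name

    def test_solid_sphere_has_no_glenoid(self):
        with pytest.raises(LandmarkExtractionError):
            extract_landmarks(_sphere((32, 32, 32), 24, (64, 64, 64)))

    def test_empty_mask_rejected(self):
        with pytest.raises(LandmarkExtractionError, match="empty"):
            extract_landmarks(Mask(np.zeros((8, 8, 8), np.uint8)))

    def test_right_angle_rotation_equivariance(self, default_phantom):
        mask, _ = default_phantom
        base = measure_mask(mask)[1].as_dict()
        rot = Mask(np.rot90(mask.data, k=1, axes=(0, 2)).copy(),
                   mask.spacing)
        rotated = measure_mask(rot)[1].as_dict()
        for key, val in base.items():
            assert rotated[key] == pytest.approx(val, abs=1e-6), key


class TestMeasurements:
    def test_recovery_within_tolerance(self, default_phantom):
        mask, truth = default_phantom
        _, ms = measure_mask(mask)
        t = truth.measurements
        assert abs(ms.glenoid_height - t.glenoid_height) <= 2.0
        assert abs(ms.glenoid_width - t.glenoid_width) <= 2.0
        for key in ("retroversion", "inclination_angle",
                    "critical_shoulder_angle", "rsa_angle"):
            assert abs(getattr(ms, key) - getattr(t, key)) <= 2.0, key

    def test_distances_scale_with_spacing(self, default_phantom):
        mask, _ = default_phantom
        _, ms1 = measure_mask(mask)
        doubled = Mask(mask.data, tuple(2 * s for s in mask.spacing))
        _, ms2 = measure_mask(doubled)
        # the detection windows are anatomical (mm) constants, so scaling
        # is linear only up to the discretization of the procedure
        assert ms2.glenoid_height == pytest.approx(2 * ms1.glenoid_height,
                                                   rel=0.02)
        assert ms2.glenoid_width == pytest.approx(2 * ms1.glenoid_width,
                                                  rel=0.02)
        for key in ("retroversion", "inclination_angle",
                    "critical_shoulder_angle", "rsa_angle"):
            assert getattr(ms2, key) == pytest.approx(getattr(ms1, key),
                                                      abs=1.0)

    def test_degenerate_rim_rejected(self, default_phantom):
        _, truth = default_phantom
        lm = truth.landmarks
        bad = LandmarkSet(
            glenoid_superior=lm.glenoid_inferior,  # coincident rim
            glenoid_inferior=lm.glenoid_inferior,
            glenoid_anterior=lm.glenoid_anterior,
            glenoid_posterior=lm.glenoid_posterior,
            glenoid_center=lm.glenoid_center,
            medial_scapula_edge=lm.medial_scapula_edge,
            lateral_supraspinatus_fossa=lm.lateral_supraspinatus_fossa,
            fossa_floor_point=lm.fossa_floor_point,
            fossa_floor_direction=lm.fossa_floor_direction,
            lateral_acromion=lm.lateral_acromion,
        )
        with pytest.raises(DegenerateGeometryError):
            glenoid_height(bad)

    def test_acromion_on_glenoid_line_gives_zero_csa(self, default_phantom):
        _, truth = default_phantom
        lm = truth.landmarks
        on_line = LandmarkSet(
            **{f: getattr(lm, f) for f in (
                "glenoid_superior", "glenoid_inferior", "glenoid_anterior",
                "glenoid_posterior", "glenoid_center", "medial_scapula_edge",
                "lateral_supraspinatus_fossa", "fossa_floor_point",
                "fossa_floor_direction")},
            lateral_acromion=lm.glenoid_superior,
        )
        assert critical_shoulder_angle(on_line) == pytest.approx(0.0)

    def test_measure_landmarks_matches_scalar_functions(self,
                                                        default_phantom):
        _, truth = default_phantom
        lm = truth.landmarks
        ms = measure_landmarks(lm)
        assert ms.glenoid_height == glenoid_height(lm)
        assert ms.glenoid_width == glenoid_width(lm)
        assert ms.retroversion == retroversion(lm)
        assert ms.inclination_angle == inclination_angle(lm)
        assert ms.critical_shoulder_angle == critical_shoulder_angle(lm)
        assert ms.rsa_angle == rsa_angle(lm)


def test_export_surface_mesh(tmp_path):
    import trimesh

    m = _sphere((12, 12, 12), 6)
    path = tmp_path / "sphere.ply"
    export_surface_mesh(m, path)
    mesh = trimesh.load(path)
    assert len(mesh.vertices) > 0 and len(mesh.faces) > 0
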