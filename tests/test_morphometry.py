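"""Morphometric measures: oracle equivalence, invariances, symmetry."""

import numpy as np
import pytest

from hipspace.mesh import (LandmarkMesh, RigidTransform, DegenerateGeometryError,
                           apply_transform, mirror_mesh)
from hipspace.morphometry import (ischiofemoral_distance, measure_femur,
                                  measure_pelvis, measure_hip, measure_cohort)
from hipspace.synthetic import default_distributions


def brute_force_min_distance(a: np.ndarray, b: np.ndarray):
    """Exhaustive all-pairs nearest-neighbor oracle."""
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return float(np.sqrt(d2[i, j])), i, j


def random_rigid(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return RigidTransform(q, rng.standard_normal(3) * 30)


class TestIschiofemoralDistance:
    def test_parallel_planes_unit_gap(self):
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        plane0 = np.c_[xs.ravel(), ys.ravel(), np.zeros(16)]
        plane1 = np.c_[xs.ravel(), ys.ravel(), np.ones(16)]
        femur = LandmarkMesh(plane0, np.empty((0, 3), int),
                             regions={"lesser_trochanter_area": np.arange(16)})
        pelvis = LandmarkMesh(plane1, np.empty((0, 3), int))
        assert ischiofemoral_distance(femur, pelvis).distance == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_oracle_exactly(self, rng):
        """KD-tree result must be bitwise equal to the brute-force scan."""
        for _ in range(100):
            a = rng.uniform(-50, 50, (500, 3))
            b = rng.uniform(-50, 50, (500, 3)) + rng.uniform(-20, 20, 3)
            femur = LandmarkMesh(a, np.empty((0, 3), int),
                                 regions={"lesser_trochanter_area": np.arange(len(a))})
            pelvis = LandmarkMesh(b, np.empty((0, 3), int))
            got = ischiofemoral_distance(femur, pelvis)
            expect, i, j = brute_force_min_distance(a, b)
            assert got.distance == expect
            assert np.array_equal(got.point_on_femur, a[i])
            assert np.array_equal(got.point_on_pelvis, b[j])

    def test_empty_region_rejected(self, mean_hip_female):
        _, pelvis, femur = mean_hip_female
        broken = femur.copy()
        broken.regions["lesser_trochanter_area"] = np.empty(0, dtype=np.int64)
        with pytest.raises(DegenerateGeometryError):
            ischiofemoral_distance(broken, pelvis)

    def test_surface_mode_not_larger_than_vertex_mode(self, mean_hip_female):
        _, pelvis, femur = mean_hip_female
        dv = ischiofemoral_distance(femur, pelvis, method="vertex").distance
        ds = ischiofemoral_distance(femur, pelvis, method="surface").distance
        assert ds <= dv + 1e-9
        assert ds == pytest.approx(dv, abs=0.5)

    def test_closest_point_falls_on_ischium(self, mean_hip_female):
        _, pelvis, femur = mean_hip_female
        pair = ischiofemoral_distance(femur, pelvis)
        ischium = pelvis.region_points("ischium")
        assert np.min(np.linalg.norm(ischium - pair.point_on_pelvis, axis=1)) < 1e-9


class TestFemurMeasures:
    def test_constructed_neck_angle_exact(self):
        """Hand-built geometry with the neck at exactly 125 deg to the shaft."""
        az = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        rings = [np.c_[np.cos(az) * 5, np.sin(az) * 5, np.full(8, z)]
                 for z in np.linspace(0, -100, 10)]
        shaft = np.vstack(rings)    # symmetric cylinder: principal axis is exactly z
        ang = np.deg2rad(125.0)
        neck_dir = np.array([-np.sin(ang), 0.0, -np.cos(ang)])  # 125 deg from -z
        head_center = 45.0 * neck_dir
        sph = np.random.default_rng(1).standard_normal((30, 3))
        sph /= np.linalg.norm(sph, axis=1, keepdims=True)
        head = head_center + 20.0 * sph
        extras = np.array([[0.0, 0, 0],           # neck base
                           [-10.0, -15.0, -5.0],  # lt apex
                           [-20.0, -10.0, -95.0], # medial posterior condyle
                           [20.0, -10.0, -95.0],  # lateral posterior condyle
                           [0.0, 0.0, -100.0]])   # mid condyle
        verts = np.vstack([shaft, head, extras])
        n_shaft = len(shaft)
        base = n_shaft + len(head)
        femur = LandmarkMesh(
            verts, np.empty((0, 3), int),
            landmarks={"neck_base": base, "lt_apex": base + 1,
                       "condyle_post_medial": base + 2, "condyle_post_lateral": base + 3,
                       "condyle_mid": base + 4},
            regions={"shaft": np.arange(n_shaft),
                     "femoral_head": np.arange(n_shaft, base),
                     "lesser_trochanter_area": np.array([base + 1]),
                     "condyles": np.arange(base + 2, base + 5)})
        fm = measure_femur(femur)
        assert fm.neck_shaft_angle == pytest.approx(125.0, abs=1e-6)
        assert fm.head_radius == pytest.approx(20.0, abs=1e-9)

    def test_missing_landmark_reported(self, mean_hip_female):
        _, _, femur = mean_hip_female
        broken = femur.copy()
        del broken.landmarks["neck_base"]
        with pytest.raises(KeyError, match="neck_base"):
            measure_femur(broken)

    def test_rigid_invariance_of_all_measures(self, mean_hip_female, rng):
        p, pelvis, femur = mean_hip_female
        ref = measure_hip(pelvis, femur)
        for _ in range(5):
            T = random_rigid(rng)
            rec = measure_hip(apply_transform(pelvis, T), apply_transform(femur, T))
            for name in ("neck_shaft_angle", "femoral_anteversion", "femoral_offset",
                         "head_radius", "lt_retroversion", "femoral_length",
                         "pelvic_width", "interspinous_distance", "ischial_spine_ratio",
                         "ischiofemoral_distance"):
                assert getattr(rec, name) == pytest.approx(getattr(ref, name), abs=1e-6), name


class TestPelvisMeasures:
    @pytest.mark.parametrize("isd,width,expected", [(100.04, 174.30, 0.57),
                                                    (114.68, 172.92, 0.66)])
    def test_spine_ratio_from_width_means(self, isd, width, expected):
        verts = np.array([[-width / 2, 0, 50.0], [width / 2, 0, 50.0],
                          [-isd / 2, -40.0, 0.0], [isd / 2, -40.0, 0.0]])
        pelvis = LandmarkMesh(verts, np.empty((0, 3), int),
                              landmarks={"iliac_lateral_left": 0, "iliac_lateral_right": 1,
                                         "ischial_spine_left": 2, "ischial_spine_right": 3})
        pm = measure_pelvis(pelvis)
        assert round(pm.ischial_spine_ratio, 2) == expected
        assert pm.ischial_spine_ratio * pm.pelvic_width == pytest.approx(
            pm.interspinous_distance, abs=1e-9)

    def test_coincident_spines_rejected(self):
        verts = np.array([[-80.0, 0, 0], [80.0, 0, 0], [0.0, -40, 0], [0.0, -40, 0]])
        pelvis = LandmarkMesh(verts, np.empty((0, 3), int),
                              landmarks={"iliac_lateral_left": 0, "iliac_lateral_right": 1,
                                         "ischial_spine_left": 2, "ischial_spine_right": 3})
        with pytest.raises(DegenerateGeometryError):
            measure_pelvis(pelvis)


class TestMirrorSymmetry:
    def test_unsigned_equal_signed_flip(self, mean_hip_female):
        _, pelvis, femur = mean_hip_female
        fm = measure_femur(femur)
        fmm = measure_femur(mirror_mesh(femur))
        assert fmm.neck_shaft_angle == pytest.approx(fm.neck_shaft_angle, abs=1e-9)
        assert fmm.femoral_offset == pytest.approx(fm.femoral_offset, abs=1e-9)
        assert fmm.femoral_length == pytest.approx(fm.femoral_length, abs=1e-9)
        assert fmm.head_radius == pytest.approx(fm.head_radius, abs=1e-9)
        assert fmm.femoral_anteversion == pytest.approx(-fm.femoral_anteversion, abs=1e-9)
        assert fmm.lt_retroversion == pytest.approx(-fm.lt_retroversion, abs=1e-9)
        pm = measure_pelvis(pelvis)
        pmm = measure_pelvis(mirror_mesh(pelvis))
        assert pmm.pelvic_width == pytest.approx(pm.pelvic_width, abs=1e-9)
        assert pmm.interspinous_distance == pytest.approx(pm.interspinous_distance, abs=1e-9)


class TestCohortMeasurement:
    def test_stable_order_and_row_count(self, small_cohorts):
        meshes, _ = small_cohorts["male"]
        df = measure_cohort(meshes[:10], sex="male")
        assert len(df) == 10
        assert list(df["sample_id"]) == list(range(10))

    def test_broken_sample_named_in_error(self, small_cohorts):
        meshes, _ = small_cohorts["male"]
        broken = meshes[3][1].copy()
        del broken.landmarks["lt_apex"]
        cohort = list(meshes[:5])
        cohort[3] = (meshes[3][0], broken)
        with pytest.raises(KeyError, match="sample 3"):
            measure_cohort(cohort)

    def test_cohort_recovery_of_gap_mean(self, small_cohorts):
        meshes, truth = small_cohorts["female"]
        df = measure_cohort(meshes, sex="female")
        se = default_distributions("female").sds[-1] / np.sqrt(len(df))
        assert abs(df["ischiofemoral_distance"].mean() - 22.24) < 3 * se + 0.5
        # per-sample agreement with the drawn ground truth
        assert np.abs(df["ischiofemoral_distance"].to_numpy()
                      - truth["ifd_gap"].to_numpy()).max() < 0.5
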