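import math
from dataclasses import replace

import numpy as np
import pytest

from acromorph import (
    AALPRegion,
    ScapularLandmarks,
    ShoulderModel,
    ShoulderSpec,
    find_MLPA,
    generate_shoulder,
    localize_AALP,
    measure_AALP_params,
    measure_AAP,
    measure_AC_angle,
    measure_AHI,
    measure_AIP,
    measure_all,
    rigid_transform,
    split_acromion,
)
from acromorph.config import RunConfig
from acromorph.errors import DegenerateGeometryError
from acromorph.geometry import TriangleMesh
from acromorph.measures import PARAMETERS, _line_offset_distance
from acromorph.scapular_frame import build_frame
from acromorph.synthetic import box_mesh, uv_sphere

from conftest import random_rotation


def _canonical_landmarks(**kw):
    theta = 2 * np.pi * np.arange(12) / 12
    rim = np.column_stack([np.zeros(12), 14 * np.cos(theta), 14 * np.sin(theta)])
    defaults = dict(
        glenoid_rim=rim, B=(-100.0, 0.0, 0.0), C=(-40.0, -120.0, 0.0),
        AM=(20.0, 26.0, -3.0), PM=(20.0, 26.0, -7.0),
        anterior_witness=(0.0, 0.0, 30.0), side="right")
    defaults.update(kw)
    return ScapularLandmarks(**defaults)


def _toy_model(acromion=None, clavicle=None, humerus=None, landmarks=None):
    """Hand-built model in the canonical frame (identity after build_frame)."""
    if acromion is None:
        acromion = box_mesh((5, 18.1, -20), (35, 24, 10), step=1.0)
    scap = TriangleMesh(acromion.vertices, acromion.faces,
                        {"acromion": np.ones(len(acromion), dtype=bool)})
    if clavicle is None:
        clavicle = box_mesh((-60, 26.6, -6.8), (18, 32, 3.2), step=1.0)
    if humerus is None:
        humerus = uv_sphere((8, 0, 0), 10.0)
    return ShoulderModel(scap, clavicle, humerus,
                         landmarks or _canonical_landmarks())


@pytest.fixture(scope="module")
def toy():
    model = _toy_model()
    return model, build_frame(model.landmarks)


class TestFindMLPA:
    def test_synthetic_apex(self, default_shoulder):
        model, truth = default_shoulder
        frame = build_frame(model.landmarks)
        assert np.allclose(find_MLPA(model, frame), truth.mlpa, atol=1e-9)

    def test_rigid_motion_same_anatomical_point(self, default_shoulder, rng):
        model, _ = default_shoulder
        p0 = find_MLPA(model, build_frame(model.landmarks))
        r, t = random_rotation(rng), rng.uniform(-40, 40, 3)
        moved = rigid_transform(model, r, t)
        p1 = find_MLPA(moved, build_frame(moved.landmarks))
        assert np.allclose(p0, p1, atol=1e-6)

    def test_tie_breaks_to_lower_y_then_z(self, toy):
        model, frame = toy
        # box: four corners share max x; rule picks min y, then min z
        mlpa = find_MLPA(model, frame)
        assert np.allclose(mlpa, (35.0, 18.1, -20.0), atol=1e-9)


class TestAHI:
    def test_flat_undersurface_closed_form(self, toy):
        model, frame = toy
        ahi, flags = measure_AHI(model, frame)
        # sphere top y=10 under flat undersurface y=18.1
        assert ahi == pytest.approx(8.1, abs=0.02)
        assert "no_overhang" not in flags

    def test_monotone_in_head_height(self, toy):
        model, frame = toy
        base, _ = measure_AHI(model, frame)
        raised = _toy_model(humerus=uv_sphere((8, 1.0, 0), 10.0))
        up, _ = measure_AHI(raised, frame)
        assert base - up == pytest.approx(1.0, abs=1e-6)

    def test_tilted_undersurface_closed_form(self):
        alpha = math.radians(10)
        r = np.array([[1, 0, 0],
                      [0, math.cos(alpha), -math.sin(alpha)],
                      [0, math.sin(alpha), math.cos(alpha)]])
        slab = box_mesh((5, 18.1, -20), (35, 24, 10), step=1.0).transformed(r, np.zeros(3))
        model = _toy_model(acromion=slab)
        frame = build_frame(model.landmarks)
        ahi, _ = measure_AHI(model, frame)
        # analytic 2D point-line distance in the y-z projection
        assert ahi == pytest.approx(18.1 - 10 * math.cos(alpha), abs=0.03)

    def test_no_overhang_flag(self):
        model = _toy_model(humerus=uv_sphere((8, 0, 40.0), 10.0))
        frame = build_frame(model.landmarks)
        ahi, flags = measure_AHI(model, frame)
        assert flags.get("no_overhang") is True
        assert ahi > 0


class TestAAPandAIP:
    def test_aap_closed_form(self, toy):
        model, frame = toy
        aap, flags = measure_AAP(model, frame)
        # clavicle anterior edge z=3.2, most anterior acromion z=10
        assert aap == pytest.approx(6.8, abs=1e-6)
        assert not flags

    def test_aap_clamped_when_posterior(self):
        clav = box_mesh((-60, 26.6, -6.8), (18, 32, 15.0), step=1.0)
        model = _toy_model(clavicle=clav)
        frame = build_frame(model.landmarks)
        aap, flags = measure_AAP(model, frame)
        assert aap == 0.0
        assert flags.get("aap_clamped") is True

    def test_aip_closed_form(self, toy):
        model, frame = toy
        mlpa = find_MLPA(model, frame)
        anterior, _ = split_acromion(model, frame, mlpa)
        aip, flags = measure_AIP(model, frame, anterior)
        # clavicle inferior edge y=26.6, lowest anterior acromion y=18.1
        assert aip == pytest.approx(8.5, abs=1e-6)
        assert not flags

    def test_aip_clamped_when_above(self):
        clav = box_mesh((-60, 10.0, -6.8), (18, 15.0, 3.2), step=1.0)
        model = _toy_model(clavicle=clav)
        frame = build_frame(model.landmarks)
        mlpa = find_MLPA(model, frame)
        anterior, _ = split_acromion(model, frame, mlpa)
        aip, flags = measure_AIP(model, frame, anterior)
        assert aip == 0.0
        assert flags.get("aip_clamped") is True

    @pytest.mark.parametrize("angle_deg", [10.0, 30.0, 60.0])
    def test_tilted_line_distance_matches_closed_form(self, angle_deg, rng):
        # points on a tilted line; offset point at known perpendicular distance
        a = math.radians(angle_deg)
        direction = np.array([math.cos(a), math.sin(a)])
        normal = np.array([-math.sin(a), math.cos(a)])
        line_pts = np.outer(np.linspace(-10, 10, 25), direction)
        point = 4.2 * normal + 3.0 * direction
        d = _line_offset_distance(line_pts, point, positive_toward=normal)
        assert d == pytest.approx(4.2, abs=1e-9)
        d = _line_offset_distance(line_pts, -point, positive_toward=normal)
        assert d < 0


class TestACAngle:
    def test_closed_form_2atan(self):
        lm = _canonical_landmarks(AM=(0.0, 5.0, -3.0), PM=(0.0, -5.0, -7.0))
        model = _toy_model(landmarks=lm)
        frame = build_frame(model.landmarks)
        angle = measure_AC_angle(model, frame, np.array([20.0, 0.0, -5.0]))
        assert angle == pytest.approx(math.degrees(2 * math.atan(5 / 20)), abs=1e-9)

    def test_orthogonal_symmetric(self):
        lm = _canonical_landmarks(AM=(0.0, 10.0, -3.0), PM=(0.0, -10.0, -7.0))
        model = _toy_model(landmarks=lm)
        frame = build_frame(model.landmarks)
        angle = measure_AC_angle(model, frame, np.array([10.0, 0.0, -5.0]))
        assert angle == pytest.approx(90.0, abs=1e-9)

    def test_random_matches_arccos_oracle(self, rng):
        for _ in range(10):
            am = rng.uniform(-20, 20, 3)
            pm = rng.uniform(-20, 20, 3)
            apex = rng.uniform(-20, 20, 3)
            lm = _canonical_landmarks(AM=am, PM=pm)
            model = _toy_model(landmarks=lm)
            frame = build_frame(model.landmarks)
            v1, v2 = am[:2] - apex[:2], pm[:2] - apex[:2]
            expected = math.degrees(math.acos(np.clip(
                v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
            assert measure_AC_angle(model, frame, apex) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_margin_errors(self):
        model = _toy_model()
        frame = build_frame(model.landmarks)
        apex = np.array([20.0, 26.0, 0.0])  # projects onto AM in x-y
        with pytest.raises(DegenerateGeometryError):
            measure_AC_angle(model, frame, apex)


class TestSplitAcromion:
    def test_z_extents(self, toy):
        model, frame = toy
        # slab z in [-20, 10], MLPA corner at z=-20: anterior spans the slab
        anterior, posterior = split_acromion(model, frame, np.array([35.0, 18.1, 0.0]))
        assert anterior.vertices[:, 2].min() >= 0.0
        assert anterior.vertices[:, 2].max() == pytest.approx(10.0)
        assert posterior.vertices[:, 2].max() < 0.0
        assert posterior.vertices[:, 2].min() == pytest.approx(-20.0)

    def test_boundary_vertex_goes_anterior(self, toy):
        model, frame = toy
        anterior, _ = split_acromion(model, frame, np.array([35.0, 18.1, -20.0]))
        assert anterior.vertices[:, 2].min() == pytest.approx(-20.0)

    def test_vertex_counts_partition(self, toy):
        model, frame = toy
        acr = model.acromion()
        anterior, posterior = split_acromion(model, frame, np.array([35.0, 18.1, 0.0]))
        assert len(anterior.vertices) + len(posterior.vertices) == len(acr.vertices)


class TestLocalizeAALP:
    def test_border_matches_analytic_crease(self, default_shoulder):
        model, truth = default_shoulder
        frame = build_frame(model.landmarks)
        mlpa = find_MLPA(model, frame)
        anterior, _ = split_acromion(model, frame, mlpa)
        config = RunConfig()
        region = localize_AALP(model, frame, anterior, config)
        assert not region.empty
        assert region.slice_count >= config.min_slices
        # analytic crease line from the generator
        b0, b1 = truth.border_bottom, truth.border_top
        for p in region.medial_border:
            t = np.clip((p[1] - b0[1]) / (b1[1] - b0[1]), 0, 1)
            expected = b0 + t * (b1 - b0)
            assert abs(p[1] - expected[1]) <= config.slice_step + 1e-9
            assert np.linalg.norm(p[[0, 2]] - expected[[0, 2]]) < 1.0

    def test_border_in_anterior_half(self, default_shoulder):
        model, truth = default_shoulder
        frame = build_frame(model.landmarks)
        mlpa = find_MLPA(model, frame)
        anterior, _ = split_acromion(model, frame, mlpa)
        region = localize_AALP(model, frame, anterior)
        assert np.all(region.medial_border[:, 2] >= mlpa[2])

    def test_smooth_acromion_yields_empty_region(self):
        model, _ = generate_shoulder(ShoulderSpec(has_lobe=False))
        frame = build_frame(model.landmarks)
        mlpa = find_MLPA(model, frame)
        anterior, _ = split_acromion(model, frame, mlpa)
        region = localize_AALP(model, frame, anterior)
        assert region.empty

    def test_tessellation_refinement_stability(self):
        borders = []
        for res in (0.8, 0.4):
            model, _ = generate_shoulder(ShoulderSpec(mesh_resolution=res))
            frame = build_frame(model.landmarks)
            mlpa = find_MLPA(model, frame)
            anterior, _ = split_acromion(model, frame, mlpa)
            borders.append(localize_AALP(model, frame, anterior).medial_border)
        coarse, fine = borders
        # compare per matching slice height
        n = min(len(coarse), len(fine))
        for p in coarse[:n]:
            j = int(np.argmin(np.abs(fine[:, 1] - p[1])))
            assert np.linalg.norm(p[[0, 2]] - fine[j][[0, 2]]) < 0.2


class TestAALPParams:
    def test_construction_arithmetic(self):
        # lobe spanning z in [2, 13.3] on an acromion spanning [-22.2, 13.3]
        acr = box_mesh((5, 18, -22.2), (35, 24, 13.3), step=1.0)
        border = np.array([[20.0, 19.0, 2.0], [20.0, 20.0, 2.0], [20.0, 21.0, 2.0]])
        members = np.array([[25.0, 19.0, 2.0], [25.0, 19.0, 13.3]])
        region = AALPRegion(medial_border=border, member_points=members, slice_count=3)
        out = measure_AALP_params(region, acr, np.array([35.0, 18.0, -5.0]))
        assert out["c_mm"] == pytest.approx(11.3, abs=1e-9)
        assert out["c_plus_d_mm"] == pytest.approx(35.5, abs=1e-9)
        assert out["ratio_percent"] == pytest.approx(31.8, abs=0.05)

    def test_empty_region_reports_absent(self):
        acr = box_mesh((5, 18, -22.2), (35, 24, 13.3), step=1.0)
        out = measure_AALP_params(AALPRegion.none(), acr, np.array([35.0, 18.0, -5.0]))
        assert out["a_mm"] is None and out["b_mm"] is None and out["c_mm"] is None
        assert out["c_plus_d_mm"] == pytest.approx(35.5)

    def test_b_uses_posterior_band(self):
        acr = box_mesh((5, 18, -22.2), (35, 24, 13.3), step=1.0)
        # border slants: most medial at anterior end, posterior end more lateral
        ys = np.linspace(19, 23, 9)
        xs = np.linspace(24.0, 20.0, 9)   # x decreases toward anterior
        zs = np.linspace(2.0, 10.0, 9)    # z increases toward anterior
        border = np.column_stack([xs, ys, zs])
        region = AALPRegion(border, border, slice_count=9)
        mlpa = np.array([35.0, 18.0, -5.0])
        out = measure_AALP_params(region, acr, mlpa)
        # a: most medial = last point; b: min x within lowest 20% of z span
        assert out["a_mm"] == pytest.approx(np.linalg.norm((20.0 - 35, 10.0 + 5)), abs=1e-9)
        band = border[border[:, 2] <= 2.0 + 0.2 * 8.0 + 1e-9]
        b_pt = band[np.argmin(band[:, 0])]
        assert out["b_mm"] == pytest.approx(
            np.linalg.norm(b_pt[[0, 2]] - mlpa[[0, 2]]), abs=1e-9)


class TestMeasureAll:
    def test_recovers_generator_truth(self, default_shoulder, default_measurements):
        _, truth = default_shoulder
        ms = default_measurements.as_dict()
        td = truth.as_dict()
        for p in PARAMETERS:
            tol = 1.5 if p == "ac_angle_deg" else max(0.5, 0.03 * abs(td[p]))
            assert abs(ms[p] - td[p]) <= tol, p

    def test_rigid_invariance(self, default_shoulder, default_measurements, rng):
        model, _ = default_shoulder
        ms0 = default_measurements.as_dict()
        r, t = random_rotation(rng), rng.uniform(-50, 50, 3)
        ms1 = measure_all(rigid_transform(model, r, t)).as_dict()
        for p in PARAMETERS:
            assert abs(ms1[p] - ms0[p]) <= 1e-6 * max(abs(ms0[p]), 1.0), p

    def test_mirror_twin_identical(self, default_measurements):
        left, _ = generate_shoulder(ShoulderSpec(side="left"))
        msl = measure_all(left).as_dict()
        ms0 = default_measurements.as_dict()
        for p in PARAMETERS:
            assert abs(msl[p] - ms0[p]) <= 1e-6, p
        assert msl["flags"].get("mirrored") is True

    def test_uniform_scaling(self, default_shoulder, default_measurements):
        model, _ = default_shoulder
        s = 1.1
        scaled = ShoulderModel(
            scapula_mesh=TriangleMesh(model.scapula_mesh.vertices * s,
                                      model.scapula_mesh.faces,
                                      dict(model.scapula_mesh.labels)),
            clavicle_mesh=TriangleMesh(model.clavicle_mesh.vertices * s,
                                       model.clavicle_mesh.faces,
                                       dict(model.clavicle_mesh.labels)),
            humerus_mesh=TriangleMesh(model.humerus_mesh.vertices * s,
                                      model.humerus_mesh.faces),
            landmarks=replace(model.landmarks,
                              glenoid_rim=model.landmarks.glenoid_rim * s,
                              B=model.landmarks.B * s, C=model.landmarks.C * s,
                              AM=model.landmarks.AM * s, PM=model.landmarks.PM * s,
                              anterior_witness=model.landmarks.anterior_witness * s))
        ms0 = default_measurements.as_dict()
        ms1 = measure_all(scaled).as_dict()
        for p in ("ahi_mm", "aap_mm", "aip_mm"):
            assert ms1[p] == pytest.approx(s * ms0[p], abs=0.02)
        for p in ("a_mm", "b_mm", "c_mm", "c_plus_d_mm"):
            assert ms1[p] == pytest.approx(s * ms0[p], abs=0.3)
        assert ms1["ac_angle_deg"] == pytest.approx(ms0["ac_angle_deg"], abs=0.01)
        assert ms1["ratio_percent"] == pytest.approx(ms0["ratio_percent"], abs=0.5)

    def test_invariants_hold(self, default_measurements):
        ms = default_measurements
        assert ms.c_mm <= ms.c_plus_d_mm
        assert 0 < ms.ratio_percent < 100
        for p in ("ahi_mm", "aap_mm", "aip_mm", "a_mm", "b_mm", "c_mm"):
            assert getattr(ms, p) >= 0
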