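"""Reference planes, morphological parameters and lumbar lordosis."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pelvisop.geometry import Pose, angle_between, plane_orientation
from pelvisop.pelvis import (
    MORPHO_ANGLE_NAMES,
    MORPHO_DISTANCE_DEFS,
    PLANE_IDS,
    DegeneratePlaneError,
    LandmarkSet,
    MissingLandmarkError,
    construct_reference_plane,
    lumbar_lordosis_angle,
    morphological_parameters,
)
from pelvisop.synthetic_data import TEMPLATE_GROUND_TRUTH


def random_rigid(rng) -> Pose:
    return Pose(Rotation.random(random_state=rng).as_matrix(),
                rng.normal(0.0, 50.0, 3))


def test_plane_registry_has_five_planes():
    assert len(PLANE_IDS) == 5
    assert {"SSP", "PTP", "APP"} <= set(PLANE_IDS)


def test_app_from_vertical_points_is_frontal():
    # ASIS and symphysis coplanar in a vertical plane -> normal along Y
    lm = LandmarkSet({
        "ASIS_L": [120, 0, 0], "ASIS_R": [-120, 0, 0],
        "pubic_symphysis": [0, 0, -90],
        "PSIS_L": [40, -150, 10], "PSIS_R": [-40, -150, 10],
        "hip_center_L": [85, -10, -40], "hip_center_R": [-85, -10, -40],
    })
    app = construct_reference_plane(lm, "APP")
    assert np.allclose(np.abs(app.normal), [0, 1, 0], atol=1e-12)
    t = plane_orientation(app, Pose.identity())
    assert np.isclose(t.sop, 0.0, atol=1e-9)


def test_template_ssp_sop_equals_designed_sacral_slope(template):
    ssp = construct_reference_plane(template, "SSP")
    sop = plane_orientation(ssp, Pose.identity()).sop
    assert np.isclose(sop, TEMPLATE_GROUND_TRUTH["sacral_slope"], atol=1e-9)
    # independent two-vector oracle: endplate direction vs horizontal
    d = template["S1_endplate_anterior"] - template["S1_endplate_posterior"]
    oracle = np.degrees(np.arctan2(d[2], d[1]))
    assert np.isclose(sop, oracle, atol=1e-9)


def test_unrelated_landmarks_do_not_move_planes(template):
    moved = dict(template.points)
    moved["ischial_tuberosity_L"] = moved["ischial_tuberosity_L"] + 5.0
    moved["iliac_crest_R"] = moved["iliac_crest_R"] - 3.0
    lm2 = LandmarkSet(moved)
    for pid in ("SSP", "APP", "PTP", "X1"):  # X2 uses crest/tuberosity
        a = construct_reference_plane(template, pid)
        b = construct_reference_plane(lm2, pid)
        assert np.allclose(a.normal, b.normal, atol=1e-12)


def test_planes_differ_in_general_but_agree_in_change(jittered_template):
    planes = [construct_reference_plane(jittered_template, pid)
              for pid in PLANE_IDS]
    sops = [plane_orientation(p, Pose.identity()).sop for p in planes]
    assert len(np.unique(np.round(sops, 6))) == len(PLANE_IDS)


def test_missing_landmark_is_named():
    lm = LandmarkSet({"ASIS_L": [1, 2, 3]})
    with pytest.raises(MissingLandmarkError):
        construct_reference_plane(lm, "APP")


def test_collinear_points_raise(template):
    pts = dict(template.points)
    pts["pubic_symphysis"] = 0.5 * (pts["ASIS_L"] + pts["ASIS_R"])
    with pytest.raises(DegeneratePlaneError):
        construct_reference_plane(LandmarkSet(pts), "APP")


def test_morpho_counts_and_registry(template):
    mp = morphological_parameters(template)
    assert len(mp.distances) == 13
    assert len(mp.angles) == 5
    assert len(mp.names) == 18
    assert set(mp.angles) == set(MORPHO_ANGLE_NAMES)
    with pytest.raises(ValueError):
        morphological_parameters(template,
                                 distance_defs=MORPHO_DISTANCE_DEFS[:5])


def test_morpho_rigid_invariance(jittered_template, rng):
    base = morphological_parameters(jittered_template).as_dict()
    for _ in range(5):
        moved = jittered_template.transformed(random_rigid(rng))
        other = morphological_parameters(moved).as_dict()
        for name, v in base.items():
            assert abs(other[name] - v) < 1e-9, name


def test_morpho_scaling(template):
    a = morphological_parameters(template)
    b = morphological_parameters(template.scaled(2.0))
    for name in a.distances:
        assert np.isclose(b.distances[name], 2.0 * a.distances[name])
    for name in a.angles:
        assert np.isclose(b.angles[name], a.angles[name], atol=1e-9)


def test_pelvic_incidence_against_dot_product_oracle(template):
    mp = morphological_parameters(template)
    d = template["S1_endplate_anterior"] - template["S1_endplate_posterior"]
    d = d / np.linalg.norm(d)
    normal = np.cross([1.0, 0, 0], d)  # template ML axis is exactly X
    normal /= np.linalg.norm(normal)
    line = template.hjc_midpoint - template["S1_endplate_center"]
    oracle = angle_between(-normal, line)
    assert np.isclose(mp.angles["pelvic_incidence"], oracle, atol=1e-9)


def test_pelvic_incidence_zero_when_perpendicular_hits_hjc():
    # hip-center midpoint placed along the caudal endplate perpendicular
    s = np.radians(30.0)
    center = np.array([0.0, 0.0, 100.0])
    d = np.array([0.0, np.cos(s), np.sin(s)])
    n = np.array([0.0, -np.sin(s), np.cos(s)])
    lm = {
        "S1_endplate_center": center,
        "S1_endplate_anterior": center + 15 * d,
        "S1_endplate_posterior": center - 15 * d,
        "hip_center_L": center - 80 * n + [60, 0, 0],
        "hip_center_R": center - 80 * n - [60, 0, 0],
        "ASIS_L": [115, 70, 90], "ASIS_R": [-115, 70, 90],
        "PSIS_L": [42, -90, 95], "PSIS_R": [-42, -90, 95],
        "pubic_symphysis": [0, 66, -25],
        "pubic_tubercle_L": [16, 68, -15], "pubic_tubercle_R": [-16, 68, -15],
        "sacral_promontory": center + 17 * d,
        "ischial_tuberosity_L": [55, -20, -95],
        "ischial_tuberosity_R": [-55, -20, -95],
        "iliac_crest_L": [65, -10, 140], "iliac_crest_R": [-65, -10, 140],
    }
    mp = morphological_parameters(LandmarkSet(lm))
    assert mp.angles["pelvic_incidence"] < 1e-6


def test_lla_parallel_endplates_is_zero(template):
    pts = dict(template.points)
    pts["L1sup_a"] = pts["S1_endplate_anterior"] + [0, 0, 160.0]
    pts["L1sup_p"] = pts["S1_endplate_posterior"] + [0, 0, 160.0]
    assert np.isclose(lumbar_lordosis_angle(LandmarkSet(pts)), 0.0, atol=1e-9)


def test_lla_closed_form_angle_difference(template):
    # L1 tangent at +30 deg, S1 at -18 deg -> LLA = 48
    pts = dict(template.points)
    for tag, tilt, z in (("L1sup", 30.0, 240.0), ):
        d = 15 * np.array([0, np.cos(np.radians(tilt)), np.sin(np.radians(tilt))])
        c = np.array([0.0, 30.0, z])
        pts[f"{tag}_a"], pts[f"{tag}_p"] = c + d, c - d
    d = 17 * np.array([0, np.cos(np.radians(-18.0)), np.sin(np.radians(-18.0))])
    c = np.array([0.0, 25.0, 80.0])
    pts["S1_endplate_anterior"], pts["S1_endplate_posterior"] = c + d, c - d
    assert np.isclose(lumbar_lordosis_angle(LandmarkSet(pts)), 48.0, atol=1e-9)


def test_lla_fused_uses_l5_and_ignores_s1(template):
    pts = dict(template.points)
    pts["S1_endplate_anterior"] = [0, 40.0, 95.0]  # corrupt S1
    lm = LandmarkSet(pts)
    fused = lumbar_lordosis_angle(lm, l5s1_fused=True)
    assert np.isclose(fused, lumbar_lordosis_angle(template, l5s1_fused=True))
    with pytest.raises(MissingLandmarkError):
        lumbar_lordosis_angle(
            LandmarkSet({k: v for k, v in template.points.items()
                         if k != "L1sup_a"}))


def test_template_lla_matches_design(template):
    assert np.isclose(lumbar_lordosis_angle(template),
                      TEMPLATE_GROUND_TRUTH["lla"], atol=1e-9)


def test_landmark_json_roundtrip(tmp_path, template):
    path = tmp_path / "lm.json"
    template.to_json(path)
    back = LandmarkSet.from_json(path)
    for name in template.names():
        assert np.allclose(back[name], template[name])
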