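"""Projection model, landmark pre-registration, contour refinement, ICP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pelvisop.geometry import (
    OrientationTriple,
    Pose,
    recompose_orientation,
    rotation_x,
    rotation_z,
)
from pelvisop.pelvis import PLANE_IDS, construct_reference_plane
from pelvisop.registration import (
    BiplanarViews,
    ContourError,
    UnderConstrainedError,
    icp_rigid,
    measure_sop,
    preregister,
    project,
    refine,
)
from pelvisop.geometry import plane_orientation
from pelvisop.synthetic_data import (
    generate_phantom_views,
    template_contour3d,
)


def views_at(landmarks, triple, noise=0.0, seed=0, contours=False):
    return generate_phantom_views(landmarks, triple, pick_noise_sd=noise,
                                  seed=seed, include_contours=contours)


def rotation_error_deg(R1, R2) -> float:
    return np.degrees(Rotation.from_matrix(R1.T @ R2).magnitude())


def test_project_drops_expected_axes():
    ap, lat = project(np.array([[1.0, 2.0, 3.0]]), Pose.identity())
    assert np.allclose(ap[0], [1, 3])
    assert np.allclose(lat[0], [2, 3])


def test_project_translation_moves_one_view_only():
    pose = Pose(np.eye(3), [0, 5.0, 0])
    ap, lat = project(np.array([[1.0, 2.0, 3.0]]), pose)
    assert np.allclose(ap[0], [1, 3])
    assert np.allclose(lat[0], [7, 3])


def test_project_matches_matrix_oracle(rng):
    pts = rng.normal(0, 50, (10, 3))
    R = rotation_z(90.0)
    pose = Pose(R, [1.0, -2.0, 3.0])
    ap, lat = project(pts, pose)
    moved = pts @ R.T + pose.translation
    assert np.allclose(ap, moved[:, [0, 2]], atol=1e-12)
    assert np.allclose(lat, moved[:, [1, 2]], atol=1e-12)
    # 90 deg about Z maps (1,0,0) to (0,1,0): AP sees (0, 0)
    ap1, _ = project(np.array([[1.0, 0, 0]]), Pose(R))
    assert np.allclose(ap1[0], [0, 0], atol=1e-12)


def test_preregister_exact_recovery(template):
    true = OrientationTriple(sop=12.0, fop=-7.0, top=21.0)
    views = views_at(template, (true.sop, true.fop, true.top))
    pose = preregister(template, views)
    assert rotation_error_deg(pose.rotation,
                              recompose_orientation(true)) < 1e-6
    assert np.linalg.norm(pose.translation) < 1e-6


def test_preregister_under_constrained(template):
    views = views_at(template, (0, 0, 0))
    two = BiplanarViews(
        ap_picks={k: views.ap_picks[k] for k in list(views.ap_picks)[:2]},
        lat_picks={k: views.lat_picks[k] for k in list(views.lat_picks)[:2]})
    with pytest.raises(UnderConstrainedError):
        preregister(template, two)


def test_preregister_noise_monte_carlo(template):
    # 0.5 mm pick noise: orientation error <= 1.5 deg in >= 95% of trials
    truth = recompose_orientation(OrientationTriple(10.0, 0.0, 5.0))
    errs = []
    for trial in range(200):
        views = views_at(template, (10.0, 0.0, 5.0), noise=0.5, seed=trial)
        pose = preregister(template, views)
        errs.append(rotation_error_deg(pose.rotation, truth))
    assert np.mean(np.asarray(errs) <= 1.5) >= 0.95


def test_refine_recovers_from_sagittal_perturbation(template):
    contour = template_contour3d(template)
    views = views_at(template, (20.0, 0.0, 0.0), contours=True)
    pose0 = Pose(rotation_x(25.0))  # 5 deg sagittal error
    result = refine(pose0, contour, views)
    ssp = construct_reference_plane(template, "SSP")
    sop = plane_orientation(ssp, result.pose).sop
    true_sop = plane_orientation(
        ssp, Pose(recompose_orientation(OrientationTriple(20.0, 0, 0)))).sop
    assert abs(sop - true_sop) < 0.3
    assert result.rms_residual >= 0


def test_refine_at_truth_stays_put(template):
    contour = template_contour3d(template)
    views = views_at(template, (15.0, 0.0, 0.0), contours=True)
    truth = Pose(recompose_orientation(OrientationTriple(15.0, 0, 0)))
    result = refine(truth, contour, views)
    assert rotation_error_deg(result.pose.rotation, truth.rotation) < 0.05


def test_refine_never_worsens_objective(template):
    contour = template_contour3d(template)
    views = views_at(template, (0.0, 0.0, 0.0), contours=True,
                     noise=1.0, seed=3)
    pose0 = Pose(rotation_x(8.0), [2.0, -3.0, 1.0])

    def objective(pose):
        from scipy.spatial import cKDTree
        ap, lat = project(contour, pose)
        return (np.mean(cKDTree(views.ap_contour).query(ap)[0] ** 2)
                + np.mean(cKDTree(views.lat_contour).query(lat)[0] ** 2))

    result = refine(pose0, contour, views)
    assert objective(result.pose) <= objective(pose0) + 1e-12


def test_refine_requires_contours(template):
    views = views_at(template, (0, 0, 0))
    with pytest.raises(ContourError):
        refine(Pose.identity(), template_contour3d(template), views)


def test_measure_sop_noise_free(template):
    # canonical pose: the SSP plane reads the designed sacral slope
    views = views_at(template, (0.0, 0.0, 0.0))
    t = measure_sop(template, views, "SSP")
    assert abs(t.sop - 38.5) < 0.1


def test_measure_sop_planes_share_the_registration_error(template):
    views = views_at(template, (7.0, 0.0, -10.0), noise=0.5, seed=11)
    truth = Pose(recompose_orientation(OrientationTriple(7.0, 0.0, -10.0)))
    deltas = []
    for pid in ("SSP", "APP"):
        plane = construct_reference_plane(template, pid)
        measured = measure_sop(template, views, pid)
        deltas.append(measured.sop - plane_orientation(plane, truth).sop)
    assert abs(deltas[0] - deltas[1]) < 0.1
    assert abs(deltas[0]) > 0  # noise did something


def test_measure_sop_missing_picks(template):
    views = BiplanarViews(ap_picks={}, lat_picks={})
    with pytest.raises(UnderConstrainedError):
        measure_sop(template, views, "SSP")


def test_end_to_end_bias_noise_free_sweep(template):
    # |measured - true| < 0.05 deg for all five planes over a pose sweep
    rng = np.random.default_rng(5)
    planes = {pid: construct_reference_plane(template, pid)
              for pid in PLANE_IDS}
    for _ in range(50):
        trip = (rng.uniform(-30, 30), rng.uniform(-15, 15),
                rng.uniform(-30, 30))
        views = views_at(template, trip)
        truth = Pose(recompose_orientation(OrientationTriple(*trip)))
        pose = preregister(template, views)
        for pid, plane in planes.items():
            measured = plane_orientation(plane, pose).sop
            expected = plane_orientation(plane, truth).sop
            assert abs(measured - expected) < 0.05


def test_sagittal_equivariance(template):
    # rotating the generating pose by dSOP shifts the measured SOP by dSOP
    base = (5.0, 0.0, 0.0)
    shifted = (5.0 + 9.0, 0.0, 0.0)
    s0 = measure_sop(template, views_at(template, base), "SSP").sop
    s1 = measure_sop(template, views_at(template, shifted), "SSP").sop
    assert abs((s1 - s0) - 9.0) < 0.05


def test_icp_identity_and_exact_recovery(template, rng):
    cloud = template_contour3d(template)
    res = icp_rigid(cloud, cloud)
    assert rotation_error_deg(res.pose.rotation, np.eye(3)) < 1e-6
    assert res.rms_residual < 1e-9

    truth = Pose(rotation_x(5.0), [5.0, -2.0, 3.0])
    res = icp_rigid(cloud, truth.apply(cloud), init=truth)
    assert rotation_error_deg(res.pose.rotation, truth.rotation) < 1e-6


def test_icp_converges_from_perturbed_start(template):
    cloud = template_contour3d(template)
    truth = Pose(rotation_x(5.0), [5.0, 0.0, 0.0])
    res = icp_rigid(cloud, truth.apply(cloud))
    assert rotation_error_deg(res.pose.rotation, truth.rotation) < 0.1
    assert np.linalg.norm(res.pose.translation - truth.translation) < 0.1
    assert res.converged


def test_icp_degenerate_geometry():
    line = np.column_stack([np.linspace(0, 10, 8),
                            np.zeros(8), np.zeros(8)])
    with pytest.raises(ValueError):
        icp_rigid(line, line)


def test_views_json_roundtrip(tmp_path, template):
    views = views_at(template, (5, 0, 0), contours=True)
    path = tmp_path / "views.json"
    views.to_json(path)
    back = BiplanarViews.from_json(path)
    for name in views.ap_picks:
        assert np.allclose(back.ap_picks[name], views.ap_picks[name])
    assert np.allclose(back.ap_contour, views.ap_contour)
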