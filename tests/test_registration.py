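"""Fiducial detection, transform fitting, targeting and fusion."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from clemtarget import phantom, registration as reg
from clemtarget.errors import (
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    RotationAmbiguousError,
    TargetNotHeldOutError,
)
from clemtarget.experiments import blind_target_trial, transform_recovery_trial
from clemtarget.transform import Transform3D
from clemtarget.volume import Modality


def _point_scene(points):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return phantom.Scene(
        organelles=[], fiducials=pts,
        fiducial_intracellular=np.zeros(len(pts), dtype=bool),
        substrate_z=0.0, true_transform=Transform3D(),
    )


def _fm_volume(points, shape=(236, 236, 31), voxel=(34.0, 34.0, 100.0)):
    tpl = phantom.make_template(shape, voxel)
    return phantom.render_fm(_point_scene(points), tpl)["fiducial"]


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def test_fm_detection_localizes_all_fiducials_within_10nm():
    rng = np.random.default_rng(0)
    pts = np.column_stack(
        [rng.uniform(1000, 7000, 10), rng.uniform(1000, 7000, 10),
         rng.uniform(500, 2500, 10)]
    )
    det = reg.detect_fiducials_fm(_fm_volume(pts))
    assert len(det) == 10
    d, _ = cKDTree(det.points[:, :2]).query(pts[:, :2])
    assert np.all(d < 10.0)


def test_fm_detection_empty_channel_returns_empty_set():
    det = reg.detect_fiducials_fm(_fm_volume(np.empty((0, 3))))
    assert len(det) == 0


def test_fm_detection_merges_subresolution_pair():
    """Two emitters half a PSF width apart form a single intensity maximum
    and must be reported as one detection."""
    p = np.array([[3000.0, 3000.0, 1500.0], [3050.0, 3000.0, 1500.0]])
    det = reg.detect_fiducials_fm(_fm_volume(p))
    assert len(det) == 1


def _em_phantom(se=True):
    cfg = phantom.SceneConfig(
        fov_nm=(3000.0, 3000.0, 1500.0),
        n_lysosomes=1, lysosome_radius_nm=(300.0, 300.0),
        n_mitochondria=0, n_er_tubules=0,
        fiducials_per_lysosome=1, n_substrate_fiducials=2,
        true_theta_deg=0.0, true_translation_nm=(0.0, 0.0, 0.0),
    )
    scene = phantom.make_scene(cfg, seed=3)
    tpl = phantom.make_template(
        (310, 310, 170), (10.0, 10.0, 10.0), origin=(-50.0, -50.0, -100.0)
    )
    bse = phantom.render_em_volume(scene, tpl, check_bounds=False)
    se_vol = (
        phantom.render_em_volume(scene, tpl, detector="SE", check_bounds=False)
        if se else None
    )
    return scene, bse, se_vol


def test_em_detection_finds_fiducials_and_rejects_lysosome_lumen():
    scene, bse, se_vol = _em_phantom()
    det = reg.detect_fiducials_em(bse, se_vol)
    assert len(det) == len(scene.fiducials)
    d, _ = cKDTree(det.points).query(scene.fiducials)
    assert np.all(d <= 10.0 * np.sqrt(3))  # within one voxel
    # the dense lysosome lumen is brighter than resin but must not be
    # reported: its blob fails the core-size gate
    lyso_center = np.asarray(scene.organelles[0].center)
    d_lyso = np.linalg.norm(det.points - lyso_center, axis=1)
    fid_d = cKDTree(scene.fiducials).query(det.points)[0]
    assert np.all(fid_d < 50.0)


def test_em_detection_bse_only_matches_dual_channel():
    scene, bse, se_vol = _em_phantom()
    dual = reg.detect_fiducials_em(bse, se_vol)
    single = reg.detect_fiducials_em(bse)
    assert len(single) == len(dual)
    assert np.allclose(
        np.sort(single.points, axis=0), np.sort(dual.points, axis=0), atol=1e-9
    )


# ---------------------------------------------------------------------------
# rotation from MIPs
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fm_pair_7p3deg():
    rng = np.random.default_rng(0)
    pts = np.column_stack(
        [rng.uniform(1000, 7000, 8), rng.uniform(1000, 7000, 8),
         rng.uniform(500, 2500, 8)]
    )
    c = np.array([4000.0, 4000.0, 0.0])
    pts_b = Transform3D(theta_z=7.3).apply(pts - c) + c
    return _fm_volume(pts), _fm_volume(pts_b)


def test_mip_rotation_identity(fm_pair_7p3deg):
    va, _ = fm_pair_7p3deg
    theta, conf = reg.estimate_rotation_mip(va, va)
    assert abs(theta) < 0.05
    assert conf > 0.99


def test_mip_rotation_recovers_known_angle(fm_pair_7p3deg):
    va, vb = fm_pair_7p3deg
    theta, _ = reg.estimate_rotation_mip(va, vb)
    assert abs(theta - 7.3) < 0.2


def test_mip_rotation_two_point_pattern_is_ambiguous():
    p = np.array([[3000.0, 4000.0, 1000.0], [5000.0, 4000.0, 1000.0]])
    v = _fm_volume(p)
    with pytest.raises(RotationAmbiguousError):
        reg.estimate_rotation_mip(v, v)


# ---------------------------------------------------------------------------
# matching and fitting
# ---------------------------------------------------------------------------


@pytest.fixture()
def anchor_cloud():
    rng = np.random.default_rng(1)
    return rng.uniform([0, 0, 100], [8000, 8000, 3000], (10, 3))


def test_match_points_identity(anchor_cloud):
    a = reg.FiducialSet(anchor_cloud, np.ones(10), Modality.FM_confocal)
    b = reg.FiducialSet(anchor_cloud, np.ones(10), Modality.EM_BSE)
    pairs = reg.match_points(a, b, Transform3D(), tol_nm=100)
    assert sorted(pairs) == [(i, i) for i in range(10)]


def test_match_points_rejects_spurious_detections(anchor_cloud):
    T = Transform3D(theta_z=7.0, translation=(1500.0, -1200.0, 400.0))
    rng = np.random.default_rng(5)
    fm = np.vstack([anchor_cloud, rng.uniform(0, 8000, (2, 3))])
    em = np.vstack([T.apply(anchor_cloud), rng.uniform(-5000, 0, (2, 3))])
    a = reg.FiducialSet(fm, np.ones(12), Modality.FM_confocal)
    b = reg.FiducialSet(em, np.ones(12), Modality.EM_BSE)
    pairs = reg.match_points(a, b, T, tol_nm=200, seed=0)
    assert sorted(pairs) == [(i, i) for i in range(10)]


def test_match_points_two_point_sets_fail():
    pts = np.array([[0.0, 0.0, 0.0], [1000.0, 0.0, 0.0]])
    a = reg.FiducialSet(pts, np.ones(2), Modality.FM_confocal)
    b = reg.FiducialSet(pts, np.ones(2), Modality.EM_BSE)
    with pytest.raises(InsufficientCorrespondencesError):
        reg.match_points(a, b, Transform3D())


def test_coarse_match_finds_transform_without_init(anchor_cloud):
    T = Transform3D(theta_z=-9.0, translation=(2000.0, 800.0, -400.0))
    a = reg.FiducialSet(anchor_cloud, np.ones(10), Modality.FM_confocal)
    b = reg.FiducialSet(T.apply(anchor_cloud), np.ones(10), Modality.EM_BSE)
    init = reg.coarse_match_transform(a, b, tol_nm=200)
    resid = np.linalg.norm(init.apply(anchor_cloud) - b.points, axis=1)
    assert np.median(resid) < 200


def test_fit_transform_exact_recovery(anchor_cloud):
    T = Transform3D(theta_z=10.0, translation=(500.0, -300.0, 1200.0))
    T_fit, report = reg.fit_transform(anchor_cloud, T.apply(anchor_cloud))
    assert abs(T_fit.theta_z - 10.0) < 1e-6
    assert np.allclose(T_fit.translation, T.translation, atol=1e-3)
    assert report.fre_nm["total"] < 1e-6


def test_fit_transform_fre_matches_injected_noise():
    """Monte Carlo: per-axis FRE tracks the injected localization SDs."""
    rows = [
        transform_recovery_trial(s, noise_nm=(30.0, 30.0, 100.0))
        for s in range(100)
    ]
    fre_x = np.mean([r["fre_x_nm"] for r in rows])
    fre_z = np.mean([r["fre_z_nm"] for r in rows])
    assert abs(fre_x - 30.0) / 30.0 < 0.3
    assert abs(fre_z - 100.0) / 100.0 < 0.3


def test_fit_transform_zscale_model():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 5000, (8, 3))
    T = Transform3D(theta_z=4.0, translation=(100.0, 200.0, -300.0),
                    scale=(1.0, 1.0, 1.08))
    T_fit, _ = reg.fit_transform(pts, T.apply(pts), model="rigid_z+zscale")
    assert abs(T_fit.scale[2] - 1.08) < 1e-9


def test_fit_transform_degenerate_geometry():
    pts = np.tile([100.0, 200.0, 0.0], (5, 1))
    pts[:, 2] = np.arange(5) * 100.0  # all at one XY location
    with pytest.raises(DegenerateGeometryError):
        reg.fit_transform(pts, pts)
    line = np.zeros((5, 3))
    line[:, 0] = np.arange(5) * 500.0  # collinear in XY
    with pytest.raises(DegenerateGeometryError):
        reg.fit_transform(line, line)


def test_fit_transform_too_few_points():
    pts = np.random.default_rng(0).uniform(0, 100, (2, 3))
    with pytest.raises(InsufficientCorrespondencesError):
        reg.fit_transform(pts, pts)


# ---------------------------------------------------------------------------
# targeting
# ---------------------------------------------------------------------------


def test_blind_target_guard_rejects_anchor_reuse(anchor_cloud):
    T, report = reg.fit_transform(anchor_cloud, anchor_cloud)
    with pytest.raises(TargetNotHeldOutError):
        reg.assess_blind_target(
            anchor_cloud[0], anchor_cloud[0],
            fit_report=report, fm_point=anchor_cloud[0],
        )


def test_blind_target_zero_noise_is_voxel_limited():
    from clemtarget.experiments import BlindTargetSetup

    setup = BlindTargetSetup(fm_noise_nm=(0.0, 0.0, 0.0), em_grid_nm=10.0)
    r = blind_target_trial(3, setup)
    assert max(r["dx_nm"], r["dy_nm"], r["dz_nm"]) < 10.0


def test_tre_grows_with_localization_noise():
    """Median blind-target error increases monotonically over a 4-level
    localization-noise ladder (aggregated over seeds)."""
    from clemtarget.experiments import BlindTargetSetup

    medians = []
    for noise in (5.0, 20.0, 60.0, 150.0):
        setup = BlindTargetSetup(
            fm_noise_nm=(noise, noise, 2.0 * noise), match_tol_nm=450.0
        )
        errs = []
        for s in range(12):
            r = blind_target_trial(1000 + s, setup)
            errs.append((r["dx_nm"] + r["dy_nm"]) / 2.0)
        medians.append(float(np.median(errs)))
    assert medians == sorted(medians)


def test_blind_target_error_exceeds_fre_in_aggregate():
    """The error at a held-out target is statistically larger than the
    residual at the anchors (which the fit has partially absorbed)."""
    rows = [blind_target_trial(200 + s) for s in range(30)]
    rms_blind_z = np.sqrt(np.mean([r["dz_nm"] ** 2 for r in rows]))
    rms_fre_z = np.sqrt(np.mean([r["fre_z_nm"] ** 2 for r in rows]))
    assert rms_blind_z > rms_fre_z


def test_roi_box_point_target_arithmetic():
    box = reg.roi_box_for_target(
        Transform3D(),
        (np.zeros(3), np.zeros(3)),
        accuracy_nm=(100.0, 100.0, 350.0),
        k_margin=3.0,
    )
    assert np.allclose(box.size, (600.0, 600.0, 2100.0))


def test_roi_box_identity_transform_pads_fm_roi():
    lo, hi = np.array([100.0, 200.0, 300.0]), np.array([400.0, 600.0, 800.0])
    box = reg.roi_box_for_target(Transform3D(), (lo, hi), k_margin=2.0)
    assert np.allclose(box.lo, lo - 2.0 * np.array([100, 100, 350]))
    assert np.allclose(box.hi, hi + 2.0 * np.array([100, 100, 350]))


def test_roi_box_lysosome_scale():
    """A 560 nm organelle plus standard margins yields a micron-scale
    acquisition box, far below a full-cell volume."""
    lo = np.zeros(3)
    hi = np.full(3, 560.0)
    box = reg.roi_box_for_target(Transform3D(theta_z=7.0), (lo, hi))
    assert 1000.0 < box.size[0] < 2000.0
    assert box.volume_reduction((20_000.0, 20_000.0, 5_000.0)) < 0.01


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def test_resample_overlay_identity_concatenates_channels():
    rng = np.random.default_rng(0)
    from clemtarget.volume import ImageVolume

    fm_vol = ImageVolume(
        rng.uniform(0, 1, (20, 20, 10)), voxel_size=(50.0, 50.0, 100.0),
        modality=Modality.FM_confocal, channel_name="lyso",
    )
    em_vol = ImageVolume(
        rng.uniform(0, 1, (20, 20, 10)), voxel_size=(50.0, 50.0, 100.0),
        modality=Modality.EM_BSE, channel_name="EM",
    )
    roi = (np.zeros(3), np.array([19 * 50.0, 19 * 50.0, 9 * 100.0]))
    fused = reg.resample_overlay({"lyso": fm_vol}, em_vol, Transform3D(), roi)
    assert set(fused) == {"lyso", "EM"}
    assert np.allclose(fused["lyso"].values, fm_vol.values, atol=1e-9)
    assert np.allclose(fused["EM"].values, em_vol.values, atol=1e-9)


def test_resample_overlay_constant_channel_stays_constant():
    from clemtarget.volume import ImageVolume

    fm_vol = ImageVolume(
        np.full((30, 30, 12), 2.5), voxel_size=(50.0, 50.0, 100.0),
        origin=(-500.0, -500.0, -200.0), modality=Modality.FM_confocal,
    )
    em_vol = ImageVolume(
        np.zeros((40, 40, 20)), voxel_size=(25.0, 25.0, 50.0),
        modality=Modality.EM_BSE,
    )
    T = Transform3D(theta_z=5.0, translation=(100.0, 50.0, 25.0))
    roi = (np.full(3, 100.0), np.full(3, 500.0))
    fused = reg.resample_overlay({"c": fm_vol}, em_vol, T, roi)
    assert np.allclose(fused["c"].values, 2.5)


def test_resample_overlay_out_of_bounds_roi_fails():
    from clemtarget.volume import ImageVolume

    vol = ImageVolume(np.zeros((10, 10, 10)), voxel_size=(10.0, 10.0, 10.0))
    roi = (np.zeros(3), np.array([5000.0, 100.0, 100.0]))
    with pytest.raises(ValueError, match="outside"):
        reg.resample_overlay({"c": vol}, vol, Transform3D(), roi)


def test_fused_fiducial_channels_coincide():
    """A fiducial visible in both modalities lands on the same output
    voxel after fusion through the true transform."""
    T = Transform3D(theta_z=6.0, translation=(800.0, -500.0, 300.0))
    pos = np.array([2000.0, 2000.0, 1000.0])
    scene = phantom.Scene(
        organelles=[], fiducials=pos[None, :],
        fiducial_intracellular=np.array([False]),
        substrate_z=0.0, true_transform=T,
    )
    fm_tpl = phantom.make_template((118, 118, 31), (34.0, 34.0, 100.0))
    fm = phantom.render_fm(scene, fm_tpl)
    em_pos = T.apply(pos)
    em_tpl = phantom.make_template(
        (120, 120, 80), (20.0, 20.0, 20.0), origin=tuple(em_pos - 1000.0)
    )
    em = phantom.render_em_volume(scene, em_tpl, check_bounds=False)
    roi = (em_pos - 500.0, em_pos + 500.0)
    fused = reg.resample_overlay(fm, em, T, roi, voxel_size=(20.0, 20.0, 20.0))
    i_fm = np.unravel_index(
        np.argmax(fused["fiducial"].values), fused["fiducial"].values.shape
    )
    i_em = np.unravel_index(
        np.argmax(fused["EM"].values), fused["EM"].values.shape
    )
    assert np.all(np.abs(np.asarray(i_fm) - np.asarray(i_em)) <= 2)
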