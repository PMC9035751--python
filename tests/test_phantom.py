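"""Phantom generator: scenes, renders, tracks, against analytic oracles."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from clemtarget import phantom
from clemtarget.errors import PackingError, SceneBoundsError
from clemtarget.transform import Transform3D

# ---------------------------------------------------------------------------
# make_scene
# ---------------------------------------------------------------------------


def test_substrate_only_scene_rests_fiducials_on_glass():
    cfg = phantom.SceneConfig(
        n_lysosomes=0, n_mitochondria=0, n_er_tubules=0,
        n_substrate_fiducials=5,
    )
    scene = phantom.make_scene(cfg, seed=1)
    assert len(scene.fiducials) == 5
    # centre sits one particle radius (45 nm) above the substrate plane
    assert np.allclose(scene.fiducials[:, 2], scene.substrate_z + 45.0)
    assert not scene.fiducial_intracellular.any()


def test_make_scene_deterministic_per_seed():
    cfg = phantom.SceneConfig()
    a = phantom.make_scene(cfg, seed=7)
    b = phantom.make_scene(cfg, seed=7)
    assert np.array_equal(a.fiducials, b.fiducials)
    assert a.to_dict() == b.to_dict()
    c = phantom.make_scene(cfg, seed=8)
    assert not np.array_equal(a.fiducials, c.fiducials)


def test_intracellular_fiducials_contained_in_lysosomes():
    cfg = phantom.SceneConfig(
        n_lysosomes=3, lysosome_radius_nm=(300.0, 300.0),
        n_mitochondria=0, n_er_tubules=0,
        fiducials_per_lysosome=2, n_substrate_fiducials=0,
    )
    scene = phantom.make_scene(cfg, seed=3)
    lysos = [o for o in scene.organelles if o.cls == "lysosome"]
    assert len(scene.fiducials) == 6 and scene.fiducial_intracellular.all()
    for f in scene.fiducials:
        d = min(np.linalg.norm(f - np.asarray(o.center)) for o in lysos)
        assert d <= 300.0 - 45.0 + 1e-9


def test_infeasible_packing_raises():
    cfg = phantom.SceneConfig(
        fov_nm=(1200.0, 1200.0, 1200.0),
        n_lysosomes=30, lysosome_radius_nm=(400.0, 400.0),
        max_attempts=200,
    )
    with pytest.raises(PackingError):
        phantom.make_scene(cfg, seed=0)


# ---------------------------------------------------------------------------
# render_fm
# ---------------------------------------------------------------------------


def _point_scene(points, substrate_z=0.0):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return phantom.Scene(
        organelles=[],
        fiducials=pts,
        fiducial_intracellular=np.zeros(len(pts), dtype=bool),
        substrate_z=substrate_z,
        true_transform=Transform3D(),
    )


def test_fm_single_fiducial_argmax_and_psf_recovery():
    """A rendered spot peaks at its voxel and refits its own PSF widths."""
    tpl = phantom.make_template((41, 41, 21), (34.0, 34.0, 100.0))
    pos = np.array([20 * 34.0, 20 * 34.0, 10 * 100.0])  # exactly a voxel centre
    ch = phantom.render_fm(_point_scene(pos), tpl)
    fid = ch["fiducial"].values
    assert np.unravel_index(np.argmax(fid), fid.shape) == (20, 20, 10)

    xs, ys, zs = (ch["fiducial"].axis_coords(a) for a in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    def model(_, amp, x0, y0, z0, sxy, sz):
        return (
            amp
            * np.exp(
                -((X - x0) ** 2 + (Y - y0) ** 2) / (2 * sxy**2)
                - ((Z - z0) ** 2) / (2 * sz**2)
            )
        ).ravel()

    popt, _ = curve_fit(
        model, None, fid.ravel(), p0=[0.9, *(pos + 20.0), 80.0, 250.0]
    )
    assert abs(popt[4] - 100.0) / 100.0 < 0.05
    assert abs(popt[5] - 300.0) / 300.0 < 0.05


def test_fm_empty_fiducial_channel_is_pure_background():
    tpl = phantom.make_template((32, 32, 8), (34.0, 34.0, 100.0))
    noise = phantom.NoiseModel(gaussian_sd=0.02, offset=0.1)
    ch = phantom.render_fm(_point_scene(np.empty((0, 3))), tpl, noise=noise, seed=2)
    vals = ch["fiducial"].values
    se = 0.02 / np.sqrt(vals.size)
    assert abs(vals.mean() - 0.1) < 3 * se


def test_fm_subvoxel_z_centroid_between_planes():
    """A spot between two z planes splits its intensity; the centroid
    recovers the true axial position well below the 200 nm step."""
    tpl = phantom.make_template((41, 41, 16), (34.0, 34.0, 200.0))
    pos = np.array([20 * 34.0, 20 * 34.0, 7 * 200.0 + 80.0])
    ch = phantom.render_fm(_point_scene(pos), tpl)
    fid = ch["fiducial"].values
    zprofile = fid.sum(axis=(0, 1))
    zs = ch["fiducial"].axis_coords(2)
    centroid = float(np.sum(zs * zprofile) / np.sum(zprofile))
    assert abs(centroid - pos[2]) < 20.0


def test_fm_total_signal_proportional_to_fiducial_count():
    tpl = phantom.make_template((80, 80, 24), (50.0, 50.0, 150.0))
    rng = np.random.default_rng(4)
    # spots kept >4 sigma from every face so no PSF mass is clipped
    pts5 = rng.uniform([1500, 1500, 1300], [2500, 2500, 2200], (5, 3))
    s1 = phantom.render_fm(_point_scene(pts5[:1]), tpl)["fiducial"].values.sum()
    s5 = phantom.render_fm(_point_scene(pts5), tpl)["fiducial"].values.sum()
    assert abs(s5 / s1 - 5.0) < 0.05


def test_fm_rejects_scene_outside_template():
    tpl = phantom.make_template((10, 10, 5), (34.0, 34.0, 100.0))
    scene = phantom.Scene(
        organelles=[
            phantom.Organelle(
                label=1, cls="lysosome", kind="ellipsoid",
                center=(5000.0, 100.0, 100.0), radii=(80.0, 80.0, 80.0),
            )
        ],
        fiducials=np.empty((0, 3)),
        fiducial_intracellular=np.empty(0, dtype=bool),
        substrate_z=0.0,
        true_transform=Transform3D(),
    )
    with pytest.raises(SceneBoundsError, match="label=1"):
        phantom.render_fm(scene, tpl)


# ---------------------------------------------------------------------------
# render_fibsem / render_em_volume
# ---------------------------------------------------------------------------


def _tube_scene(theta=0.0, translation=(0.0, 0.0, 0.0)):
    """Content invariant along the milling axis (tubes parallel to y)."""
    orgs = [
        phantom.Organelle(
            label=1, cls="mitochondrion", kind="tube",
            path=np.array([[600.0, -1e4, 400.0], [600.0, 1e4, 400.0]]),
            radius=150.0,
        ),
        phantom.Organelle(
            label=2, cls="ER_tubule", kind="tube",
            path=np.array([[1100.0, -1e4, 750.0], [1100.0, 1e4, 750.0]]),
            radius=60.0,
        ),
    ]
    return phantom.Scene(
        organelles=orgs,
        fiducials=np.empty((0, 3)),
        fiducial_intracellular=np.empty(0, dtype=bool),
        substrate_z=0.0,
        true_transform=Transform3D(theta_z=theta, translation=translation),
    )


def test_fibsem_fiducial_core_at_transformed_position():
    T = Transform3D(theta_z=5.0, translation=(300.0, -200.0, 100.0))
    scene = phantom.Scene(
        organelles=[],
        fiducials=np.array([[900.0, 900.0, 500.0]]),
        fiducial_intracellular=np.array([False]),
        substrate_z=0.0,
        true_transform=T,
    )
    tpl = phantom.make_template(
        (200, 100, 100), (10.0, 20.0, 10.0), origin=(200.0, -400.0, 0.0),
        modality="EM_BSE", axis_order="XZY",
    )
    render = phantom.render_fibsem(scene, tpl, check_bounds=False)
    expected = T.apply(scene.fiducials[0])
    # frames are (y, z, x); the 30 nm core renders as a flat plateau at the
    # maximum, so compare its centroid (not an arbitrary argmax voxel)
    core = np.argwhere(render.bse.frames >= render.bse.frames.max())
    iy, iz, ix = core.mean(axis=0)
    found = np.array(
        [200.0 + ix * 10.0, -400.0 + iy * 20.0, 0.0 + iz * 10.0]
    )
    assert np.all(np.abs(found - expected) <= np.array([10.0, 20.0, 10.0]))


def _brute_force_integer_shift(ref, mov, max_shift=20):
    """Exhaustive integer x-shift maximizing normalized correlation."""
    best, best_score = 0, -np.inf
    w = ref.shape[1]
    for d in range(-max_shift, max_shift + 1):
        if d >= 0:
            a, b = ref[:, d:w], mov[:, 0 : w - d]
        else:
            a, b = ref[:, 0 : w + d], mov[:, -d:w]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        score = (a * b).sum() / denom if denom > 0 else -np.inf
        if score > best_score:
            best, best_score = d, score
    return best


def test_fibsem_recorded_jitter_matches_brute_force_oracle():
    """The injected jitter vector is exactly what exhaustive integer
    cross-correlation of adjacent noise-free slices recovers."""
    scene = _tube_scene()
    contrast = phantom.EmContrast(texture_amplitude=0.0)
    tpl = phantom.make_template(
        (180, 30, 100), (10.0, 10.0, 10.0), origin=(0.0, 0.0, -100.0),
        modality="EM_BSE", axis_order="XZY",
    )
    render = phantom.render_fibsem(
        scene, tpl, jitter_px=15, contrast=contrast, seed=7, check_bounds=False
    )
    jit = render.jitter_px
    for i in range(1, render.bse.n_slices):
        d = _brute_force_integer_shift(
            render.bse.frames[i - 1], render.bse.frames[i], max_shift=31
        )
        # d shifts the moving frame onto the reference, i.e. undoes the
        # jitter increment
        assert d == int(jit[i - 1] - jit[i])


def test_fibsem_jitter_exceeding_frame_width_rejected():
    scene = _tube_scene()
    tpl = phantom.make_template(
        (50, 10, 60), (10.0, 20.0, 10.0), origin=(0, 0, -100),
        modality="EM_BSE", axis_order="XZY",
    )
    with pytest.raises(ValueError, match="jitter"):
        phantom.render_fibsem(scene, tpl, jitter_px=60, check_bounds=False)


def test_em_volume_sphere_volume_within_3_percent():
    scene = phantom.Scene(
        organelles=[
            phantom.Organelle(
                label=1, cls="lysosome", kind="ellipsoid",
                center=(700.0, 700.0, 700.0), radii=(280.0, 280.0, 280.0),
            )
        ],
        fiducials=np.empty((0, 3)),
        fiducial_intracellular=np.empty(0, dtype=bool),
        substrate_z=0.0,
        true_transform=Transform3D(),
    )
    tpl = phantom.make_template((140, 140, 140), (10.0, 10.0, 10.0))
    em = phantom.render_em_volume(scene, tpl, check_bounds=False)
    mask = em.values > 0.6  # between resin (0.40) and organelle levels
    measured = mask.sum() * 10.0**3
    analytic = 4.0 / 3.0 * np.pi * 280.0**3
    assert abs(measured - analytic) / analytic < 0.03


def test_frame_separation_fm_untransformed_em_transformed():
    """The same fiducial localizes at p in FM and at T(p) in EM."""
    T = Transform3D(theta_z=10.0, translation=(500.0, 300.0, 200.0))
    pos = np.array([1000.0, 800.0, 600.0])
    scene = phantom.Scene(
        organelles=[], fiducials=pos[None, :],
        fiducial_intracellular=np.array([False]),
        substrate_z=0.0, true_transform=T,
    )
    fm_tpl = phantom.make_template((60, 60, 30), (34.0, 34.0, 100.0))
    fm = phantom.render_fm(scene, fm_tpl)["fiducial"]
    fm_peak = fm.index_to_world(
        np.unravel_index(np.argmax(fm.values), fm.values.shape)
    )[0]
    assert np.linalg.norm(fm_peak[:2] - pos[:2]) < 34.0

    em_tpl = phantom.make_template(
        (150, 150, 100), (20.0, 20.0, 20.0), origin=(500.0, 300.0, 0.0)
    )
    em = phantom.render_em_volume(scene, em_tpl, check_bounds=False)
    em_peak = em.index_to_world(
        np.unravel_index(np.argmax(em.values), em.values.shape)
    )[0]
    assert np.linalg.norm(em_peak - T.apply(pos)) < 2 * 20.0


# ---------------------------------------------------------------------------
# make_tracks
# ---------------------------------------------------------------------------


def test_stationary_track_has_zero_path():
    tr = phantom.make_tracks(phantom.Stationary(1.0, 2.0), n_frames=180)
    assert np.allclose(tr.xy_um, [1.0, 2.0])
    steps = np.linalg.norm(np.diff(tr.xy_um, axis=0), axis=1)
    assert steps.sum() == 0.0


def test_directed_track_arithmetic():
    tr = phantom.make_tracks(
        phantom.Directed(v_um_s=0.2, heading_deg=30.0), n_frames=180,
        frame_interval=1.0,
    )
    steps = np.linalg.norm(np.diff(tr.xy_um, axis=0), axis=1)
    assert np.allclose(steps, 0.2)
    assert np.isclose(steps.sum(), 35.8)
    assert np.isclose(np.linalg.norm(tr.xy_um[-1] - tr.xy_um[0]), 35.8)


def test_confined_brownian_mean_square_step():
    D, dt = 0.01, 1.0
    tr = phantom.make_tracks(
        phantom.ConfinedBrownian(d_um2_s=D, radius_um=50.0),
        n_frames=10_000, frame_interval=dt, seed=11,
    )
    msd_step = float(np.mean(np.sum(np.diff(tr.xy_um, axis=0) ** 2, axis=1)))
    assert abs(msd_step - 4 * D * dt) / (4 * D * dt) < 0.05


def test_confined_brownian_never_leaves_radius():
    tr = phantom.make_tracks(
        phantom.ConfinedBrownian(d_um2_s=0.05, radius_um=0.4),
        n_frames=2000, seed=3,
    )
    assert np.all(np.linalg.norm(tr.xy_um, axis=1) <= 0.4 + 1e-12)


@pytest.mark.parametrize(
    "model",
    [phantom.ConfinedBrownian(d_um2_s=-1.0), phantom.Directed(v_um_s=0.0)],
)
def test_invalid_motion_parameters_rejected(model):
    with pytest.raises(ValueError):
        phantom.make_tracks(model, n_frames=10)


def test_too_few_frames_rejected():
    with pytest.raises(ValueError):
        phantom.make_tracks(phantom.Stationary(), n_frames=1)
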