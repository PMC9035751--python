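"""Fiducial detection and FM-to-EM volume registration.

The registration chain mirrors a fiducial-anchored targeted volume-CLEM
workflow: gold-core/silica-shell nanoparticles are localized in the
fluorescence stack (sub-voxel 3D Gaussian refinement) and in the FIB-SEM
volume (BSE-bright core, optional SE shell check); a coarse in-plane
rotation is recovered from maximum-intensity projections; point
correspondences are established by mutual nearest neighbours plus RANSAC
over rigid z-rotation transforms; and the final transform is a
closed-form least-squares fit (z-restricted Procrustes in the plane,
independent z offset, optional z scale).  From the fitted transform the
module predicts target positions, evaluates blind-target accuracy (TRE)
and computes minimal EM acquisition boxes around FM-selected regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _rotate_image

from .errors import (
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    RotationAmbiguousError,
    TargetNotHeldOutError,
)
from .transform import Transform3D
from .volume import ImageVolume, Modality

__all__ = [
    "FiducialSet",
    "RegistrationReport",
    "TargetBox",
    "detect_fiducials_fm",
    "detect_fiducials_em",
    "estimate_rotation_mip",
    "coarse_match_transform",
    "match_points",
    "fit_transform",
    "resample_overlay",
    "predict_target",
    "assess_blind_target",
    "roi_box_for_target",
]


@dataclass
class FiducialSet:
    """Sub-voxel 3D fiducial localizations in a volume's world frame (nm)."""

    points: np.ndarray  # (n, 3)
    intensities: np.ndarray  # (n,)
    modality: Modality
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if self.confidence is None:
            self.confidence = np.full(len(self.points), np.nan)
        self.confidence = np.asarray(self.confidence, dtype=float).reshape(-1)
        if not (len(self.points) == len(self.intensities) == len(self.confidence)):
            raise ValueError("points, intensities and confidence must align")

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "x_nm": self.points[:, 0],
                "y_nm": self.points[:, 1],
                "z_nm": self.points[:, 2],
                "intensity": self.intensities,
                "confidence": self.confidence,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, modality: Modality) -> "FiducialSet":
        df = pd.read_csv(path)
        return cls(
            points=df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
            intensities=df["intensity"].to_numpy(),
            modality=modality,
            confidence=df.get("confidence", pd.Series(np.nan, index=df.index)).to_numpy(),
        )


@dataclass
class RegistrationReport:
    """Fit quality of a fiducial registration.

    ``fre_nm`` is the RMS residual at the anchor fiducials (per axis and
    total); ``tre_nm`` collects per-axis errors at named blind targets.
    """

    correspondences: list[tuple[int, int]]
    fre_nm: dict[str, float]
    n_inliers: int
    anchors_fm: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    anchors_em: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    tre_nm: dict[str, tuple[float, float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _gaussian3d(params, coords):
    amp, x0, y0, z0, sxy, sz, off = params
    x, y, z = coords
    return off + amp * np.exp(
        -((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sxy**2)
        - ((z - z0) ** 2) / (2.0 * sz**2)
    )


def detect_fiducials_fm(
    vol: ImageVolume,
    psf_sigma: tuple[float, float] = (100.0, 300.0),
    k_threshold: float = 8.0,
) -> FiducialSet:
    """Localize fluorescent fiducial spots in a confocal volume.

    Laplacian-of-Gaussian filtering at the fiducial scale proposes
    candidate voxels (local maxima above ``k_threshold`` robust standard
    deviations of the filtered volume); each candidate is refined by a
    3D Gaussian least-squares fit in a window of +-3 sigma, and
    detections closer than one lateral PSF width are merged (keeping the
    brighter).  Confidence is the fitted amplitude over the robust
    background SD.  An empty result is not an error.
    """
    if not vol.modality.is_fm:
        raise ValueError("detect_fiducials_fm requires an FM volume")
    tpl = vol.to_xyz()
    arr = np.asarray(tpl.values, dtype=float)
    vs = np.asarray(tpl.voxel_size)
    sxy, sz = psf_sigma
    sig_vox = np.array([sxy, sxy, sz]) / vs
    log = -ndimage.gaussian_laplace(arr, sig_vox)
    med = np.median(log)
    mad = np.median(np.abs(log - med))
    thr = med + k_threshold * 1.4826 * mad
    local_max = ndimage.maximum_filter(log, size=3) == log
    cand = np.argwhere(local_max & (log > thr) & (log > 0))

    bg_med = np.median(arr)
    bg_sd = 1.4826 * np.median(np.abs(arr - bg_med))
    half = np.maximum(np.rint(3.0 * sig_vox).astype(int), 2)
    hits: list[tuple[np.ndarray, float]] = []
    for idx in cand:
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, arr.shape)
        sub = arr[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        coords = np.meshgrid(
            *(tpl.axis_coords(a)[lo[a] : hi[a]] for a in range(3)), indexing="ij"
        )
        p0 = np.array(
            [
                max(arr[tuple(idx)] - bg_med, 1e-6),
                *tpl.index_to_world(idx)[0],
                sxy,
                sz,
                bg_med,
            ]
        )
        lo_w = [c.min() for c in coords]
        hi_w = [c.max() for c in coords]
        try:
            res = least_squares(
                lambda p: (_gaussian3d(p, coords) - sub).ravel(),
                p0,
                bounds=(
                    [0.0, lo_w[0], lo_w[1], lo_w[2], sxy / 4, sz / 4, -np.inf],
                    [np.inf, hi_w[0], hi_w[1], hi_w[2], sxy * 4, sz * 4, np.inf],
                ),
                max_nfev=200,
            )
        except Exception:  # fit divergence: drop candidate
            continue
        if not res.success and res.status <= 0:
            continue
        amp, x0, y0, z0 = res.x[0], res.x[1], res.x[2], res.x[3]
        hits.append((np.array([x0, y0, z0]), float(amp)))

    # merge duplicates within one lateral PSF width
    hits.sort(key=lambda h: -h[1])
    kept: list[tuple[np.ndarray, float]] = []
    for p, a in hits:
        if all(np.linalg.norm(p - q) > sxy for q, _ in kept):
            kept.append((p, a))
    if not kept:
        return FiducialSet(
            points=np.empty((0, 3)), intensities=np.empty(0), modality=tpl.modality
        )
    pts = np.array([p for p, _ in kept])
    amps = np.array([a for _, a in kept])
    conf = amps / bg_sd if bg_sd > 0 else np.full_like(amps, np.inf)
    return FiducialSet(points=pts, intensities=amps, modality=tpl.modality, confidence=conf)


def detect_fiducials_em(
    bse: ImageVolume,
    se: ImageVolume | None = None,
    min_contrast: float = 0.6,
    size_gate_nm: tuple[float, float] = (40.0, 80.0),
    shell_radius_nm: float = 45.0,
    core_radius_nm: float = 30.0,
    se_min_contrast: float = 0.3,
) -> FiducialSet:
    """Localize fiducial nanoparticles in a FIB-SEM volume.

    Gold cores backscatter far more strongly than any stained structure
    of comparable size, so candidates come from a white top-hat
    transform (image minus its grey opening with a structuring element
    just larger than the core): extended bright regions such as dense
    lysosomal lumina vanish, while core-sized peaks keep their full
    local contrast, which must exceed ``min_contrast`` (in the image's
    intensity units; the default separates gold from thin stained
    membranes, whose tangential caps also survive the opening but at
    much lower contrast).  Candidate blobs whose equivalent diameter is
    compatible with the ~60 nm core pass the size gate; when an SE
    volume is supplied, a coincident bright silica-shell annulus is
    additionally required.  The position is the intensity-weighted
    centre of mass of the core voxels.
    """
    tpl = bse.to_xyz()
    arr = np.asarray(tpl.values, dtype=float)
    vs = np.asarray(tpl.voxel_size)
    foot = tuple(
        int(np.ceil(2.0 * core_radius_nm / v)) + 2 for v in vs
    )
    tophat = arr - ndimage.grey_opening(arr, size=foot)
    mask = tophat > min_contrast
    if not mask.any():
        return FiducialSet(
            points=np.empty((0, 3)), intensities=np.empty(0), modality=tpl.modality
        )
    lab, n = ndimage.label(mask)
    voxel_vol = float(np.prod(vs))
    se_arr = se_med = se_mad = None
    if se is not None:
        se_arr = np.asarray(se.to_xyz().values, dtype=float)
        se_med = np.median(se_arr)
        se_mad = 1.4826 * np.median(np.abs(se_arr - se_med))
    pts, amps, conf = [], [], []
    bg = np.median(arr)
    for i in range(1, n + 1):
        sel = lab == i
        vol_nm3 = sel.sum() * voxel_vol
        eq_diam = (6.0 * vol_nm3 / np.pi) ** (1.0 / 3.0)
        if not (size_gate_nm[0] <= eq_diam <= size_gate_nm[1]):
            continue
        w = np.where(sel, arr - bg, 0.0)
        com_idx = np.array(ndimage.center_of_mass(w))
        p = tpl.index_to_world(com_idx)[0]
        if se_arr is not None:
            X, Y, Z = np.meshgrid(
                *(tpl.axis_coords(a) for a in range(3)), indexing="ij", sparse=True
            )
            d2 = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2
            annulus = (d2 > core_radius_nm**2) & (d2 <= shell_radius_nm**2)
            if not annulus.any():
                continue
            if se_arr[annulus].mean() <= se_med + max(3.0 * se_mad,
                                                      se_min_contrast):
                continue
        pts.append(p)
        amps.append(float(arr[sel].max()))
        conf.append(float((arr[sel].max() - bg) / (1.4826 * np.median(np.abs(arr - bg)) + 1e-12)))
    if not pts:
        return FiducialSet(
            points=np.empty((0, 3)), intensities=np.empty(0), modality=tpl.modality
        )
    return FiducialSet(
        points=np.array(pts),
        intensities=np.array(amps),
        modality=tpl.modality,
        confidence=np.array(conf),
    )


# ---------------------------------------------------------------------------
# rotation from maximum-intensity projections
# ---------------------------------------------------------------------------


def _mip_xy(vol: ImageVolume) -> tuple[np.ndarray, tuple[float, float]]:
    tpl = vol.to_xyz()
    mip = np.asarray(tpl.values, dtype=float).max(axis=2)  # (x, y)
    return mip, (tpl.voxel_size[0], tpl.voxel_size[1])


def _match_score(img_a: np.ndarray, img_b: np.ndarray, theta: float) -> float:
    """Correlation score of a rotated by ``theta`` (world CCW) against b.

    The translation is solved by phase correlation at the candidate
    angle; the score is the Pearson correlation of the shifted, rotated
    image with the target.
    """
    # values[x, y]: world CCW rotation == rotate(+theta) in skimage's
    # row/col convention with both axes transposed (sign checked in tests)
    rot = _rotate_image(img_a, theta, preserve_range=True, order=3)
    try:
        # plain (unnormalized) cross-correlation: robust for smooth,
        # sparse spot images where phase whitening amplifies noise
        shift, _, _ = phase_cross_correlation(
            img_b, rot, upsample_factor=10, normalization=None
        )
    except Exception:
        return -np.inf
    moved = ndimage.shift(rot, shift, order=3, mode="constant")
    a = moved - moved.mean()
    b = img_b - img_b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return -np.inf
    return float((a * b).sum() / denom)


def estimate_rotation_mip(
    fm_a: ImageVolume,
    fm_b: ImageVolume,
    angle_range: tuple[float, float] = (-20.0, 20.0),
    coarse_step: float = 1.0,
    fine_step: float = 0.1,
    ambiguity_ratio: float = 0.98,
) -> tuple[float, float]:
    """Recover the in-plane rotation between two stacks from their MIPs.

    Automated replacement for manual MIP registration on fiducial
    clusters: normalized phase-correlation response is maximized over an
    angle grid (coarse scan over ``angle_range``, then refinement at
    ``fine_step``); the translation is solved by phase correlation at
    each candidate angle.  Returns ``(theta_z_deg, confidence)`` where
    ``theta_z`` maps ``fm_a`` world coordinates onto ``fm_b``.

    Raises
    ------
    RotationAmbiguousError
        If the pattern is (near) 180-degree symmetric, i.e. the score at
        ``theta + 180`` rivals the best score; the caller must then
        supply the angle manually.
    """
    mip_a, ps_a = _mip_xy(fm_a)
    mip_b, ps_b = _mip_xy(fm_b)
    # resample to a common pixel size (the coarser of the two)
    from skimage.transform import rescale

    common = (max(ps_a[0], ps_b[0]), max(ps_a[1], ps_b[1]))
    if ps_a != common:
        mip_a = rescale(mip_a, (ps_a[0] / common[0], ps_a[1] / common[1]), order=1)
    if ps_b != common:
        mip_b = rescale(mip_b, (ps_b[0] / common[0], ps_b[1] / common[1]), order=1)
    # pad to equal shape
    shape = tuple(max(sa, sb) for sa, sb in zip(mip_a.shape, mip_b.shape))
    pad_a = [(0, s - c) for s, c in zip(shape, mip_a.shape)]
    pad_b = [(0, s - c) for s, c in zip(shape, mip_b.shape)]
    mip_a = np.pad(mip_a, pad_a)
    mip_b = np.pad(mip_b, pad_b)

    coarse = np.arange(angle_range[0], angle_range[1] + coarse_step / 2, coarse_step)
    scores = [_match_score(mip_a, mip_b, th) for th in coarse]
    best = coarse[int(np.argmax(scores))]
    fine = np.arange(best - coarse_step, best + coarse_step + fine_step / 2, fine_step)
    fscores = [_match_score(mip_a, mip_b, th) for th in fine]
    i_best = int(np.argmax(fscores))
    theta, score = float(fine[i_best]), float(fscores[i_best])
    if 0 < i_best < len(fine) - 1:
        y0, y1, y2 = fscores[i_best - 1], fscores[i_best], fscores[i_best + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # concave peak: parabolic sub-step refinement
            theta += 0.5 * (y0 - y2) / denom * fine_step
    opposite = _match_score(mip_a, mip_b, theta + 180.0)
    if score <= 0 or opposite >= ambiguity_ratio * score:
        raise RotationAmbiguousError(
            f"rotation ambiguous: score({theta:.2f}deg)={score:.3f} vs "
            f"score({theta + 180.0:.2f}deg)={opposite:.3f}; supply the angle manually"
        )
    return theta, score


# ---------------------------------------------------------------------------
# correspondence and transform fitting
# ---------------------------------------------------------------------------


def _fit_rigid_z(
    fm: np.ndarray, em: np.ndarray, z_scale: bool = False
) -> Transform3D:
    """Closed-form least-squares z-rotation + translation (+ z scale)."""
    fm = np.asarray(fm, dtype=float)
    em = np.asarray(em, dtype=float)
    fbar, ebar = fm.mean(axis=0), em.mean(axis=0)
    a = fm[:, :2] - fbar[:2]
    b = em[:, :2] - ebar[:2]
    num = float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]))
    den = float(np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]))
    theta = np.degrees(np.arctan2(num, den))
    if z_scale:
        az = fm[:, 2] - fbar[2]
        bz = em[:, 2] - ebar[2]
        denom = float(az @ az)
        sz = float(az @ bz) / denom if denom > 0 else 1.0
    else:
        sz = 1.0
    T_rot = Transform3D(theta_z=theta, scale=(1.0, 1.0, sz))
    t = ebar - T_rot.apply(fbar)
    return Transform3D(theta_z=theta, translation=tuple(t), scale=(1.0, 1.0, sz))


def fit_transform(
    fm_points: np.ndarray,
    em_points: np.ndarray,
    model: str = "rigid_z",
    correspondences: list[tuple[int, int]] | None = None,
) -> tuple[Transform3D, RegistrationReport]:
    """Fit the FM-to-EM transform to matched fiducial pairs.

    ``model`` is ``'rigid_z'`` (z-rotation + 3D translation; >= 3 pairs)
    or ``'rigid_z+zscale'`` (additionally a z scale absorbing FM axial
    calibration error; >= 4 pairs).  The in-plane part is a Procrustes
    fit restricted to z-rotation; the z offset (and scale) is an
    independent 1D least-squares fit.  Raises
    :class:`DegenerateGeometryError` when the anchors are collinear in
    XY and hence do not constrain the rotation direction reliably.
    """
    fm = np.asarray(fm_points, dtype=float).reshape(-1, 3)
    em = np.asarray(em_points, dtype=float).reshape(-1, 3)
    if fm.shape != em.shape:
        raise ValueError("fm_points and em_points must have matching shapes")
    z_scale = model == "rigid_z+zscale"
    if model not in ("rigid_z", "rigid_z+zscale"):
        raise ValueError(f"unknown model {model!r}")
    n_min = 4 if z_scale else 3
    if len(fm) < n_min:
        raise InsufficientCorrespondencesError(
            f"model {model} needs >= {n_min} correspondences, got {len(fm)}"
        )
    centered = fm[:, :2] - fm[:, :2].mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0 or sv[1] / sv[0] < 1e-9:
        raise DegenerateGeometryError(
            "anchor fiducials are collinear (or coincident) in XY; "
            "the in-plane rotation is unconstrained"
        )
    T = _fit_rigid_z(fm, em, z_scale=z_scale)
    res = T.apply(fm) - em
    fre = {
        "x": float(np.sqrt(np.mean(res[:, 0] ** 2))),
        "y": float(np.sqrt(np.mean(res[:, 1] ** 2))),
        "z": float(np.sqrt(np.mean(res[:, 2] ** 2))),
        "total": float(np.sqrt(np.mean(np.sum(res**2, axis=1)))),
    }
    report = RegistrationReport(
        correspondences=correspondences or [(i, i) for i in range(len(fm))],
        fre_nm=fre,
        n_inliers=len(fm),
        anchors_fm=fm,
        anchors_em=em,
    )
    return T, report


def coarse_match_transform(
    a: FiducialSet,
    b: FiducialSet,
    theta_range: tuple[float, float] = (-20.0, 20.0),
    theta_step: float = 0.5,
    tol_nm: float = 300.0,
) -> Transform3D:
    """Coarse FM-to-EM alignment directly on fiducial point clouds.

    For each candidate z-rotation, every point pair (one from each set)
    proposes a translation; the hypothesis matching the most points
    within ``tol_nm`` wins.  Complexity O(n_theta * |a| * |b|), intended
    for the few tens of fiducials typical of one field of view; the
    result seeds :func:`match_points`.
    """
    if len(a) < 3 or len(b) < 3:
        raise InsufficientCorrespondencesError(
            "need at least 3 points in each set for coarse alignment"
        )
    best: tuple[int, float, Transform3D] | None = None
    tree_b = cKDTree(b.points)
    for theta in np.arange(theta_range[0], theta_range[1] + theta_step / 2, theta_step):
        R = Transform3D(theta_z=float(theta))
        ra = R.apply(a.points)
        for i in range(len(a)):
            for j in range(len(b)):
                t = b.points[j] - ra[i]
                d, _ = tree_b.query(ra + t)
                score = int(np.sum(d <= tol_nm))
                cost = float(np.sum(d[d <= tol_nm]))
                if best is None or score > best[0] or (
                    score == best[0] and cost < best[1]
                ):
                    best = (
                        score,
                        cost,
                        Transform3D(theta_z=float(theta), translation=tuple(t)),
                    )
    assert best is not None
    if best[0] < 3:
        raise InsufficientCorrespondencesError(
            f"coarse alignment matched only {best[0]} points within {tol_nm} nm"
        )
    return best[2]


def match_points(
    a: FiducialSet,
    b: FiducialSet,
    init: Transform3D,
    tol_nm: float = 300.0,
    n_iter: int = 500,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Match fiducials of ``a`` to ``b`` under an approximate transform.

    Mutual-nearest-neighbour pairs within ``tol_nm`` of the initial
    transform seed a RANSAC search (3-point samples over rigid-z
    transforms, inlier band ``tol_nm``, ``n_iter`` iterations, seeded
    RNG); the largest consensus set is returned as index pairs into
    ``a`` and ``b``.  Robust to a minority of spurious detections on
    either side.
    """
    if len(a) < 3 or len(b) < 3:
        raise InsufficientCorrespondencesError(
            "need at least 3 points in each set to match"
        )
    pa = init.apply(a.points)
    pb = b.points
    tree_b = cKDTree(pb)
    tree_a = cKDTree(pa)
    d_ab, nn_ab = tree_b.query(pa)
    _, nn_ba = tree_a.query(pb)
    pairs = [
        (i, int(j))
        for i, (j, d) in enumerate(zip(nn_ab, d_ab))
        if d <= 5.0 * tol_nm and nn_ba[j] == i
    ]
    if len(pairs) < 3:
        raise InsufficientCorrespondencesError(
            f"only {len(pairs)} mutual-nearest-neighbour pairs under init"
        )
    rng = np.random.default_rng(seed)
    pairs_arr = np.asarray(pairs)
    fm_all = a.points[pairs_arr[:, 0]]
    em_all = pb[pairs_arr[:, 1]]
    best_inliers: np.ndarray | None = None
    for _ in range(n_iter):
        pick = rng.choice(len(pairs), size=3, replace=False)
        sub_fm, sub_em = fm_all[pick], em_all[pick]
        sv = np.linalg.svd(sub_fm[:, :2] - sub_fm[:, :2].mean(axis=0),
                           compute_uv=False)
        if sv[0] == 0 or sv[1] / sv[0] < 1e-6:
            continue
        T = _fit_rigid_z(sub_fm, sub_em)
        resid = np.linalg.norm(T.apply(fm_all) - em_all, axis=1)
        inl = resid < tol_nm
        if best_inliers is None or inl.sum() > best_inliers.sum():
            best_inliers = inl
    if best_inliers is None or best_inliers.sum() < 3:
        raise InsufficientCorrespondencesError(
            "RANSAC found fewer than 3 consistent correspondences"
        )
    return [tuple(p) for p in pairs_arr[best_inliers]]


# ---------------------------------------------------------------------------
# targeting and fusion
# ---------------------------------------------------------------------------


def predict_target(T: Transform3D, fm_point: np.ndarray) -> np.ndarray:
    """Predicted EM-frame position of an FM-frame point (nm)."""
    return T.apply(np.asarray(fm_point, dtype=float))


def assess_blind_target(
    predicted: np.ndarray,
    em_reference: np.ndarray,
    fit_report: RegistrationReport | None = None,
    fm_point: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Per-axis absolute targeting error (nm) at a held-out blind target.

    When the fit report and the FM-frame target position are supplied,
    guards the leave-one-out contract: the blind target must not be one
    of the anchors used in the fit.
    """
    if fit_report is not None and fm_point is not None and len(fit_report.anchors_fm):
        d = np.linalg.norm(fit_report.anchors_fm - np.asarray(fm_point), axis=1)
        if np.min(d) < 1.0:
            raise TargetNotHeldOutError(
                "target not held out: blind target coincides with a fit anchor"
            )
    err = np.abs(np.asarray(predicted, dtype=float) - np.asarray(em_reference, dtype=float))
    return float(err[0]), float(err[1]), float(err[2])


@dataclass
class TargetBox:
    """An EM acquisition box around a transformed FM ROI (nm)."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    @property
    def size(self) -> tuple[float, float, float]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def volume_reduction(self, full_box_nm: tuple[float, float, float]) -> float:
        """Acquisition-volume ratio vs. a stated full-cell box."""
        v = np.prod(self.size)
        return float(v / np.prod(full_box_nm))


def roi_box_for_target(
    T: Transform3D,
    fm_roi: tuple[np.ndarray, np.ndarray],
    accuracy_nm: tuple[float, float, float] = (100.0, 100.0, 350.0),
    k_margin: float = 3.0,
) -> TargetBox:
    """Minimal EM acquisition box covering an FM ROI with safety margins.

    The FM ROI corners are transformed to the EM frame, the axis-aligned
    hull is taken, and each axis is padded by ``k_margin`` times the
    per-axis registration accuracy.  This is what makes targeted
    acquisition cheap: only a micrometre-scale box around the organelle
    of interest needs to be milled and imaged.
    """
    if any(acc <= 0 for acc in accuracy_nm):
        raise ValueError("accuracy must be positive")
    lo, hi = (np.asarray(v, dtype=float) for v in fm_roi)
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
         for z in (lo[2], hi[2])]
    )
    tc = T.apply(corners)
    pad = k_margin * np.asarray(accuracy_nm)
    return TargetBox(lo=tuple(tc.min(axis=0) - pad), hi=tuple(tc.max(axis=0) + pad))


def resample_overlay(
    fm: dict[str, ImageVolume],
    em: ImageVolume,
    T: Transform3D,
    roi_box: tuple[np.ndarray, np.ndarray],
    voxel_size: tuple[float, float, float] | None = None,
) -> dict[str, ImageVolume]:
    """Fuse FM channels with the EM volume on a common EM-frame grid.

    The output grid spans ``roi_box`` (EM-frame nm) at ``voxel_size``
    (default: the EM voxel size).  FM channels are sampled through the
    inverse transform with trilinear interpolation; the EM volume is
    sampled on its own grid and appended as the final channel ``'EM'``.
    """
    em_x = em.to_xyz()
    vs = np.asarray(voxel_size if voxel_size is not None else em_x.voxel_size)
    lo, hi = (np.asarray(v, dtype=float) for v in roi_box)
    n = np.maximum(np.floor((hi - lo) / vs).astype(int) + 1, 1)
    axes = [lo[a] + np.arange(n[a]) * vs[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts_em = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    def _sample(vol: ImageVolume, pts: np.ndarray) -> np.ndarray:
        v = vol.to_xyz()
        idx = v.world_to_index(pts)
        lo_i, hi_i = idx.min(axis=0), idx.max(axis=0)
        shape = np.asarray(v.shape_xyz)
        if np.any(lo_i < -0.51) or np.any(hi_i > shape - 0.49):
            raise ValueError(
                f"roi extends outside volume '{v.channel_name}': fractional index "
                f"range {lo_i.round(2)}..{hi_i.round(2)} vs shape {tuple(shape)}"
            )
        return ndimage.map_coordinates(
            np.asarray(v.values, dtype=float), idx.T, order=1, mode="nearest"
        )

    pts_fm = T.inverse().apply(pts_em)
    out: dict[str, ImageVolume] = {}
    for name, vol in fm.items():
        vals = _sample(vol, pts_fm).reshape(tuple(n))
        out[name] = ImageVolume(
            values=vals,
            voxel_size=tuple(vs),
            axis_order="XYZ",
            origin=tuple(lo),
            modality=vol.modality,
            channel_name=name,
        )
    em_vals = _sample(em_x, pts_em).reshape(tuple(n))
    out["EM"] = ImageVolume(
        values=em_vals,
        voxel_size=tuple(vs),
        axis_order="XYZ",
        origin=tuple(lo),
        modality=em_x.modality,
        channel_name="EM",
    )
    return out
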