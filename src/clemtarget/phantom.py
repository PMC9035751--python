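"""Synthetic dual-modality phantom with known ground truth.

Generates scenes of parametric organelles (lysosomes, mitochondria, ER
tubules and sheets) above a glass substrate, decorated with ~90 nm
gold-core / silica-shell fiducial nanoparticles both inside lysosomal
compartments (emulating endocytic uptake, which distributes fiducials in
3D through the endo-lysosomal system) and resting on the substrate.  The
same scene is rendered into:

* multi-channel confocal fluorescence stacks (ER / lysosome / fiducial
  channels, anisotropic Gaussian PSF, Poisson + Gaussian noise), in the
  FM world frame, and
* FIB-SEM slice stacks (BSE and SE detectors) in the EM world frame,
  i.e. after applying the scene's ground-truth FM-to-EM transform, with
  per-slice lateral jitter and row drift injected and recorded.

EM contrast follows backscattered-electron imaging of heavy-metal
stained samples: stained membranes and dense lysosomal lumina are
bright, electron-lucent ER lumina dark, the fiducial gold core bright in
BSE and the silica shell bright in SE, and the glass substrate forms a
high-contrast horizontal boundary.

All renders are pure functions of (scene, geometry, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import PackingError, SceneBoundsError
from .stack_align import RawSemStack
from .transform import Transform3D
from .volume import ImageVolume, LabelVolume, Modality

__all__ = [
    "Organelle",
    "Scene",
    "Track",
    "SceneConfig",
    "NoiseModel",
    "EmContrast",
    "FibsemRender",
    "Stationary",
    "ConfinedBrownian",
    "Directed",
    "make_scene",
    "make_tracks",
    "make_template",
    "render_fm",
    "render_em_volume",
    "render_fibsem",
    "scene_labels",
]

#: organelle class -> segmentation class
SEGMENTATION_CLASS = {
    "lysosome": "lysosome",
    "mitochondrion": "mitochondrion",
    "ER_tubule": "ER",
    "ER_sheet": "ER",
}


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------


@dataclass
class Organelle:
    """Parametric organelle geometry in the FM world frame (nm).

    ``kind`` selects the primitive:

    * ``ellipsoid`` (lysosomes): ``center`` + ``radii``;
    * ``tube`` (mitochondria, ER tubules): capsule around the polyline
      ``path`` with ``radius``;
    * ``sheet`` (ER sheets): axis-aligned slab, ``center`` +
      half-extents ``radii``.

    ``membrane_nm`` is the thickness of the stained boundary layer.
    """

    label: int
    cls: str
    kind: str
    center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] | None = None
    path: np.ndarray | None = None
    radius: float | None = None
    membrane_nm: float = 20.0

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned (lo, hi) bounds in nm."""
        if self.kind == "ellipsoid" or self.kind == "sheet":
            c, r = np.asarray(self.center), np.asarray(self.radii)
            return c - r, c + r
        path = np.asarray(self.path)
        return path.min(axis=0) - self.radius, path.max(axis=0) + self.radius

    def masks(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(inside-whole-organelle, inside-lumen) masks for points (N, 3)."""
        mem = self.membrane_nm
        if self.kind == "ellipsoid":
            c, r = np.asarray(self.center), np.asarray(self.radii)
            d = pts - c
            total = np.sum((d / r) ** 2, axis=-1) <= 1.0
            r_in = np.maximum(r - mem, 1e-6)
            lumen = np.sum((d / r_in) ** 2, axis=-1) <= 1.0
            return total, lumen
        if self.kind == "tube":
            d = _dist_to_polyline(pts, np.asarray(self.path, dtype=float))
            return d <= self.radius, d <= max(self.radius - mem, 0.0)
        if self.kind == "sheet":
            c, r = np.asarray(self.center), np.asarray(self.radii)
            d = np.abs(pts - c)
            total = np.all(d <= r, axis=-1)
            lumen = np.all(d <= np.maximum(r - mem, 1e-6), axis=-1)
            return total, lumen
        raise ValueError(f"unknown organelle kind {self.kind!r}")


def _dist_to_polyline(pts: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Euclidean distance from points (..., 3) to a polyline (M, 3)."""
    flat = pts.reshape(-1, 3)
    best = np.full(flat.shape[0], np.inf)
    for a, b in zip(path[:-1], path[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            closest = a
        else:
            t = np.clip((flat - a) @ ab / denom, 0.0, 1.0)
            closest = a + t[:, None] * ab
        d = np.linalg.norm(flat - closest, axis=1)
        np.minimum(best, d, out=best)
    return best.reshape(pts.shape[:-1])


@dataclass
class Track:
    """A 2D time-lapse trajectory of one organelle.

    ``t_s`` in seconds (strictly increasing, constant interval),
    ``xy_um`` positions in micrometres.
    """

    t_s: np.ndarray
    xy_um: np.ndarray
    frame_interval: float
    organelle_label: int = 0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if self.t_s.ndim != 1 or self.xy_um.shape != (self.t_s.size, 2):
            raise ValueError("t_s must be (n,), xy_um must be (n, 2)")
        dt = np.diff(self.t_s)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if dt.size and np.any(np.abs(dt - self.frame_interval) > 1e-9):
            raise ValueError("frame interval must be constant within 1e-9 s")


@dataclass
class Scene:
    """Ground truth for one phantom: geometry, fiducials, transform, tracks."""

    organelles: list[Organelle]
    fiducials: np.ndarray  # (n, 3) nm, FM world frame
    fiducial_intracellular: np.ndarray  # (n,) bool
    substrate_z: float
    true_transform: Transform3D
    tracks: list[Track] = field(default_factory=list)
    fiducial_diameter: float = 90.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.fiducials = np.asarray(self.fiducials, dtype=float).reshape(-1, 3)
        self.fiducial_intracellular = np.asarray(
            self.fiducial_intracellular, dtype=bool
        ).reshape(-1)
        labels = [o.label for o in self.organelles]
        if len(set(labels)) != len(labels) or any(l <= 0 for l in labels):
            raise ValueError("organelle labels must be unique and > 0")

    @property
    def fiducial_radius(self) -> float:
        return self.fiducial_diameter / 2.0

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds of all scene content, FM frame, nm."""
        los, his = [], []
        for o in self.organelles:
            lo, hi = o.bbox()
            los.append(lo)
            his.append(hi)
        if self.fiducials.size:
            r = self.fiducial_radius
            los.append(self.fiducials.min(axis=0) - r)
            his.append(self.fiducials.max(axis=0) + r)
        if not los:
            z = self.substrate_z
            return np.array([0.0, 0.0, z]), np.array([0.0, 0.0, z])
        return np.min(los, axis=0), np.max(his, axis=0)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        orgs = []
        for o in self.organelles:
            d = asdict(o)
            if d["path"] is not None:
                d["path"] = np.asarray(d["path"]).tolist()
            orgs.append(d)
        return {
            "organelles": orgs,
            "fiducials_nm": self.fiducials.tolist(),
            "fiducial_intracellular": self.fiducial_intracellular.tolist(),
            "substrate_z_nm": self.substrate_z,
            "true_transform": self.true_transform.to_dict(),
            "fiducial_diameter_nm": self.fiducial_diameter,
            "rng_seed": self.rng_seed,
            "tracks": [
                {
                    "t_s": tr.t_s.tolist(),
                    "xy_um": tr.xy_um.tolist(),
                    "frame_interval": tr.frame_interval,
                    "organelle_label": tr.organelle_label,
                }
                for tr in self.tracks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        orgs = []
        for od in d["organelles"]:
            od = dict(od)
            if od.get("path") is not None:
                od["path"] = np.asarray(od["path"], dtype=float)
            if od.get("center") is not None:
                od["center"] = tuple(od["center"])
            if od.get("radii") is not None:
                od["radii"] = tuple(od["radii"])
            orgs.append(Organelle(**od))
        tracks = [
            Track(
                t_s=np.asarray(td["t_s"]),
                xy_um=np.asarray(td["xy_um"]),
                frame_interval=td["frame_interval"],
                organelle_label=td["organelle_label"],
            )
            for td in d.get("tracks", [])
        ]
        return cls(
            organelles=orgs,
            fiducials=np.asarray(d["fiducials_nm"], dtype=float).reshape(-1, 3),
            fiducial_intracellular=np.asarray(d["fiducial_intracellular"], dtype=bool),
            substrate_z=float(d["substrate_z_nm"]),
            true_transform=Transform3D.from_dict(d["true_transform"]),
            tracks=tracks,
            fiducial_diameter=float(d.get("fiducial_diameter_nm", 90.0)),
            rng_seed=int(d.get("rng_seed", 0)),
        )


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


@dataclass
class SceneConfig:
    """Parameters of :func:`make_scene`.  All lengths in nm.

    Defaults emulate a peripheral patch of a cultured cell: a few
    endo-lysosomes of 250-350 nm radius, a mitochondrion, ER tubules of
    ~60 nm radius, endocytosed fiducials inside the lysosomes and free
    fiducials on the glass, and a modest in-plane rotation plus a
    micrometre-scale offset between the FM and EM coordinate frames.
    """

    fov_nm: tuple[float, float, float] = (8000.0, 8000.0, 3000.0)
    substrate_z: float = 0.0
    n_lysosomes: int = 3
    lysosome_radius_nm: tuple[float, float] = (250.0, 350.0)
    n_mitochondria: int = 1
    mito_radius_nm: float = 150.0
    mito_length_nm: tuple[float, float] = (800.0, 1400.0)
    n_er_tubules: int = 2
    er_tubule_radius_nm: float = 60.0
    er_tubule_length_nm: tuple[float, float] = (1500.0, 2500.0)
    n_er_sheets: int = 0
    er_sheet_extent_nm: tuple[float, float, float] = (600.0, 600.0, 80.0)
    membrane_nm: float = 20.0
    fiducials_per_lysosome: int = 2
    n_substrate_fiducials: int = 5
    fiducial_diameter: float = 90.0
    true_theta_deg: float = 7.0
    true_translation_nm: tuple[float, float, float] = (1500.0, -1200.0, 400.0)
    max_attempts: int = 2000


def _bounding_radius(org: Organelle) -> tuple[np.ndarray, float]:
    lo, hi = org.bbox()
    c = (lo + hi) / 2.0
    return c, float(np.linalg.norm(hi - c))


def make_scene(config: SceneConfig | None = None, seed: int = 0) -> Scene:
    """Sample a ground-truth scene; deterministic for a fixed seed.

    Organelles are placed by bounded rejection sampling so that their
    bounding spheres do not overlap and everything lies above the
    substrate plane; an infeasible packing request raises
    :class:`PackingError` after ``config.max_attempts`` rejections.
    Intracellular fiducials are drawn uniformly inside lysosomes
    (mirroring endocytic uptake); substrate fiducials rest on the glass,
    i.e. centre at ``substrate_z + fiducial_radius``.
    """
    cfg = config or SceneConfig()
    if cfg.n_lysosomes < 0 or cfg.n_mitochondria < 0 or cfg.n_er_tubules < 0:
        raise ValueError("organelle counts must be >= 0")
    if any(v <= 0 for v in cfg.fov_nm):
        raise ValueError("field of view must be positive")
    rng = np.random.default_rng(seed)
    fx, fy, fz = cfg.fov_nm
    organelles: list[Organelle] = []
    placed: list[tuple[np.ndarray, float]] = []
    attempts = 0
    label = 1

    def try_place(org: Organelle) -> bool:
        nonlocal attempts
        c, r = _bounding_radius(org)
        lo, _ = org.bbox()
        if lo[2] < cfg.substrate_z:
            return False
        for pc, pr in placed:
            if np.linalg.norm(c - pc) < r + pr:
                return False
        placed.append((c, r))
        organelles.append(org)
        return True

    def sample_until(make_one) -> None:
        nonlocal attempts
        while True:
            attempts += 1
            if attempts > cfg.max_attempts:
                raise PackingError(
                    f"could not place organelles without overlap within "
                    f"{cfg.max_attempts} attempts; reduce counts or sizes"
                )
            if try_place(make_one()):
                return

    for _ in range(cfg.n_lysosomes):

        def make_lyso() -> Organelle:
            r = rng.uniform(*cfg.lysosome_radius_nm)
            c = (
                rng.uniform(r, fx - r),
                rng.uniform(r, fy - r),
                rng.uniform(cfg.substrate_z + r + 50.0, fz - r),
            )
            return Organelle(
                label=label, cls="lysosome", kind="ellipsoid",
                center=c, radii=(r, r, r), membrane_nm=cfg.membrane_nm,
            )

        sample_until(make_lyso)
        label += 1

    for _ in range(cfg.n_mitochondria):

        def make_mito() -> Organelle:
            length = rng.uniform(*cfg.mito_length_nm)
            r = cfg.mito_radius_nm
            c = np.array(
                [
                    rng.uniform(length / 2 + r, fx - length / 2 - r),
                    rng.uniform(length / 2 + r, fy - length / 2 - r),
                    rng.uniform(cfg.substrate_z + r + 50.0, fz - r),
                ]
            )
            phi = rng.uniform(0, 2 * np.pi)
            d = np.array([np.cos(phi), np.sin(phi), 0.0])
            path = np.stack([c - d * length / 2, c + d * length / 2])
            return Organelle(
                label=label, cls="mitochondrion", kind="tube",
                path=path, radius=r, membrane_nm=cfg.membrane_nm,
            )

        sample_until(make_mito)
        label += 1

    for _ in range(cfg.n_er_tubules):

        def make_er() -> Organelle:
            length = rng.uniform(*cfg.er_tubule_length_nm)
            r = cfg.er_tubule_radius_nm
            n_seg = 4
            start = np.array(
                [
                    rng.uniform(r + 100, fx - r - 100),
                    rng.uniform(r + 100, fy - r - 100),
                    rng.uniform(cfg.substrate_z + r + 100.0, fz - r - 100.0),
                ]
            )
            phi = rng.uniform(0, 2 * np.pi)
            d = np.array([np.cos(phi), np.sin(phi), 0.0])
            pts = [start]
            for _ in range(n_seg):
                wobble = rng.normal(0.0, 0.3, size=3)
                wobble[2] *= 0.3  # tubules run mostly in-plane
                step = d + wobble
                step /= np.linalg.norm(step)
                pts.append(pts[-1] + step * length / n_seg)
            path = np.clip(
                np.asarray(pts),
                [r, r, cfg.substrate_z + r + 10.0],
                [fx - r, fy - r, fz - r],
            )
            return Organelle(
                label=label, cls="ER_tubule", kind="tube",
                path=path, radius=r, membrane_nm=cfg.membrane_nm,
            )

        sample_until(make_er)
        label += 1

    for _ in range(cfg.n_er_sheets):

        def make_sheet() -> Organelle:
            ex, ey, ez = np.asarray(cfg.er_sheet_extent_nm) / 2.0
            c = (
                rng.uniform(ex, fx - ex),
                rng.uniform(ey, fy - ey),
                rng.uniform(cfg.substrate_z + ez + 50.0, fz - ez),
            )
            return Organelle(
                label=label, cls="ER_sheet", kind="sheet",
                center=c, radii=(ex, ey, ez), membrane_nm=cfg.membrane_nm,
            )

        sample_until(make_sheet)
        label += 1

    fid_r = cfg.fiducial_diameter / 2.0
    fids: list[np.ndarray] = []
    intra: list[bool] = []
    for org in organelles:
        if org.cls != "lysosome":
            continue
        r_max = min(org.radii) - fid_r
        for _ in range(cfg.fiducials_per_lysosome):
            while True:
                u = rng.uniform(-1.0, 1.0, size=3)
                if np.linalg.norm(u) <= 1.0:
                    break
            fids.append(np.asarray(org.center) + u * max(r_max, 0.0))
            intra.append(True)
    for _ in range(cfg.n_substrate_fiducials):
        fids.append(
            np.array(
                [
                    rng.uniform(fid_r, fx - fid_r),
                    rng.uniform(fid_r, fy - fid_r),
                    cfg.substrate_z + fid_r,
                ]
            )
        )
        intra.append(False)

    return Scene(
        organelles=organelles,
        fiducials=np.asarray(fids, dtype=float).reshape(-1, 3),
        fiducial_intracellular=np.asarray(intra, dtype=bool),
        substrate_z=cfg.substrate_z,
        true_transform=Transform3D(
            theta_z=cfg.true_theta_deg, translation=cfg.true_translation_nm
        ),
        fiducial_diameter=cfg.fiducial_diameter,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# track models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stationary:
    """Immobile organelle."""

    x_um: float = 0.0
    y_um: float = 0.0


@dataclass(frozen=True)
class ConfinedBrownian:
    """Brownian motion (diffusivity ``d_um2_s`` in um^2/s) confined to a disc."""

    d_um2_s: float
    radius_um: float = 1.0
    center_um: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class Directed:
    """Constant-velocity motion: ``v_um_s`` um/s along ``heading_deg``."""

    v_um_s: float
    heading_deg: float = 0.0
    start_um: tuple[float, float] = (0.0, 0.0)


def make_tracks(
    model: Stationary | ConfinedBrownian | Directed,
    n_frames: int,
    frame_interval: float = 1.0,
    seed: int = 0,
    organelle_label: int = 0,
) -> Track:
    """Simulate one 2D track under a motility model.

    The three models reproduce the phenotypes seen in live-cell imaging
    of lysosomes: stationary, Brownian motion in a confined region, and
    directed (motor-driven) transport at constant speed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    t = np.arange(n_frames) * frame_interval
    if isinstance(model, Stationary):
        xy = np.tile([model.x_um, model.y_um], (n_frames, 1)).astype(float)
    elif isinstance(model, Directed):
        if model.v_um_s <= 0:
            raise ValueError("directed velocity must be positive")
        h = math.radians(model.heading_deg)
        step = model.v_um_s * frame_interval * np.array([math.cos(h), math.sin(h)])
        xy = np.asarray(model.start_um) + np.arange(n_frames)[:, None] * step
    elif isinstance(model, ConfinedBrownian):
        if model.d_um2_s <= 0:
            raise ValueError("diffusivity must be positive")
        rng = np.random.default_rng(seed)
        sd = math.sqrt(2.0 * model.d_um2_s * frame_interval)
        c = np.asarray(model.center_um)
        xy = np.empty((n_frames, 2))
        xy[0] = c
        for i in range(1, n_frames):
            for _ in range(1000):
                cand = xy[i - 1] + rng.normal(0.0, sd, size=2)
                if np.linalg.norm(cand - c) <= model.radius_um:
                    break
            else:  # pathological confinement: fall back to the boundary
                v = xy[i - 1] - c
                cand = c + v / max(np.linalg.norm(v), 1e-12) * model.radius_um
            xy[i] = cand
    else:
        raise TypeError(f"unknown track model {model!r}")
    return Track(
        t_s=t, xy_um=xy, frame_interval=frame_interval, organelle_label=organelle_label
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise (photon budget per unit intensity) + Gaussian read
    noise + constant offset.  ``poisson_scale=None`` disables shot noise."""

    poisson_scale: float | None = None
    gaussian_sd: float = 0.0
    offset: float = 0.0

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(img, dtype=float)
        if self.poisson_scale:
            out = rng.poisson(np.clip(out, 0.0, None) * self.poisson_scale) / float(
                self.poisson_scale
            )
        out = out + self.offset
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return out


@dataclass(frozen=True)
class EmContrast:
    """Mean intensities of the EM render, arbitrary units in [0, 1]."""

    resin: float = 0.40
    glass: float = 0.08
    membrane: float = 0.80
    lysosome_lumen: float = 0.95
    mito_matrix: float = 0.60
    er_lumen: float = 0.18
    fiducial_core_bse: float = 1.60
    fiducial_shell_se: float = 0.95
    se_background: float = 0.30
    se_glass: float = 0.10
    se_membrane: float = 0.45
    #: split of the 90 nm particle: bright BSE core disc / SE shell annulus
    core_radius_nm: float = 30.0
    shell_radius_nm: float = 45.0
    #: cytoplasmic granularity (ribosomes, stain mottle): amplitude and
    #: correlation length of a world-anchored value-noise field added to
    #: the background class
    texture_amplitude: float = 0.05
    texture_scale_nm: float = 80.0
    #: width of the glass/resin transition (partial-volume blur of the
    #: substrate edge); enables sub-pixel substrate localization
    glass_edge_nm: float = 10.0


def make_template(
    shape_xyz: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    modality: Modality = Modality.FM_confocal,
    axis_order: str = "XYZ",
) -> ImageVolume:
    """Empty volume describing a render grid."""
    perm = {"XYZ": (0, 1, 2), "XZY": (0, 2, 1)}[axis_order]
    storage_shape = tuple(shape_xyz[p] for p in perm)
    return ImageVolume(
        values=np.zeros(storage_shape, dtype=float),
        voxel_size=voxel_size,
        axis_order=axis_order,
        origin=origin,
        modality=modality,
    )


def _check_fits(scene: Scene, vol: ImageVolume, frame: str) -> None:
    T = scene.true_transform
    lo_v = np.asarray(vol.origin) - np.asarray(vol.voxel_size) / 2.0
    hi_v = lo_v + np.asarray(vol.shape_xyz) * np.asarray(vol.voxel_size)
    for org in scene.organelles:
        lo, hi = org.bbox()
        if frame == "EM":
            corners = np.array(
                [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
                 for z in (lo[2], hi[2])]
            )
            tc = T.apply(corners)
            lo, hi = tc.min(axis=0), tc.max(axis=0)
        if np.any(lo < lo_v) or np.any(hi > hi_v):
            raise SceneBoundsError(
                f"organelle label={org.label} ({org.cls}) extends outside the "
                f"{frame} render grid"
            )


def _em_class_fields(
    scene: Scene, pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point class id, and fiducial core / shell masks, in the FM frame.

    Class ids: 0 background, 1 glass, 2 membrane, 3 lysosome lumen,
    4 mito matrix, 5 ER lumen.
    """
    cls_id = np.zeros(pts.shape[:-1], dtype=np.uint8)
    lumen_code = {"lysosome": 3, "mitochondrion": 4, "ER_tubule": 5, "ER_sheet": 5}
    for org in scene.organelles:
        total, lumen = org.masks(pts)
        cls_id[total & ~lumen] = 2
        cls_id[lumen] = lumen_code[org.cls]
    core = np.zeros(pts.shape[:-1], dtype=bool)
    shell = np.zeros(pts.shape[:-1], dtype=bool)
    return cls_id, core, shell


def _value_noise(pts: np.ndarray, scale_nm: float, seed: int) -> np.ndarray:
    """Deterministic smooth value noise in [-1, 1] over world points (..., 3).

    Trilinear interpolation of a hashed lattice with spacing
    ``scale_nm``; anchored to world coordinates so that renders sampled
    on shifted grids see a consistently shifted texture.
    """

    def _hash(i: np.ndarray, j: np.ndarray, k: np.ndarray) -> np.ndarray:
        v = np.sin(
            i * 12.9898 + j * 78.233 + k * 37.719 + seed * 0.6180339887
        ) * 43758.5453
        return 2.0 * (v - np.floor(v)) - 1.0

    g = pts / scale_nm
    i0 = np.floor(g).astype(np.int64)
    f = g - i0
    f = f * f * (3.0 - 2.0 * f)  # smoothstep fade
    out = np.zeros(pts.shape[:-1])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[..., 0] if dx else 1.0 - f[..., 0])
                    * (f[..., 1] if dy else 1.0 - f[..., 1])
                    * (f[..., 2] if dz else 1.0 - f[..., 2])
                )
                out += w * _hash(
                    i0[..., 0] + dx, i0[..., 1] + dy, i0[..., 2] + dz
                )
    return out


def _em_intensity_points(
    scene: Scene,
    pts_em: np.ndarray,
    contrast: EmContrast,
) -> tuple[np.ndarray, np.ndarray]:
    """(BSE, SE) intensities at EM-frame points (..., 3) nm, noise free."""
    T_inv = scene.true_transform.inverse()
    pts_fm = T_inv.apply(pts_em.reshape(-1, 3)).reshape(pts_em.shape)
    cls_id, _, _ = _em_class_fields(scene, pts_fm)
    c = contrast
    bse_lut = np.array(
        [c.resin, c.glass, c.membrane, c.lysosome_lumen, c.mito_matrix, c.er_lumen]
    )
    se_lut = np.array(
        [c.se_background, c.se_glass, c.se_membrane,
         c.se_background, c.se_background, c.se_background]
    )
    bse = bse_lut[cls_id]
    se = se_lut[cls_id]
    if c.texture_amplitude > 0:
        tex = _value_noise(pts_fm, c.texture_scale_nm, scene.rng_seed)
        bg = cls_id == 0
        bse = np.where(bg, bse + c.texture_amplitude * tex, bse)
        se = np.where(bg, se + 0.5 * c.texture_amplitude * tex, se)
    # glass substrate: linear partial-volume transition of finite width
    g = np.clip(
        (scene.substrate_z - pts_fm[..., 2]) / max(c.glass_edge_nm, 1e-9) + 0.5,
        0.0, 1.0,
    )
    bse = (1.0 - g) * bse + g * c.glass
    se = (1.0 - g) * se + g * c.se_glass
    # fiducials: bright gold core in BSE, bright silica shell in SE
    fid_em = scene.true_transform.apply(scene.fiducials)
    for f in np.atleast_2d(fid_em):
        d2 = np.sum((pts_em - f) ** 2, axis=-1)
        core = d2 <= c.core_radius_nm**2
        shell = (d2 <= c.shell_radius_nm**2) & ~core
        bse[core] = c.fiducial_core_bse
        se[shell] = c.fiducial_shell_se
    return bse, se


def render_em_volume(
    scene: Scene,
    template: ImageVolume,
    contrast: EmContrast | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    detector: str = "BSE",
    check_bounds: bool = True,
) -> ImageVolume:
    """Render the scene as a noise-free or noisy EM volume on an XYZ grid.

    The template grid lives in the EM world frame; the scene's ground
    truth transform is applied (scene geometry is mapped from the FM
    frame).  Used for segmentation and EM fiducial-detection phantoms
    where slice-by-slice acquisition artefacts are not under study.
    """
    contrast = contrast or EmContrast()
    tpl = template.to_xyz()
    if check_bounds:
        _check_fits(scene, tpl, frame="EM")
    xs = tpl.axis_coords(0)
    ys = tpl.axis_coords(1)
    zs = tpl.axis_coords(2)
    nx, ny, nz = tpl.shape_xyz
    out = np.empty((nx, ny, nz), dtype=float)
    for j, y in enumerate(ys):  # slice along y to bound memory
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        pts = np.stack([X, np.full_like(X, y), Z], axis=-1)
        bse, se = _em_intensity_points(scene, pts, contrast)
        out[:, j, :] = bse if detector == "BSE" else se
    if noise is not None:
        out = noise.apply(out, np.random.default_rng(seed))
    modality = Modality.EM_BSE if detector == "BSE" else Modality.EM_SE
    return tpl.like(out, modality=modality, channel_name=f"EM_{detector}")


@dataclass
class FibsemRender:
    """Raw slice stacks plus the injected ground-truth acquisition errors."""

    bse: RawSemStack
    se: RawSemStack
    jitter_px: np.ndarray
    drift_rows: np.ndarray


def render_fibsem(
    scene: Scene,
    template: ImageVolume,
    jitter_px: np.ndarray | int | None = None,
    drift_rows: np.ndarray | None = None,
    contrast: EmContrast | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    check_bounds: bool = True,
) -> FibsemRender:
    """Render raw FIB-SEM slice sequences (BSE and SE detectors).

    The template must be an XZY EM-frame grid (frames are X-Z images,
    the milling direction is Y).  ``jitter_px`` is either a per-slice
    lateral shift vector (pixels), an integer bound ``J`` for uniform
    integer jitter in ``[-J, J]``, or ``None``; ``drift_rows`` is an
    optional per-slice vertical drift in rows.  Both are injected by
    shifting the sampling grid (content-exact, no interpolation) and
    returned as ground truth.
    """
    contrast = contrast or EmContrast()
    if template.axis_order != "XZY":
        raise ValueError("FIB-SEM template must have axis_order 'XZY'")
    if check_bounds:
        _check_fits(scene, template, frame="EM")
    nx, ny, nz = template.shape_xyz
    rng = np.random.default_rng(seed)
    if jitter_px is None:
        jitter = np.zeros(ny)
    elif np.isscalar(jitter_px):
        if jitter_px >= nx:
            raise ValueError("requested jitter exceeds frame width")
        jitter = rng.integers(-int(jitter_px), int(jitter_px) + 1, size=ny).astype(
            float
        )
    else:
        jitter = np.asarray(jitter_px, dtype=float)
        if jitter.shape != (ny,):
            raise ValueError(f"jitter_px must have shape ({ny},)")
    if np.max(np.abs(jitter)) >= nx:
        raise ValueError("requested jitter exceeds frame width")
    drift = (
        np.zeros(ny) if drift_rows is None else np.asarray(drift_rows, dtype=float)
    )
    if drift.shape != (ny,):
        raise ValueError(f"drift_rows must have shape ({ny},)")

    dx, dy, dz = template.voxel_size
    ox, oy, oz = template.origin
    frames_bse = np.empty((ny, nz, nx), dtype=float)
    frames_se = np.empty((ny, nz, nx), dtype=float)
    cols = np.arange(nx)
    rows = np.arange(nz)
    for i in range(ny):
        x = ox + (cols - jitter[i]) * dx
        z = oz + (rows - drift[i]) * dz
        Zg, Xg = np.meshgrid(z, x, indexing="ij")
        pts = np.stack([Xg, np.full_like(Xg, oy + i * dy), Zg], axis=-1)
        bse, se = _em_intensity_points(scene, pts, contrast)
        frames_bse[i] = bse
        frames_se[i] = se
    if noise is not None:
        nrng = np.random.default_rng(seed + 1)
        frames_bse = noise.apply(frames_bse, nrng)
        frames_se = noise.apply(frames_se, nrng)
    common = dict(pixel_size=(dx, dz), slice_pitch=dy, origin=(ox, oy, oz))
    return FibsemRender(
        bse=RawSemStack(frames=frames_bse, detector="BSE", **common),
        se=RawSemStack(frames=frames_se, detector="SE", **common),
        jitter_px=jitter,
        drift_rows=drift,
    )


def render_fm(
    scene: Scene,
    template: ImageVolume,
    psf_sigma: tuple[float, float] = (100.0, 300.0),
    noise: NoiseModel | None = None,
    seed: int = 0,
    fiducial_amplitude: float = 1.0,
) -> dict[str, ImageVolume]:
    """Render confocal fluorescence channels in the FM world frame.

    Channels: ``ER`` (Sec61b-like membrane marker over ER tubules and
    sheets), ``lysosome`` (luminal stain), ``fiducial`` (point emitters).
    The PSF is an anisotropic 3D Gaussian with ``psf_sigma = (sxy, sz)``
    in nm; fiducial spots are rendered analytically at their sub-voxel
    positions, organelle channels are rasterized and blurred.  The
    ground-truth FM-to-EM transform is *not* applied.
    """
    if not template.modality.is_fm:
        raise ValueError("template modality must be FM_confocal or FM_integrated")
    sxy, sz = psf_sigma
    if sxy <= 0 or sz <= 0:
        raise ValueError("psf sigmas must be positive")
    tpl = template.to_xyz()
    _check_fits(scene, tpl, frame="FM")
    nx, ny, nz = tpl.shape_xyz
    dx, dy, dz = tpl.voxel_size
    xs, ys, zs = (tpl.axis_coords(a) for a in range(3))

    er = np.zeros((nx, ny, nz), dtype=float)
    lyso = np.zeros((nx, ny, nz), dtype=float)
    for org in scene.organelles:
        target = er if org.cls.startswith("ER") else (
            lyso if org.cls == "lysosome" else None
        )
        if target is None:
            continue
        lo, hi = org.bbox()
        sl = tuple(
            slice(
                int(np.clip(np.floor((l - o) / v), 0, n)),
                int(np.clip(np.ceil((h - o) / v) + 1, 0, n)),
            )
            for l, h, o, v, n in zip(
                lo, hi, tpl.origin, tpl.voxel_size, (nx, ny, nz)
            )
        )
        X, Y, Z = np.meshgrid(xs[sl[0]], ys[sl[1]], zs[sl[2]], indexing="ij")
        total, _ = org.masks(np.stack([X, Y, Z], axis=-1))
        target[sl] += total.astype(float)
    sig_vox = (sxy / dx, sxy / dy, sz / dz)
    er = ndimage.gaussian_filter(er, sig_vox)
    lyso = ndimage.gaussian_filter(lyso, sig_vox)

    fid = np.zeros((nx, ny, nz), dtype=float)
    half = (4.0 * sxy, 4.0 * sxy, 4.0 * sz)
    for p in np.atleast_2d(scene.fiducials):
        sl = tuple(
            slice(
                int(np.clip(np.floor((p[a] - half[a] - tpl.origin[a]) / tpl.voxel_size[a]), 0, n)),
                int(np.clip(np.ceil((p[a] + half[a] - tpl.origin[a]) / tpl.voxel_size[a]) + 1, 0, n)),
            )
            for a, n in zip(range(3), (nx, ny, nz))
        )
        X, Y, Z = np.meshgrid(xs[sl[0]], ys[sl[1]], zs[sl[2]], indexing="ij")
        fid[sl] += fiducial_amplitude * np.exp(
            -((X - p[0]) ** 2 + (Y - p[1]) ** 2) / (2.0 * sxy**2)
            - ((Z - p[2]) ** 2) / (2.0 * sz**2)
        )

    rng = np.random.default_rng(seed)
    out: dict[str, ImageVolume] = {}
    for name, arr in (("ER", er), ("lysosome", lyso), ("fiducial", fid)):
        vals = noise.apply(arr, rng) if noise is not None else arr
        out[name] = tpl.like(vals, channel_name=name)
    return out


def scene_labels(
    scene: Scene,
    template: ImageVolume,
    frame: str = "EM",
    collapse_er: bool = True,
    transform: Transform3D | None = None,
) -> LabelVolume:
    """Rasterize ground-truth organelle labels on a template grid.

    ``frame='EM'`` rasterizes in the EM world frame (the ground-truth
    transform applied), ``'FM'`` in the FM frame.  ``transform``
    overrides the FM-to-EM map, e.g. with a fitted transform when the
    template grid lives in an aligned acquisition frame rather than the
    nominal EM world frame.  With ``collapse_er`` the class map uses
    segmentation classes (ER tubules and sheets both map to ``'ER'``).
    """
    tpl = template.to_xyz()
    xs, ys, zs = (tpl.axis_coords(a) for a in range(3))
    nx, ny, nz = tpl.shape_xyz
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    T_inv = (transform or scene.true_transform).inverse()
    for j, y in enumerate(ys):
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        pts = np.stack([X, np.full_like(X, y), Z], axis=-1)
        if frame == "EM":
            pts = T_inv.apply(pts.reshape(-1, 3)).reshape(pts.shape)
        plane = np.zeros(X.shape, dtype=np.int32)
        for org in scene.organelles:
            total, _ = org.masks(pts)
            plane[total] = org.label
        labels[:, j, :] = plane
    class_map = {
        o.label: (SEGMENTATION_CLASS[o.cls] if collapse_er else o.cls)
        for o in scene.organelles
    }
    return LabelVolume(
        labels=labels,
        voxel_size=tpl.voxel_size,
        origin=tpl.origin,
        class_map=class_map,
    )
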