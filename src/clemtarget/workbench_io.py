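"""File formats, validated configuration and the end-to-end pipeline.

Volumes travel as OME-TIFF with voxel size in the OME pixel metadata
plus a JSON sidecar carrying the full grid description (origin, axis
order, modality); ground truth and reports are JSON; point sets, tracks
and per-frame shifts are CSV.  :func:`run_pipeline` chains
phantom -> stack alignment -> registration -> segmentation ->
quantification on a synthetic scene and writes a machine-readable
report with provenance (config hash, seeds, package versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__, phantom, quantify, registration, segmentation, stack_align
from .transform import Transform3D
from .volume import ImageVolume, LabelVolume, Modality

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "write_labels",
    "read_labels",
    "tracks_to_csv",
    "tracks_from_csv",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as OME-TIFF plus a JSON grid sidecar.

    Data are stored in ZYX page order with physical pixel sizes in the
    OME metadata; the sidecar preserves origin, axis order, modality and
    channel name exactly, so a round trip is bit-identical.
    """
    path = Path(path)
    v = vol.to_xyz()
    arr = np.transpose(np.asarray(v.values), (2, 1, 0))  # (z, y, x)
    dx, dy, dz = v.voxel_size
    tifffile.imwrite(
        path,
        arr,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": dx / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz / 1000.0,
            "PhysicalSizeZUnit": "µm",
        },
    )
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "voxel_size_nm": list(v.voxel_size),
                "origin_nm": list(v.origin),
                "axis_order": "XYZ",
                "modality": v.modality.value,
                "channel_name": v.channel_name,
            },
            indent=2,
        )
    )


def read_volume(path: str | Path) -> ImageVolume:
    """Read an OME-TIFF volume written by :func:`write_volume`.

    Voxel size must be recoverable from the sidecar or from the OME
    pixel metadata; otherwise the reader refuses the file and demands a
    sidecar rather than guessing physical units.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        ome = tf.ome_metadata
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel = tuple(meta["voxel_size_nm"])
        origin = tuple(meta.get("origin_nm", (0.0, 0.0, 0.0)))
        modality = Modality(meta.get("modality", "FM_confocal"))
        channel = meta.get("channel_name", "")
    elif ome is not None and "PhysicalSizeX" in ome:
        import re

        def _size(axis: str) -> float:
            m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome)
            if not m:
                raise ValueError(
                    f"missing PhysicalSize{axis} in OME metadata of {path}; "
                    "provide a JSON sidecar with voxel_size_nm"
                )
            return float(m.group(1)) * 1000.0  # µm -> nm

        voxel = (_size("X"), _size("Y"), _size("Z"))
        origin = (0.0, 0.0, 0.0)
        modality = Modality.FM_confocal
        channel = ""
    else:
        raise ValueError(
            f"no voxel-size metadata for {path}: provide a JSON sidecar "
            "(voxel_size_nm) next to the TIFF"
        )
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path}, got shape {arr.shape}")
    values = np.transpose(arr, (2, 1, 0))  # back to (x, y, z)
    return ImageVolume(
        values=values,
        voxel_size=voxel,
        axis_order="XYZ",
        origin=origin,
        modality=modality,
        channel_name=channel,
    )


def write_labels(lab: LabelVolume, path: str | Path) -> None:
    """Label volume as uint16 OME-TIFF + class map in the sidecar."""
    path = Path(path)
    if lab.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit uint16 storage")
    arr = np.transpose(lab.labels.astype(np.uint16), (2, 1, 0))
    tifffile.imwrite(path, arr, ome=True, metadata={"axes": "ZYX"})
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "voxel_size_nm": list(lab.voxel_size),
                "origin_nm": list(lab.origin),
                "class_map": {str(k): v for k, v in lab.class_map.items()},
            },
            indent=2,
        )
    )


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return LabelVolume(
        labels=np.transpose(arr, (2, 1, 0)).astype(np.int32),
        voxel_size=tuple(meta["voxel_size_nm"]),
        origin=tuple(meta.get("origin_nm", (0.0, 0.0, 0.0))),
        class_map={int(k): v for k, v in meta["class_map"].items()},
    )


def tracks_to_csv(tracks: list[phantom.Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for t, (x, y) in zip(tr.t_s, tr.xy_um):
            rows.append(
                {"t_s": t, "x_um": x, "y_um": y, "label": tr.organelle_label}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def tracks_from_csv(path: str | Path) -> list[phantom.Track]:
    df = pd.read_csv(path)
    out = []
    for label, g in df.groupby("label"):
        t = g["t_s"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        out.append(
            phantom.Track(
                t_s=t,
                xy_um=g[["x_um", "y_um"]].to_numpy(),
                frame_interval=dt,
                organelle_label=int(label),
            )
        )
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class PhantomStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fov_nm: tuple[float, float, float] = (4000.0, 4000.0, 1800.0)
    n_lysosomes: int = 2
    n_mitochondria: int = 1
    n_er_tubules: int = 1
    lysosome_radius_nm: tuple[float, float] = (250.0, 320.0)
    fiducials_per_lysosome: int = 3
    n_substrate_fiducials: int = 5
    true_theta_deg: float = 7.0
    true_translation_nm: tuple[float, float, float] = (1500.0, -1200.0, 400.0)
    #: confocal stack geometry: in-plane pixel / z-step, nm
    fm_voxel_nm: tuple[float, float, float] = (100.0, 100.0, 200.0)
    psf_sigma_nm: tuple[float, float] = (100.0, 300.0)
    fm_noise_sd: float = 0.01
    fm_photon_scale: float | None = 500.0
    #: raw FIB-SEM frame pixel (x, z) and milling pitch (y), nm
    em_pixel_nm: tuple[float, float] = (10.0, 10.0)
    em_slice_pitch_nm: float = 20.0
    em_noise_sd: float = 0.02
    jitter_max_px: int = 8
    em_margin_nm: float = 300.0


class AlignStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_shift_px: float = 40.0
    #: 'running_median' absorbs the smooth apparent drift that oblique
    #: structures induce in consecutive-slice correlations
    detrend: bool | str = "running_median"
    trend_window: int = 15
    #: analysis voxel after binning/interpolation, nm
    target_voxel_nm: tuple[float, float, float] = (20.0, 20.0, 20.0)


class RegisterStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: str = "rigid_z"
    match_tol_nm: float = 300.0
    ransac_iterations: int = 500
    theta_range_deg: tuple[float, float] = (-20.0, 20.0)
    accuracy_nm: tuple[float, float, float] = (100.0, 100.0, 350.0)
    k_margin: float = 3.0


class SegmentStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bunch_size: int = 10
    min_votes: int = 2
    dilation_px: int = 5
    class_order: tuple[str, ...] = ("lysosome", "mitochondrion", "ER")


class QuantifyStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gap_max_nm: float = 20.0
    extent_min_nm: float = 20.0
    contact_pairs: tuple[tuple[str, str], ...] = (
        ("lysosome", "ER"),
        ("lysosome", "mitochondrion"),
    )


class PipelineConfig(BaseModel):
    """Validated end-to-end configuration; unknown keys are rejected.

    ``seed`` is mandatory; per-stage seeds default to deterministic
    offsets of it so that every stochastic stage has an explicit seed in
    the resolved configuration.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int
    phantom_seed: int | None = None
    render_seed: int | None = None
    ransac_seed: int | None = None
    phantom: PhantomStageConfig = Field(default_factory=PhantomStageConfig)
    alignment: AlignStageConfig = Field(default_factory=AlignStageConfig)
    registration: RegisterStageConfig = Field(default_factory=RegisterStageConfig)
    segmentation: SegmentStageConfig = Field(default_factory=SegmentStageConfig)
    quantification: QuantifyStageConfig = Field(default_factory=QuantifyStageConfig)

    @model_validator(mode="after")
    def _derive_seeds(self) -> "PipelineConfig":
        if self.phantom_seed is None:
            self.phantom_seed = self.seed
        if self.render_seed is None:
            self.render_seed = self.seed + 1000
        if self.ransac_seed is None:
            self.ransac_seed = self.seed + 2000
        return self

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    s = int(a.sum()) + int(b.sum())
    return float(2.0 * np.sum(a & b) / s) if s else float("nan")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run phantom -> align -> register -> segment -> quantify.

    Writes all stage artifacts plus ``report.json`` into ``out_dir`` and
    returns the report.  Any stage failure aborts with the stage name;
    artifacts of completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {"clemtarget": __version__, "numpy": np.__version__},
        "stages": {},
    }
    stage = "phantom"
    try:
        # ---- phantom ---------------------------------------------------
        pc = config.phantom
        scene_cfg = phantom.SceneConfig(
            fov_nm=pc.fov_nm,
            n_lysosomes=pc.n_lysosomes,
            n_mitochondria=pc.n_mitochondria,
            n_er_tubules=pc.n_er_tubules,
            lysosome_radius_nm=pc.lysosome_radius_nm,
            fiducials_per_lysosome=pc.fiducials_per_lysosome,
            n_substrate_fiducials=pc.n_substrate_fiducials,
            true_theta_deg=pc.true_theta_deg,
            true_translation_nm=pc.true_translation_nm,
        )
        scene = phantom.make_scene(scene_cfg, seed=config.phantom_seed)
        for i, org in enumerate(scene.organelles):
            scene.tracks.append(
                phantom.make_tracks(
                    phantom.ConfinedBrownian(d_um2_s=0.005, radius_um=0.5),
                    n_frames=180,
                    seed=config.phantom_seed + 10 + i,
                    organelle_label=org.label,
                )
            )
        (out / "scene.json").write_text(json.dumps(scene.to_dict(), indent=2))
        tracks_to_csv(scene.tracks, out / "tracks.csv")

        # +1: voxel-centre convention, grid must cover the full field of view
        fm_shape = tuple(
            int(np.ceil(f / v)) + 1 for f, v in zip(pc.fov_nm, pc.fm_voxel_nm)
        )
        fm_tpl = phantom.make_template(fm_shape, pc.fm_voxel_nm)
        fm_noise = phantom.NoiseModel(
            poisson_scale=pc.fm_photon_scale, gaussian_sd=pc.fm_noise_sd
        )
        fm = phantom.render_fm(
            scene, fm_tpl, psf_sigma=pc.psf_sigma_nm,
            noise=fm_noise, seed=config.render_seed,
        )
        for name, vol in fm.items():
            write_volume(vol, out / f"fm_{name}.ome.tif")

        lo, hi = scene.bounds()
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
             for z in (lo[2], hi[2])]
        )
        tc = scene.true_transform.apply(corners)
        m = pc.em_margin_nm
        em_lo = tc.min(axis=0) - m
        em_hi = tc.max(axis=0) + m
        em_lo[2] = min(em_lo[2], scene.true_transform.apply((0.0, 0.0, scene.substrate_z))[2] - m)
        px, pz = pc.em_pixel_nm
        pitch = pc.em_slice_pitch_nm
        nx = int(np.ceil((em_hi[0] - em_lo[0]) / px))
        ny = int(np.ceil((em_hi[1] - em_lo[1]) / pitch))
        nz = int(np.ceil((em_hi[2] - em_lo[2]) / pz))
        em_tpl = phantom.make_template(
            (nx, ny, nz), (px, pitch, pz), origin=tuple(em_lo),
            modality=Modality.EM_BSE, axis_order="XZY",
        )
        render = phantom.render_fibsem(
            scene, em_tpl,
            jitter_px=pc.jitter_max_px,
            noise=phantom.NoiseModel(gaussian_sd=pc.em_noise_sd),
            seed=config.render_seed,
            check_bounds=False,
        )
        pd.DataFrame(
            {"frame": np.arange(len(render.jitter_px)),
             "jitter_px": render.jitter_px, "drift_rows": render.drift_rows}
        ).to_csv(out / "true_jitter.csv", index=False)
        report["stages"]["phantom"] = {
            "n_organelles": len(scene.organelles),
            "n_fiducials": int(len(scene.fiducials)),
            "em_stack_shape": list(render.bse.frames.shape),
        }

        # ---- stack alignment -------------------------------------------
        stage = "align"
        ac = config.alignment
        res_v = stack_align.align_vertical(render.bse)
        # correlate only above the substrate: the glass band is static
        # under lateral jitter and would pin the correlation at zero
        level = res_v.residual["substrate_level_row"]
        crop = (slice(int(np.ceil(level)) + 4, None), slice(None))
        res_l = stack_align.align_lateral(
            res_v.aligned, max_shift_px=ac.max_shift_px, detrend=ac.detrend,
            crop=crop, trend_window=ac.trend_window,
        )
        pd.DataFrame(
            {
                "frame": np.arange(render.bse.n_slices),
                "dy_px": res_v.shifts_px,
                "dx_px": res_l.shifts_px,
                "substrate_row": res_v.substrate_rows,
            }
        ).to_csv(out / "alignment_shifts.csv", index=False)
        em_vol = stack_align.reorder_to_xyz(res_l.aligned, ac.target_voxel_nm)
        # SE channel follows the BSE corrections
        se_stack = render.se
        se_aligned = stack_align.RawSemStack(
            frames=_apply_shifts(se_stack.frames, res_v.shifts_px, res_l.shifts_px),
            pixel_size=se_stack.pixel_size,
            slice_pitch=se_stack.slice_pitch,
            detector="SE",
            origin=res_l.aligned.origin,
        )
        se_vol = stack_align.reorder_to_xyz(se_aligned, ac.target_voxel_nm)
        write_volume(em_vol, out / "em_bse.ome.tif")
        write_volume(se_vol, out / "em_se.ome.tif")
        jit_err = _jitter_residual(
            res_l.shifts_px, render.jitter_px, trend_window=ac.trend_window
        )
        report["stages"]["align"] = {
            "n_frames": int(render.bse.n_slices),
            "vertical_fail_frames": res_v.residual["n_failed"],
            "lateral_jitter_residual_rms_px": jit_err,
        }

        # ---- registration ----------------------------------------------
        stage = "register"
        rc = config.registration
        fm_fids = registration.detect_fiducials_fm(
            fm["fiducial"], psf_sigma=pc.psf_sigma_nm
        )
        em_fids = registration.detect_fiducials_em(em_vol, se_vol)
        fm_fids.to_csv(out / "fiducials_fm.csv")
        em_fids.to_csv(out / "fiducials_em.csv")
        init = registration.coarse_match_transform(
            fm_fids, em_fids, theta_range=rc.theta_range_deg, tol_nm=rc.match_tol_nm
        )
        pairs = registration.match_points(
            fm_fids, em_fids, init,
            tol_nm=rc.match_tol_nm, n_iter=rc.ransac_iterations,
            seed=config.ransac_seed,
        )
        fm_m = fm_fids.points[[i for i, _ in pairs]]
        em_m = em_fids.points[[j for _, j in pairs]]
        # hold out the last matched pair as a blind target
        T, reg_report = registration.fit_transform(
            fm_m[:-1], em_m[:-1], model=rc.model
        )
        pred = registration.predict_target(T, fm_m[-1])
        tre = registration.assess_blind_target(
            pred, em_m[-1], fit_report=reg_report, fm_point=fm_m[-1]
        )
        T.save(out / "transform.json")
        true_T = scene.true_transform
        report["stages"]["register"] = {
            "n_fm_detections": len(fm_fids),
            "n_em_detections": len(em_fids),
            "n_matched": len(pairs),
            "fre_nm": reg_report.fre_nm,
            "blind_target_error_nm": {"x": tre[0], "y": tre[1], "z": tre[2]},
            "theta_error_deg": float(T.theta_z - true_T.theta_z),
            "translation_error_nm": [
                float(a - b)
                for a, b in zip(T.translation, true_T.translation)
            ],
        }

        # ---- segmentation ----------------------------------------------
        stage = "segment"
        sc = config.segmentation
        # rasterize ground truth through the *fitted* transform: the
        # aligned stack lives in a substrate-anchored frame whose offset
        # from the nominal EM world frame the fit has absorbed
        gt = phantom.scene_labels(scene, em_vol, transform=T)
        params = segmentation.SegmentationParams(
            bunch_size=sc.bunch_size, min_votes=sc.min_votes
        )
        book: dict[str, dict[str, list]] = {c: {} for c in sc.class_order}
        for ori in segmentation.ORIENTATIONS:
            prompts = segmentation.scripted_prompter(
                gt, ori, bunch_size=sc.bunch_size, dilation_px=sc.dilation_px
            )
            for cls, lst in prompts.items():
                book.setdefault(cls, {})[ori] = lst
        labels = segmentation.sequential_pipeline(
            em_vol, book, class_order=sc.class_order, params=params
        )
        write_labels(labels, out / "labels.ome.tif")
        dice = {
            cls: _dice(labels.class_mask(cls), gt.class_mask(cls))
            for cls in sc.class_order
        }
        report["stages"]["segment"] = {"dice_vs_ground_truth": dice}

        # ---- quantification --------------------------------------------
        stage = "quantify"
        qc = config.quantification
        track_rows = []
        for tr in scene.tracks:
            st = quantify.track_stats(tr)
            track_rows.append(
                {
                    "label": tr.organelle_label,
                    "avg_velocity_um_s": st.avg_velocity_um_s,
                    "path_length_um": st.path_length_um,
                    "net_displacement_um": st.net_displacement_um,
                }
            )
        pd.DataFrame(track_rows).to_csv(out / "track_stats.csv", index=False)
        morpho_rows = []
        for label in sorted(labels.class_map):
            mm = quantify.morphometrics(labels, label)
            morpho_rows.append(
                {
                    "label": label,
                    "class": labels.class_map[label],
                    "extent_x_um": mm.extents_um[0],
                    "extent_y_um": mm.extents_um[1],
                    "extent_z_um": mm.extents_um[2],
                    "volume_um3": mm.volume_um3,
                    "surface_area_um2": mm.surface_area_um2,
                    "sphericity": mm.sphericity,
                }
            )
        pd.DataFrame(morpho_rows).to_csv(out / "morphometrics.csv", index=False)
        contact_rows = []
        for cls_a, cls_b in qc.contact_pairs:
            for site in quantify.find_contacts(
                labels, cls_a, cls_b,
                gap_max_nm=qc.gap_max_nm, extent_min_nm=qc.extent_min_nm,
            ):
                contact_rows.append(
                    {
                        "class_a": cls_a,
                        "class_b": cls_b,
                        "label_a": site.label_pair[0],
                        "label_b": site.label_pair[1],
                        "contact_voxels": site.contact_voxels,
                        "area_um2": site.area_um2,
                        "min_gap_nm": site.min_gap_nm,
                        "extent_nm": site.extent_nm,
                    }
                )
        pd.DataFrame(
            contact_rows,
            columns=[
                "class_a", "class_b", "label_a", "label_b",
                "contact_voxels", "area_um2", "min_gap_nm", "extent_nm",
            ],
        ).to_csv(out / "contacts.csv", index=False)
        report["stages"]["quantify"] = {
            "n_tracks": len(track_rows),
            "n_organelles_measured": len(morpho_rows),
            "n_contact_sites": len(contact_rows),
        }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _apply_shifts(
    frames: np.ndarray, dy_px: np.ndarray, dx_px: np.ndarray
) -> np.ndarray:
    from scipy import ndimage as _ndi

    out = np.empty_like(frames)
    for i in range(frames.shape[0]):
        out[i] = _ndi.shift(
            frames[i], (dy_px[i], dx_px[i]), order=1, mode="nearest"
        )
    return out


def _jitter_residual(
    recovered: np.ndarray, injected: np.ndarray, trend_window: int = 15
) -> float:
    """RMS mismatch between recovered corrections and injected jitter.

    The correction should equal minus the jitter up to a smooth trend
    (unobservable from pairwise correlation, and deliberately removed by
    the aligner), so the comparison removes the same sliding-median
    trend before taking the RMS.
    """
    resid = recovered + injected
    resid = resid - stack_align.running_median(resid, trend_window | 1)
    return float(np.sqrt(np.mean(resid**2)))
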