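"""End-to-end orchestration: simulate -> beamform -> select -> ROI -> metrics -> stats.

A run is driven by a single config (YAML/JSON-loadable dict).  Synthetic
frames are generated per post-injection time point with a time-varying
signal amplitude, beamformed, filtered by mask overlap and duplicate
flags, quantified with ROI metrics, and compared across time points with
the nonparametric procedure.  Every run writes a manifest recording the
seed, a config hash, library versions, per-stage frame accounting
(frames in, retained, duplicate-excluded, ROI-failed), and output paths,
so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .acquisition import AcquisitionParams, ImageGrid
from .beamform import BeamformedImage, beamform_frame
from .metrics import compute_frame_metrics
from .roi import (
    RoiPlacementError,
    find_brightest_pixel,
    place_background_roi,
    place_target_roi,
    roi_size_px,
)
from .select import MaskPair, flag_stationary_duplicates, retain_frame
from .simulate import PhantomScene, make_phantom, make_truth_masks, simulate_channel_data
from .stats import compare_groups

__all__ = ["RunConfig", "run_pipeline", "render_overlay", "default_demo_config"]

log = logging.getLogger("pavis")


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic run."""

    output_dir: str
    seed: int = 0
    acquisition: dict = field(default_factory=dict)
    scene: dict = field(default_factory=dict)
    time_points: list = field(default_factory=list)
    beamform: dict = field(default_factory=dict)
    roi: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    save_frames: bool = False
    save_images: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_demo_config(output_dir: str, seed: int = 1) -> RunConfig:
    """Demo configuration: six post-injection time points with peak signal
    amplitude at 20--30 min, a reduced 128-element aperture, and per-time-
    point duplicate and off-target frames to exercise frame selection."""
    tps = []
    for minutes, amp in zip(
        (10, 20, 30, 60, 70, 80), (0.3, 1.0, 0.8, 0.5, 0.3, 0.55)
    ):
        tps.append(
            {
                "minutes": minutes,
                "n_frames": 5,
                "amplitude": amp,
                "n_duplicates": 1,
                "n_miss": 1,
            }
        )
    return RunConfig(
        output_dir=output_dir,
        seed=seed,
        acquisition={"n_elements": 128, "aperture_width_mm": 11.52, "n_samples": 832},
        scene={
            "lumen": {
                "center": [-2.0, 4.5],
                "half_widths": [2.2, 0.9],
                "shape": "ellipse",
                "n_absorbers": 80,
                "amplitude": 1.0,
            },
            "adventitia": {"n_absorbers": 10, "amplitude": 0.6, "thickness_mm": 0.15},
            "noise_sigma": 0.12,
        },
        time_points=tps,
        beamform={"dynamic_range_db": 30.0},
        roi={"lateral_mm": 3.0, "axial_mm": 0.6},
        selection={"iou_threshold": 0.95, "corr_threshold": 0.99, "min_overlap_px": 1},
        stats={"adjust": "none"},
    )


def _scale_scene(scene_cfg: dict, amplitude: float, seed: int, shift_mm: float = 0.0) -> dict:
    cfg = json.loads(json.dumps(scene_cfg))  # deep copy
    cfg["seed"] = seed
    if "lumen" in cfg and cfg["lumen"] is not None:
        cfg["lumen"]["amplitude"] = float(cfg["lumen"].get("amplitude", 1.0)) * amplitude
        if "adventitia" in cfg and cfg["adventitia"] is not None:
            cfg["adventitia"]["amplitude"] = (
                float(cfg["adventitia"].get("amplitude", 1.0)) * amplitude
            )
        if shift_mm:
            cfg["lumen"]["center"] = [
                float(cfg["lumen"]["center"][0]) + shift_mm,
                float(cfg["lumen"]["center"][1]),
            ]
    return cfg


def _frame_seeds(master_seed: int, n: int) -> list[int]:
    # independent per-frame streams, kept below 2^31
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the run manifest (also written to
    ``<output_dir>/manifest.json``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = AcquisitionParams(**config.acquisition)
    grid = ImageGrid.from_params(params)
    dr = float(config.beamform.get("dynamic_range_db", 30.0))
    bandpass = bool(config.beamform.get("bandpass", False))
    roi_lat = float(config.roi.get("lateral_mm", 3.0))
    roi_ax = float(config.roi.get("axial_mm", 0.6))
    h_px, w_px = roi_size_px(grid, roi_lat, roi_ax)
    if not config.time_points:
        raise ValueError("config has no time points")

    n_total = sum(
        int(tp["n_frames"]) + int(tp.get("n_duplicates", 0)) + int(tp.get("n_miss", 0))
        for tp in config.time_points
    )
    seeds = iter(_frame_seeds(config.seed, n_total))

    # ---- simulate + beamform -------------------------------------------
    images: list[BeamformedImage] = []
    masks: list[MaskPair] = []
    counts = {"frames_in": 0, "retained": 0, "duplicate_excluded": 0, "roi_failed": 0}
    for tp in config.time_points:
        minutes = float(tp["minutes"])
        amp = float(tp.get("amplitude", 1.0))
        produced: list[tuple[BeamformedImage, MaskPair]] = []
        for i in range(int(tp["n_frames"])):
            fid = f"t{minutes:g}_f{i}"
            scene = make_phantom(_scale_scene(config.scene, amp, next(seeds)), params)
            frame = simulate_channel_data(scene, params, minutes, fid)
            if config.save_frames:
                pio.write_frame_h5(frame, out / f"{fid}.h5")
            img = beamform_frame(frame, dr, grid, bandpass=bandpass)
            lumen, signal = make_truth_masks(scene, grid, params)
            produced.append((img, MaskPair(lumen, signal, grid, fid)))
        # stationary duplicates: exact copies appended after the last frame
        for i in range(int(tp.get("n_duplicates", 0))):
            src_img, src_masks = produced[-1]
            fid = f"t{minutes:g}_dup{i}"
            dup_img = BeamformedImage(
                rf=src_img.rf,
                envelope=src_img.envelope,
                bmode_db=src_img.bmode_db,
                grid=grid,
                dynamic_range_db=dr,
                time_point_min=minutes,
                frame_id=fid,
            )
            dup_masks = MaskPair(src_masks.ureter_mask, src_masks.signal_mask, grid, fid)
            produced.append((dup_img, dup_masks))
        # off-target frames: lumen (and its absorbers) shifted laterally so
        # the photoacoustic signal misses the segmented ureter position
        for i in range(int(tp.get("n_miss", 0))):
            fid = f"t{minutes:g}_miss{i}"
            s = next(seeds)
            base = make_phantom(_scale_scene(config.scene, amp, s), params)
            shifted = make_phantom(_scale_scene(config.scene, amp, s, shift_mm=5.0), params)
            frame = simulate_channel_data(shifted, params, minutes, fid)
            img = beamform_frame(frame, dr, grid, bandpass=bandpass)
            lumen, _ = make_truth_masks(base, grid, params)  # ureter where it should be
            _, signal = make_truth_masks(shifted, grid, params)  # signal elsewhere
            produced.append((img, MaskPair(lumen, signal, grid, fid)))
        for img, mp in produced:
            images.append(img)
            masks.append(mp)
    counts["frames_in"] = len(images)

    # ---- frame selection -----------------------------------------------
    sel = config.selection
    dup_flags = flag_stationary_duplicates(
        masks,
        [im.envelope for im in images],
        iou_threshold=float(sel.get("iou_threshold", 0.95)),
        corr_threshold=float(sel.get("corr_threshold", 0.99)),
        manual_exclusions=set(sel.get("manual_exclusions", [])),
    )
    min_overlap = int(sel.get("min_overlap_px", 1))
    retention_rows = []
    kept: list[int] = []
    for i, (img, mp) in enumerate(zip(images, masks)):
        ok, overlap = retain_frame(mp, min_overlap)
        retained = ok and not dup_flags[i]
        retention_rows.append(
            {
                "frame_id": mp.frame_id,
                "time_point_min": img.time_point_min,
                "retained": retained,
                "overlap_px": overlap,
                "duplicate_flag": dup_flags[i],
            }
        )
        if dup_flags[i]:
            counts["duplicate_excluded"] += 1
        if retained:
            kept.append(i)
    retention_df = pd.DataFrame(retention_rows)
    retention_path = out / "retention.csv"
    retention_df.to_csv(retention_path, index=False)

    # ---- ROI placement + metrics ---------------------------------------
    roi_rows, metric_rows = [], []
    for i in kept:
        img, mp = images[i], masks[i]
        search = mp.ureter_mask & mp.signal_mask
        try:
            bright = find_brightest_pixel(img.envelope, search)
            target = place_target_roi(mp.ureter_mask, bright, h_px, w_px)
            background = place_background_roi(
                target, img.envelope.shape, pitch_mm=params.pitch_mm
            )
        except (RoiPlacementError, ValueError) as exc:
            counts["roi_failed"] += 1
            log.warning("frame %s dropped: %s", mp.frame_id, exc)
            continue
        if config.save_images:
            pio.write_image_tiff(img.envelope, out / f"{mp.frame_id}.tiff", grid)
        rec = compute_frame_metrics(img, target, background)
        init_r, init_c = bright[0] - (h_px - 1) // 2, bright[1] - (w_px - 1) // 2
        for roi_obj in (target, background):
            roi_rows.append(
                {
                    "frame_id": mp.frame_id,
                    "roi_role": roi_obj.role,
                    "row0": roi_obj.row0,
                    "col0": roi_obj.col0,
                    "height_px": roi_obj.height_px,
                    "width_px": roi_obj.width_px,
                    "displacement_px": abs(roi_obj.row0 - init_r) + abs(roi_obj.col0 - init_c)
                    if roi_obj.role == "target"
                    else 0,
                }
            )
        metric_rows.append(
            {
                "frame_id": rec.frame_id,
                "time_point_min": rec.time_point_min,
                "contrast_db": rec.contrast_db,
                "snr": rec.snr,
                "gcnr": rec.gcnr,
                "target_row0": target.row0,
                "target_col0": target.col0,
                "background_row0": background.row0,
                "background_col0": background.col0,
            }
        )
    counts["retained"] = len(metric_rows)
    pd.DataFrame(roi_rows).to_csv(out / "rois.csv", index=False)
    metrics_df = pd.DataFrame(metric_rows)
    metrics_path = out / "metrics.csv"
    metrics_df.to_csv(metrics_path, index=False)

    # ---- group statistics ----------------------------------------------
    adjust = str(config.stats.get("adjust", "none"))
    reports = {}
    if not metrics_df.empty:
        for metric in ("contrast_db", "snr", "gcnr"):
            groups = {
                float(tp): g[metric].to_numpy()
                for tp, g in metrics_df.groupby("time_point_min")
                if len(g) >= 3  # too few retained frames for a group test
            }
            if len(groups) >= 2:
                reports[metric] = compare_groups(groups, metric, adjust=adjust).to_dict()
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(reports, indent=2, default=float))

    # ---- manifest -------------------------------------------------------
    from . import __version__

    cfg_dict = config.to_dict()
    manifest = {
        "pavis_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg_dict,
        "counts": counts,
        "outputs": {
            "retention": str(retention_path),
            "rois": str(out / "rois.csv"),
            "metrics": str(metrics_path),
            "stats": str(stats_path),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info(
        "pipeline done: %d frames in, %d retained, %d duplicates, %d ROI failures",
        counts["frames_in"], counts["retained"],
        counts["duplicate_excluded"], counts["roi_failed"],
    )
    return manifest


def render_overlay(
    bmode_db: np.ndarray,
    pa_db: np.ndarray,
    bmode_dynamic_range_db: float = 45.0,
    pa_dynamic_range_db: float = 30.0,
    pa_threshold_db: float | None = None,
    cmap: str = "hot",
) -> np.ndarray:
    """Color-mapped photoacoustic signal overlaid on a grayscale B-mode.

    Pixels of ``pa_db`` strictly above ``pa_threshold_db`` (default: the
    bottom of the photoacoustic dynamic range) are colored; all others
    show the B-mode underlay.  Returns an (H, W, 3) float RGB array.
    """
    from matplotlib import colormaps

    bmode_db = np.asarray(bmode_db, dtype=float)
    pa_db = np.asarray(pa_db, dtype=float)
    if bmode_db.shape != pa_db.shape:
        raise ValueError("B-mode and photoacoustic images must share the grid")
    if pa_threshold_db is None:
        pa_threshold_db = -pa_dynamic_range_db
    gray = np.clip(bmode_db + bmode_dynamic_range_db, 0, bmode_dynamic_range_db)
    gray /= bmode_dynamic_range_db
    rgb = np.repeat(gray[..., None], 3, axis=2)
    above = pa_db > pa_threshold_db
    pa_norm = np.clip((pa_db + pa_dynamic_range_db) / pa_dynamic_range_db, 0, 1)
    colors = colormaps[cmap](pa_norm)[..., :3]
    rgb[above] = colors[above]
    return rgb
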