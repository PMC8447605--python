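"""Readers, writers and the batch pipeline.

Scenes come in as one grayscale TIFF/PNG per channel (8- or 16-bit),
normalized to [0, 1] by the bit-depth maximum; ROI masks are images whose
nonzero pixels mark the analysis region. Batch runs are driven by a
manifest CSV (one scene per row) and emit a per-scene metrics CSV, a
condition-comparison CSV and a machine-readable run log. Runs are fully
deterministic: identical config, inputs and seed give byte-identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .assays import AssayCount, InvasionProfile, invasion_fraction, \
    recycling_timecourse
from .config import PipelineConfig
from .images import ChannelImage, ROIMask
from .metrics import METRIC_COLUMNS, compute_all_metrics
from .simulate import SceneGroundTruth
from .stats import stars, t_test

__all__ = [
    "load_channel", "load_scene", "load_mask", "save_scene",
    "run_pipeline", "RunError", "compare_conditions",
    "read_counts_csv", "write_counts_csv", "read_invasion_csv",
    "COMPARED_METRICS",
]


class RunError(RuntimeError):
    """Every manifest row failed (or the manifest was empty)."""


def _read_gray(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            f"{path} is RGB(A); split it into per-channel grayscale files")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D grayscale image, "
                         f"got shape {arr.shape}")
    return arr


def _normalize(arr: np.ndarray, path) -> tuple[np.ndarray, int]:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0, 16
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}; "
                     "expected uint8 or uint16 grayscale")


def load_channel(path, label: str = "other") -> ChannelImage:
    """Read one grayscale image and normalize by its bit-depth maximum."""
    arr = _read_gray(path)
    norm, depth = _normalize(arr, path)
    return ChannelImage(norm, label=label, source_bit_depth=depth)


def load_scene(paths, channel_map: Sequence[str]) -> list[ChannelImage]:
    """Load a scene from per-channel files or one multi-page TIFF.

    ``paths`` is either a sequence of file paths (one per channel) or a
    single multi-page TIFF path; ``channel_map`` assigns a label to each
    channel in order.
    """
    if isinstance(paths, (str, Path)):
        stack = tifffile.imread(paths)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"{paths}: expected a multi-page grayscale TIFF")
        if len(channel_map) != stack.shape[0]:
            if stack.shape[-1] in (3, 4):
                raise ValueError(
                    f"{paths} looks RGB(A); split it into per-channel "
                    "grayscale files")
            raise ValueError("channel_map length != number of pages")
        arrays = list(stack)
    else:
        if len(channel_map) != len(paths):
            raise ValueError("channel_map length != number of paths")
        arrays = [_read_gray(p) for p in paths]

    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"mixed channel dimensions: {sorted(shapes)}")
    out = []
    for arr, label in zip(arrays, channel_map):
        norm, depth = _normalize(arr, paths)
        out.append(ChannelImage(norm, label=label, source_bit_depth=depth))
    return out


def load_mask(path) -> ROIMask:
    """Nonzero pixels of a grayscale image become the ROI."""
    return ROIMask(_read_gray(path) != 0)


def save_scene(channels: Sequence[ChannelImage],
               truth: Optional[SceneGroundTruth], out_dir, stem: str
               ) -> dict[str, str]:
    """Write per-channel 8-bit TIFFs plus a ground-truth JSON sidecar.

    Returns a map from channel label to the written file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for ch in channels:
        p = out_dir / f"{stem}_{ch.label}.tif"
        tifffile.imwrite(p, np.round(ch.pixels * 255.0).astype(np.uint8))
        paths[ch.label] = str(p)
    if truth is not None:
        sidecar = out_dir / f"{stem}_truth.json"
        sidecar.write_text(json.dumps(truth.to_json_dict(), sort_keys=True,
                                      indent=1))
    return paths


# -------------------------------------------------------------- pipeline

#: metric columns compared between conditions
COMPARED_METRICS = ["f_r", "f_g", "f_f", "of_rg", "of_rf", "of_rfg",
                    "m1", "m2", "triple_m1", "triple_m2"]

_CHANNEL_PATH_COLUMNS = {"r_path": "R", "g_path": "G", "f_path": "F",
                         "nuclei_path": "nuclei"}


def compare_conditions(metrics: pd.DataFrame,
                       config: Optional[PipelineConfig] = None
                       ) -> pd.DataFrame:
    """Pairwise condition t tests for every compared metric column."""
    cfg = config or PipelineConfig()
    rows = []
    conditions = sorted(metrics["condition"].dropna().unique())
    for metric in COMPARED_METRICS:
        if metric not in metrics.columns:
            continue
        for i, ca in enumerate(conditions):
            for cb in conditions[i + 1:]:
                va = metrics.loc[metrics["condition"] == ca, metric].dropna()
                vb = metrics.loc[metrics["condition"] == cb, metric].dropna()
                if len(va) < 2 or len(vb) < 2:
                    continue
                cmp_ = t_test(va.to_numpy(), vb.to_numpy(),
                              variant=cfg.stats.variant, label_a=str(ca),
                              label_b=str(cb))
                rows.append({
                    "metric": metric, "group_a": cmp_.group_a,
                    "group_b": cmp_.group_b, "n_a": cmp_.n_a,
                    "n_b": cmp_.n_b, "median_a": cmp_.median_a,
                    "median_b": cmp_.median_b, "sd_a": cmp_.sd_a,
                    "sd_b": cmp_.sd_b, "t_stat": cmp_.t_stat,
                    "p_value": cmp_.p_value,
                    "stars": stars(cmp_.p_value, cfg.stats.star_thresholds),
                })
    return pd.DataFrame(rows, columns=[
        "metric", "group_a", "group_b", "n_a", "n_b", "median_a",
        "median_b", "sd_a", "sd_b", "t_stat", "p_value", "stars"])


def run_pipeline(config: PipelineConfig, manifest_csv, out_dir
                 ) -> dict[str, Path]:
    """Run the co-localization pipeline over a manifest of scenes.

    The manifest CSV needs ``scene_id`` and ``condition`` columns plus
    per-channel path columns (``r_path``, ``g_path``, optional ``f_path``,
    ``nuclei_path``); optional ``roi_path`` (nonzero-mask image; full frame
    when absent), ``roi_id`` and ``time_point_min``. A row whose images
    cannot be read is recorded as failed and the run continues; a run where
    every row fails raises :class:`RunError`.

    Writes ``metrics.csv``, ``comparisons.csv`` and ``run_log.json`` into
    ``out_dir`` and returns their paths.
    """
    config.validate()
    manifest = pd.read_csv(manifest_csv)
    if manifest.empty:
        raise RunError("manifest has no rows")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows, failures = [], []
    for _, rec in manifest.iterrows():
        scene_id = str(rec.get("scene_id", ""))
        try:
            channels = []
            for col, label in _CHANNEL_PATH_COLUMNS.items():
                p = rec.get(col)
                if isinstance(p, str) and p:
                    channels.append(load_channel(p, label=label))
            roi_path = rec.get("roi_path")
            if isinstance(roi_path, str) and roi_path:
                roi = load_mask(roi_path)
            else:
                roi = ROIMask.full(channels[0].shape)
            tp = rec.get("time_point_min")
            metrics = compute_all_metrics(
                channels, roi, config, scene_id=scene_id,
                roi_id=str(rec.get("roi_id", "") or ""),
                condition=str(rec.get("condition", "") or ""),
                time_point_min=float(tp) if pd.notna(tp) else None)
            rows.append(metrics.to_row())
        except Exception as exc:  # noqa: BLE001 — degrade per row
            failures.append({"scene_id": scene_id, "error": str(exc)})
    if not rows:
        raise RunError(f"all {len(failures)} manifest rows failed")

    metrics_df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    comparisons = compare_conditions(metrics_df, config)

    metrics_path = out_dir / "metrics.csv"
    comparisons_path = out_dir / "comparisons.csv"
    log_path = out_dir / "run_log.json"
    metrics_df.to_csv(metrics_path, index=False)
    comparisons.to_csv(comparisons_path, index=False)
    log = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "config": config.to_flat(),
        "n_scenes": len(rows),
        "failures": failures,
        "flags": {r["scene_id"]: r["flags"] for r in rows if r["flags"]},
    }
    log_path.write_text(json.dumps(log, sort_keys=True, indent=1))
    return {"metrics": metrics_path, "comparisons": comparisons_path,
            "log": log_path}


# ------------------------------------------------------------ assay tables

_COUNT_COLUMNS = ["scene_id", "condition", "time_point_min", "compartment",
                  "n_nuclei", "n_positive"]


def read_counts_csv(path) -> list[AssayCount]:
    df = pd.read_csv(path)
    missing = set(_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    return [AssayCount(scene_id=str(r.scene_id), condition=str(r.condition),
                       time_point_min=float(r.time_point_min),
                       compartment=str(r.compartment),
                       n_nuclei=int(r.n_nuclei),
                       n_positive=int(r.n_positive))
            for r in df.itertuples()]


def write_counts_csv(counts: Sequence[AssayCount], path) -> None:
    pd.DataFrame(
        [{c: getattr(a, c) for c in _COUNT_COLUMNS} for a in counts],
        columns=_COUNT_COLUMNS).to_csv(path, index=False)


def read_invasion_csv(path) -> list[InvasionProfile]:
    """Section table (insert_id, condition, depth_um, total_intensity)."""
    df = pd.read_csv(path)
    needed = {"insert_id", "condition", "depth_um", "total_intensity"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"invasion CSV missing columns: {sorted(missing)}")
    profiles = []
    for (insert_id, condition), grp in df.groupby(
            ["insert_id", "condition"], sort=True):
        grp = grp.sort_values("depth_um")
        profiles.append(InvasionProfile(
            insert_id=str(insert_id), condition=str(condition),
            sections=tuple(zip(grp["depth_um"].astype(float),
                               grp["total_intensity"].astype(float)))))
    return profiles
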