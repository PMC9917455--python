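"""On-disk formats: framesets as per-camera TIFF directories with JSON
sidecars, templates as JSON, detections/tracks as CSV, mosaics as TIFF."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .optics import ArrayConfig
from .simulate import RawFrameSet, SceneSpec
from .stitch import MosaicFrame

__all__ = [
    "write_frameset",
    "read_frameset",
    "write_mosaic",
    "detections_to_frame",
    "write_detections_csv",
    "read_detections_csv",
    "write_detections_coco",
]


def _cam_dir(key) -> str:
    return f"cam_r{key[0]:02d}_c{key[1]:02d}"


def write_frameset(frameset: RawFrameSet, outdir, seed: int | None = None) -> Path:
    """Write one frameset under ``outdir`` (appending to any session there).

    Layout: ``cam_rRR_cCC/frame_TTTTTT.tif`` per camera plus ``frameset.json``
    (array config, frame times, optional seed) and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = frameset.frame_index
    for key, img in frameset.frames.items():
        d = outdir / _cam_dir(key)
        d.mkdir(exist_ok=True)
        tifffile.imwrite(d / f"frame_{t:06d}.tif", img)
    meta_path = outdir / "frameset.json"
    meta = {"array_config": frameset.array_config.to_dict(), "frames": {}, "bayer_pattern": frameset.bayer_pattern}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    if seed is not None:
        meta["seed"] = int(seed)
    meta["frames"][str(t)] = {"timestamp_s": frameset.timestamp_s}
    meta_path.write_text(json.dumps(meta, indent=1))
    if frameset.ground_truth is not None:
        gt_path = outdir / "ground_truth.json"
        gt = json.loads(gt_path.read_text()) if gt_path.exists() else {}
        gt[str(t)] = frameset.ground_truth.to_dict()
        gt_path.write_text(json.dumps(gt, indent=1))
    return outdir


def read_frameset(directory, frame_index: int = 0) -> RawFrameSet:
    """Read one frameset written by :func:`write_frameset`."""
    directory = Path(directory)
    meta = json.loads((directory / "frameset.json").read_text())
    config = ArrayConfig.from_dict(meta["array_config"])
    frames = {}
    for d in sorted(directory.glob("cam_r*_c*")):
        r, c = int(d.name[5:7]), int(d.name[9:11])
        frames[(r, c)] = tifffile.imread(d / f"frame_{frame_index:06d}.tif")
    if not frames:
        raise FileNotFoundError(f"no camera frames for index {frame_index} in {directory}")
    gt = None
    gt_path = directory / "ground_truth.json"
    if gt_path.exists():
        gt_all = json.loads(gt_path.read_text())
        if str(frame_index) in gt_all:
            gt = SceneSpec.from_dict(gt_all[str(frame_index)])
    ts = meta.get("frames", {}).get(str(frame_index), {}).get("timestamp_s", 0.0)
    return RawFrameSet(
        frames=frames,
        array_config=config,
        frame_index=frame_index,
        bayer_pattern=meta.get("bayer_pattern", "none"),
        ground_truth=gt,
        timestamp_s=ts,
    )


def write_mosaic(mosaic: MosaicFrame, path, bit_depth: int = 8) -> None:
    """Write a mosaic as (Big)TIFF with a µm-per-pixel resolution tag."""
    img = np.asarray(mosaic.image)
    full = (1 << bit_depth) - 1
    arr = np.clip(np.round(img), 0, full).astype(np.uint8 if bit_depth == 8 else np.uint16)
    px_per_cm = 1e4 / mosaic.scale_um_per_px
    tifffile.imwrite(
        path,
        arr,
        bigtiff=arr.nbytes > 2**31,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"um_per_px": mosaic.scale_um_per_px, "origin_mm": list(mosaic.origin_mm)},
    )


def detections_to_frame(detections) -> pd.DataFrame:
    rows = [
        {
            "frame": d.frame_index,
            "label": d.label,
            "x0": d.box_px[0],
            "y0": d.box_px[1],
            "x1": d.box_px[2],
            "y1": d.box_px[3],
            "score": d.score,
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=["frame", "label", "x0", "y0", "x1", "y1", "score"])


def write_detections_csv(detections, path) -> None:
    detections_to_frame(detections).to_csv(path, index=False)


def read_detections_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_detections_coco(detections, path, mosaic_shape_px=(0, 0)) -> None:
    """COCO-style JSON: one image per frame index, xywh boxes, score field."""
    frames = sorted({d.frame_index for d in detections})
    labels = sorted({d.label for d in detections})
    cat_id = {lb: i + 1 for i, lb in enumerate(labels)}
    out = {
        "images": [
            {"id": t, "file_name": f"frame_{t:06d}", "width": mosaic_shape_px[0], "height": mosaic_shape_px[1]}
            for t in frames
        ],
        "categories": [{"id": i, "name": lb} for lb, i in cat_id.items()],
        "annotations": [
            {
                "id": k,
                "image_id": d.frame_index,
                "category_id": cat_id[d.label],
                "bbox": [d.box_px[0], d.box_px[1], d.box_px[2] - d.box_px[0], d.box_px[3] - d.box_px[1]],
                "score": d.score,
            }
            for k, d in enumerate(detections)
        ],
    }
    Path(path).write_text(json.dumps(out, indent=1))
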