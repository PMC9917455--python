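"""Object detection over arbitrarily large mosaics.

Any per-tile detector satisfying the contract ``tile_image -> (boxes,
scores[, labels])`` (boxes in tile coordinates) is run over an overlapping
tile plan; boxes are lifted to global mosaic coordinates and de-duplicated by
cross-tile greedy non-max suppression (NMS).  A classical
difference-of-Gaussians blob detector is provided as the reference detector
so the pipeline is testable at desk scale without a trained network, and an
occluder-augmentation utility composes training images with controlled
overlap.

Boxes are axis-aligned, half-open ``(x0, y0, x1, y1)`` in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "TilePlan",
    "Detection",
    "plan_tiles",
    "iou_matrix",
    "nms",
    "detect_tiled",
    "reference_blob_detector",
    "BlobDetector",
    "occluder_augment",
]


@dataclass
class Detection:
    box_px: tuple[float, float, float, float]
    score: float
    label: str = "organism"
    frame_index: int = 0
    source_tile: tuple[int, int] | None = None

    def __post_init__(self):
        x0, y0, x1, y1 = self.box_px
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate box {self.box_px}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box_px
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class TilePlan:
    tile_px: tuple[int, int]
    stride_px: tuple[int, int]
    tiles: list[tuple[int, int]] = field(default_factory=list)
    mosaic_shape_px: tuple[int, int] = (0, 0)


def _axis_origins(extent: int, tile: int, stride: int) -> list[int]:
    if tile >= extent:
        return [0]
    origins = []
    x = 0
    while x + tile < extent:
        origins.append(x)
        x += stride
    last = extent - tile
    if not origins or origins[-1] != last:
        origins.append(last)
    return origins


def plan_tiles(mosaic_shape_px: tuple[int, int], tile_px=1024, stride_px=None) -> TilePlan:
    """Plan a covering grid of (possibly overlapping) tiles.

    ``mosaic_shape_px`` is (width, height).  Origins advance in stride steps;
    the final row/column is clamped so tiles end exactly at the mosaic edge,
    guaranteeing complete coverage.
    """
    if isinstance(tile_px, int):
        tile_px = (tile_px, tile_px)
    if stride_px is None:
        stride_px = (max(tile_px[0] - 300, 1), max(tile_px[1] - 300, 1))
    if isinstance(stride_px, int):
        stride_px = (stride_px, stride_px)
    mw, mh = mosaic_shape_px
    tw, th = tile_px
    sx, sy = stride_px
    if tw <= 0 or th <= 0 or sx <= 0 or sy <= 0:
        raise ValueError("tile and stride must be positive")
    if sx > tw or sy > th:
        raise ValueError("stride must not exceed tile size")
    xs = _axis_origins(mw, min(tw, mw), sx)
    ys = _axis_origins(mh, min(th, mh), sy)
    tiles = [(x, y) for y in ys for x in xs]
    return TilePlan(
        tile_px=(min(tw, mw), min(th, mh)),
        stride_px=(sx, sy),
        tiles=tiles,
        mosaic_shape_px=(mw, mh),
    )


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union of two (n, 4) box arrays."""
    a = np.atleast_2d(np.asarray(boxes_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(boxes_b, dtype=np.float64))
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix1 - ix0, 0, None) * np.clip(iy1 - iy0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def nms(boxes, scores, iou_threshold: float = 0.5) -> list[int]:
    """Greedy non-max suppression; returns kept indices.

    Boxes are visited in descending score order (ties broken by lower index);
    a box is suppressed iff its IoU with an already-kept box exceeds
    ``iou_threshold``.
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64)
    if len(boxes) != len(scores):
        raise ValueError("boxes and scores must have equal length")
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in [0, 1]")
    if (boxes[:, 2] <= boxes[:, 0]).any() or (boxes[:, 3] <= boxes[:, 1]).any():
        raise ValueError("malformed boxes (need x1 > x0 and y1 > y0)")
    if len(boxes) == 0:
        return []
    order = np.lexsort((np.arange(len(scores)), -scores))
    iou = iou_matrix(boxes, boxes)
    kept: list[int] = []
    for i in order:
        if all(iou[i, j] <= iou_threshold for j in kept):
            kept.append(int(i))
    return sorted(kept)


def detect_tiled(
    mosaic: np.ndarray,
    detector,
    tile_plan: TilePlan | None = None,
    nms_iou: float = 0.5,
    frame_index: int = 0,
) -> tuple[list[Detection], list[dict]]:
    """Run a per-tile detector over a large mosaic with cross-tile NMS.

    Returns ``(detections, failures)``: per-tile detector exceptions are
    recorded and other tiles proceed; if every tile fails an error is raised.
    An object straddling a tile boundary is seen by both tiles; the tile
    whose *ownership region* (tiles own centers up to the midpoint of each
    overlap) contains the box center reports it, and the global per-label
    NMS removes any remaining duplicates, so it yields exactly one detection.
    """
    h, w = mosaic.shape[:2]
    plan = tile_plan or plan_tiles((w, h))

    def _ownership(origins, tile_len, extent):
        edges = [0.0]
        for a, b in zip(origins[:-1], origins[1:]):
            edges.append((b + a + tile_len) / 2.0)
        edges.append(float(extent))
        return {o: (edges[i], edges[i + 1]) for i, o in enumerate(origins)}

    xs = sorted({t[0] for t in plan.tiles})
    ys = sorted({t[1] for t in plan.tiles})
    own_x = _ownership(xs, plan.tile_px[0], w)
    own_y = _ownership(ys, plan.tile_px[1], h)

    all_boxes, all_scores, all_labels, all_src = [], [], [], []
    failures = []
    for (x0, y0) in plan.tiles:
        tw, th = plan.tile_px
        tile = mosaic[y0 : y0 + th, x0 : x0 + tw]
        try:
            out = detector(tile)
        except Exception as exc:  # noqa: BLE001 - contract: record and continue
            failures.append({"tile": (x0, y0), "error": repr(exc)})
            continue
        boxes, scores = out[0], out[1]
        labels = out[2] if len(out) > 2 else ["organism"] * len(scores)
        for bb, sc, lb in zip(boxes, scores, labels):
            bx0 = min(max(bb[0] + x0, 0), w)
            by0 = min(max(bb[1] + y0, 0), h)
            bx1 = min(max(bb[2] + x0, 0), w)
            by1 = min(max(bb[3] + y0, 0), h)
            if bx1 <= bx0 or by1 <= by0:
                continue
            cx, cy = (bx0 + bx1) / 2.0, (by0 + by1) / 2.0
            ox0, ox1 = own_x[x0]
            oy0, oy1 = own_y[y0]
            if not (ox0 <= cx < ox1 and oy0 <= cy < oy1):
                continue  # a neighboring tile owns this object
            all_boxes.append((bx0, by0, bx1, by1))
            all_scores.append(float(sc))
            all_labels.append(str(lb))
            all_src.append((x0, y0))
    if failures and len(failures) == len(plan.tiles):
        raise RuntimeError(f"detector failed on all {len(failures)} tiles")

    detections: list[Detection] = []
    for label in sorted(set(all_labels)):
        idx = [i for i, lb in enumerate(all_labels) if lb == label]
        kept = nms([all_boxes[i] for i in idx], [all_scores[i] for i in idx], nms_iou)
        for j in kept:
            i = idx[j]
            detections.append(
                Detection(
                    box_px=all_boxes[i],
                    score=all_scores[i],
                    label=label,
                    frame_index=frame_index,
                    source_tile=all_src[i],
                )
            )
    detections.sort(key=lambda d: (-d.score, d.box_px))
    return detections, failures


def reference_blob_detector(
    image: np.ndarray,
    scale_range_px: tuple[float, float] = (4.0, 20.0),
    polarity: str = "dark",
    threshold: float = 0.08,
    min_area_px: int = 12,
    close_px: int | None = None,
):
    """Classical difference-of-Gaussians blob detector (reference detector).

    Band-pass responses over a geometric ladder of scales are combined by
    maximum, thresholded (polarity-aware), closed morphologically (radius
    ``close_px``, default a third of the largest scale -- joins the response
    fragments of one elongated organism without fusing well-separated
    blobs), grouped into connected components and returned as bounding boxes
    with scores normalized to [0, 1] by the tile's maximum response.
    """
    lo, hi = scale_range_px
    if not (lo > 0 and hi >= lo):
        raise ValueError("empty or invalid scale range")
    img = np.asarray(image, dtype=np.float64)
    sigmas, s = [], lo / 2.0
    while s <= hi / 2.0 + 1e-9:
        sigmas.append(s)
        s *= 1.6
    resp = None
    for sig in sigmas:
        dog = ndimage.gaussian_filter(img, sig) - ndimage.gaussian_filter(img, 3.0 * sig)
        # a dark blob is below its local background: negative center response
        r = -dog if polarity == "dark" else dog
        resp = r if resp is None else np.maximum(resp, r)
    peak = float(resp.max())
    if peak <= threshold:
        return np.zeros((0, 4)), np.zeros(0)
    mask = resp > threshold
    if close_px is None:
        close_px = max(1, int(round(hi / 3.0)))
    if close_px > 0:
        rr = np.arange(-close_px, close_px + 1)
        disk = rr[:, None] ** 2 + rr[None, :] ** 2 <= close_px**2
        mask = ndimage.binary_closing(mask, structure=disk)
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros((0, 4)), np.zeros(0)
    boxes, scores = [], []
    for sl, idx in zip(ndimage.find_objects(labels), range(1, n + 1)):
        if sl is None:
            continue
        area = int((labels[sl] == idx).sum())
        if area < min_area_px:
            continue
        y0, y1 = sl[0].start, sl[0].stop
        x0, x1 = sl[1].start, sl[1].stop
        comp_peak = float(resp[sl][labels[sl] == idx].max())
        pad = 2
        boxes.append(
            (
                max(x0 - pad, 0),
                max(y0 - pad, 0),
                min(x1 + pad, img.shape[1]),
                min(y1 + pad, img.shape[0]),
            )
        )
        scores.append(comp_peak / peak)
    return np.asarray(boxes, dtype=np.float64).reshape(-1, 4), np.asarray(scores)


@dataclass
class BlobDetector:
    """Configured reference detector satisfying the tile-detector contract."""

    scale_range_px: tuple[float, float] = (4.0, 20.0)
    polarity: str = "dark"
    threshold: float = 0.08
    min_area_px: int = 12
    close_px: int | None = None
    label: str = "organism"

    def __call__(self, tile: np.ndarray):
        boxes, scores = reference_blob_detector(
            tile, self.scale_range_px, self.polarity, self.threshold, self.min_area_px, self.close_px
        )
        return boxes, scores, [self.label] * len(scores)


def occluder_augment(
    organism_crops: list[tuple[np.ndarray, np.ndarray]],
    background: np.ndarray,
    n_pastes: int,
    overlap_range: tuple[float, float] = (0.0, 0.3),
    seed: int = 0,
    max_attempts: int = 1000,
):
    """Paste masked organism crops onto a background with controlled overlap.

    Emulates synthetic-occluder training augmentation: crops (image, boolean
    foreground mask) are pasted at random positions such that every pairwise
    box IoU is at most ``overlap_range[1]`` and, when ``overlap_range[0] > 0``
    and more than one crop is pasted, each crop overlaps at least one other by
    at least the lower bound.  Returns ``(augmented_image, boxes)`` with exact
    ground-truth boxes, including occluded ones.
    """
    lo, hi = overlap_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("overlap_range must satisfy 0 <= lo <= hi <= 1")
    out = np.array(background, dtype=np.float64, copy=True)
    if n_pastes == 0:
        return out, []
    rng = np.random.default_rng([int(seed) % (2**31), 555])
    bh, bw = out.shape[:2]

    for _ in range(max_attempts):
        img = np.array(background, dtype=np.float64, copy=True)
        boxes = []
        ok = True
        for i in range(n_pastes):
            crop, mask = organism_crops[int(rng.integers(len(organism_crops)))]
            k = int(rng.integers(4))
            crop, mask = np.rot90(crop, k), np.rot90(mask, k)
            ch, cw = crop.shape[:2]
            if ch >= bh or cw >= bw:
                raise ValueError("crop larger than background")
            placed = False
            for _ in range(200):
                if lo > 0 and boxes:
                    # aim near an existing box so the IoU lower bound is reachable
                    tx0, ty0, _, _ = boxes[int(rng.integers(len(boxes)))]
                    x = int(np.clip(tx0 + rng.integers(-cw, cw + 1), 0, bw - cw))
                    y = int(np.clip(ty0 + rng.integers(-ch, ch + 1), 0, bh - ch))
                else:
                    x = int(rng.integers(0, bw - cw))
                    y = int(rng.integers(0, bh - ch))
                box = (x, y, x + cw, y + ch)
                if boxes:
                    ious = iou_matrix([box], boxes)[0]
                    if ious.max() > hi:
                        continue
                    if lo > 0 and ious.max() < lo:
                        continue
                boxes.append(box)
                region = img[y : y + ch, x : x + cw]
                region[mask] = crop[mask]
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        if lo > 0 and n_pastes > 1:
            ious = iou_matrix(boxes, boxes)
            np.fill_diagonal(ious, 0.0)
            if (ious.max(axis=1) < lo).any():
                continue
        return img, boxes
    raise RuntimeError(
        f"could not satisfy overlap constraint {overlap_range} in {max_attempts} attempts"
    )
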