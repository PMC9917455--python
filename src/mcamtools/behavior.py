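"""Behavioral readouts distilled from tracks and mosaics.

Occupancy heatmaps (spatial probability of finding an animal), tail and eye
kinematics from single-organism crops, block-matching optical-flow activity
for arena-wide arousal, and connectivity-based individual/swarm counting for
dense cohorts (e.g. nematode plates).

Tail and eye algorithms operate on world-oriented grayscale crops with dark
organisms on a bright background: binarize, keep the largest component,
skeletonize, walk the skeleton from the head end (identified as the wider
body end via the distance transform), then measure segment angles relative
to the head-region body axis, or fit the two darkest elliptical head
components for eye orientations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "OccupancyMap",
    "TailTrace",
    "EyeMeasurement",
    "SegmentationCounts",
    "occupancy_heatmap",
    "tail_trace",
    "eye_angles",
    "optical_flow_activity",
    "reference_segmenter",
    "segment_count",
    "density_per_area",
]


@dataclass
class OccupancyMap:
    grid: np.ndarray  # (ny, nx), sums to 1
    bin_size_mm: float
    arena_box_mm: tuple[float, float, float, float]
    n_samples: int


@dataclass
class TailTrace:
    segment_angles_rad: np.ndarray  # head to tail tip, relative to body axis
    body_axis_rad: float  # head-region axis, pointing head -> tail
    n_segments: int

    def __post_init__(self):
        if len(self.segment_angles_rad) != self.n_segments:
            raise ValueError("angle list length must equal n_segments")


@dataclass
class EyeMeasurement:
    left_rad: float | None
    right_rad: float | None
    missing: bool = False


@dataclass
class SegmentationCounts:
    n_individuals: int
    n_swarms: int
    individual_areas_px: list[int]
    swarm_areas_px: list[int]
    density_individuals_per_cm2: float | None = None
    density_swarms_per_cm2: float | None = None

    def __post_init__(self):
        if self.n_individuals != len(self.individual_areas_px):
            raise ValueError("individual count does not match area list")
        if self.n_swarms != len(self.swarm_areas_px):
            raise ValueError("swarm count does not match area list")


def occupancy_heatmap(
    track_positions_mm: np.ndarray,
    arena_box_mm: tuple[float, float, float, float],
    bin_size_mm: float = 5.0,
) -> OccupancyMap:
    """Normalized 2-D histogram of positions: P(animal in bin).

    Positions outside the arena are clipped to its edge with a warning; the
    grid always sums to exactly 1 (n_samples > 0 required).
    """
    pos = np.atleast_2d(np.asarray(track_positions_mm, dtype=np.float64))
    if pos.size == 0:
        raise ValueError("no positions given")
    x0, y0, x1, y1 = arena_box_mm
    outside = (pos[:, 0] < x0) | (pos[:, 0] > x1) | (pos[:, 1] < y0) | (pos[:, 1] > y1)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} positions outside the arena were clipped", stacklevel=2)
        pos = np.clip(pos, [x0, y0], [x1, y1])
    nx = max(1, int(math.ceil((x1 - x0) / bin_size_mm)))
    ny = max(1, int(math.ceil((y1 - y0) / bin_size_mm)))
    grid, _, _ = np.histogram2d(
        pos[:, 1], pos[:, 0], bins=[ny, nx], range=[[y0, y0 + ny * bin_size_mm], [x0, x0 + nx * bin_size_mm]]
    )
    grid /= grid.sum()
    return OccupancyMap(grid=grid, bin_size_mm=bin_size_mm, arena_box_mm=arena_box_mm, n_samples=len(pos))


# --------------------------------------------------------------------------
# skeleton-based kinematics


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _organism_mask(crop: np.ndarray, min_area_px: int):
    """Dark organism on bright background; threshold referenced to the
    background level (median) so light body texture stays inside the mask."""
    img = np.asarray(crop, dtype=np.float64)
    bg = float(np.median(img))
    thr = bg - 0.15 * (bg - float(img.min()))
    mask = img < thr
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)), iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no organism blob found in crop")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area_px:
        raise ValueError(f"largest blob area {int(areas[best - 1])} px below minimum {min_area_px}")
    return labels == best, img


def _skeleton_path(mask: np.ndarray):
    """Ordered (row, col) path along the skeleton's longest end-to-end walk."""
    skel = skeletonize(mask)
    pts = {tuple(p) for p in np.argwhere(skel)}
    if not pts:
        raise ValueError("empty skeleton")

    def nbrs(p):
        return [(p[0] + dy, p[1] + dx) for dy, dx in _NEIGHBORS if (p[0] + dy, p[1] + dx) in pts]

    endpoints = [p for p in pts if len(nbrs(p)) == 1]
    if not endpoints:
        raise ValueError("skeleton has no endpoints (closed loop): irrecoverable")

    def farthest_path(start):
        # BFS tree walk; returns the longest simple path from start
        prev = {start: None}
        order = [start]
        queue = [start]
        while queue:
            nxt = []
            for p in queue:
                for q in nbrs(p):
                    if q not in prev:
                        prev[q] = p
                        order.append(q)
                        nxt.append(q)
            queue = nxt
        end = order[-1]
        path = []
        p = end
        while p is not None:
            path.append(p)
            p = prev[p]
        return path[::-1]

    path = farthest_path(endpoints[0])
    path = farthest_path(path[-1])  # double-sweep: longest end-to-end path
    return path, skel


def _head_first(path, mask):
    """Order the path head-first: the head end sits in the wider body region."""
    dist = ndimage.distance_transform_edt(mask)
    k = max(2, len(path) // 6)
    width_start = np.mean([dist[p] for p in path[:k]])
    width_end = np.mean([dist[p] for p in path[-k:]])
    return path if width_start >= width_end else path[::-1]


def _resample_path(path, n_points):
    pts = np.asarray(path, dtype=np.float64)  # (n, 2) row, col
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n_points)
    rows = np.interp(targets, arc, pts[:, 0])
    cols = np.interp(targets, arc, pts[:, 1])
    return np.stack([rows, cols], axis=1)


def _wrap(a):
    return (a + math.pi) % (2 * math.pi) - math.pi


def tail_trace(fish_crop: np.ndarray, n_segments: int = 8, min_area_px: int = 200) -> TailTrace:
    """Segment-wise tail angles of one organism, head to tail tip.

    Angles are measured relative to the head-region body axis (the direction
    of the first quarter of the midline, pointing head to tail); a straight
    organism yields all-zero angles.
    """
    mask, _ = _organism_mask(fish_crop, min_area_px)
    path, _ = _skeleton_path(mask)
    path = _head_first(path, mask)
    pts = _resample_path(path, n_segments + 1)
    quarter = _resample_path(path, 5)
    axis_vec = quarter[1] - quarter[0]
    body_axis = math.atan2(axis_vec[0], axis_vec[1])  # rows = y, cols = x
    chords = np.diff(pts, axis=0)
    angles = np.array([_wrap(math.atan2(c[0], c[1]) - body_axis) for c in chords])
    return TailTrace(segment_angles_rad=angles, body_axis_rad=body_axis, n_segments=n_segments)


def eye_angles(
    fish_crop: np.ndarray,
    min_area_px: int = 200,
    min_eye_area_px: int = 12,
) -> EyeMeasurement:
    """Orientation of both eyes relative to the body axis.

    The head is located as the wider end of the skeletonized midline; the two
    darkest elliptical components in the head region are taken as the eyes;
    each eye angle is its second-moment major-axis orientation minus the
    body-axis orientation, and left/right follows the sign of the cross
    product with the heading.  Fewer than two eye components flags the
    measurement as missing.
    """
    mask, img = _organism_mask(fish_crop, min_area_px)
    path, _ = _skeleton_path(mask)
    path = _head_first(path, mask)
    pts = np.asarray(path, dtype=np.float64)
    n_head = max(3, len(path) // 4)
    head_pts = pts[:n_head]
    quarter = _resample_path(path, 5)
    axis_vec = quarter[1] - quarter[0]  # head -> tail (row, col)
    body_axis = math.atan2(axis_vec[0], axis_vec[1])
    heading = (-axis_vec[0], -axis_vec[1])  # tail -> head = forward

    # head region: pixels near the first quarter of the midline
    dist = ndimage.distance_transform_edt(mask)
    body_halfwidth = float(dist.max())
    head_mask = np.zeros_like(mask)
    r0 = int(max(head_pts[:, 0].min() - 2 * body_halfwidth, 0))
    r1 = int(min(head_pts[:, 0].max() + 2 * body_halfwidth + 1, mask.shape[0]))
    c0 = int(max(head_pts[:, 1].min() - 2 * body_halfwidth, 0))
    c1 = int(min(head_pts[:, 1].max() + 2 * body_halfwidth + 1, mask.shape[1]))
    head_mask[r0:r1, c0:c1] = True
    head_mask &= mask

    vals = img[head_mask]
    thr = vals.min() + 0.20 * (np.median(vals) - vals.min())
    dark = head_mask & (img <= thr)
    labels, n = ndimage.label(dark)
    comps = []
    for idx in range(1, n + 1):
        ys, xs = np.nonzero(labels == idx)
        if len(ys) < min_eye_area_px:
            continue
        comps.append((len(ys), ys, xs))
    if len(comps) < 2:
        return EyeMeasurement(left_rad=None, right_rad=None, missing=True)
    comps.sort(key=lambda c: -c[0])
    head_origin = head_pts[0]
    out = {}
    for _, ys, xs in comps[:2]:
        mu_y, mu_x = ys.mean(), xs.mean()
        dy, dx = ys - mu_y, xs - mu_x
        theta = 0.5 * math.atan2(2 * np.mean(dx * dy), np.mean(dx**2) - np.mean(dy**2))
        ang = _wrap(theta - (body_axis + math.pi))
        # fold to (-pi/2, pi/2]: the major axis is orientation-only
        if ang > math.pi / 2:
            ang -= math.pi
        elif ang <= -math.pi / 2:
            ang += math.pi
        off = (mu_y - head_origin[0], mu_x - head_origin[1])
        cross = heading[1] * off[0] - heading[0] * off[1]  # x*dy - y*dx in (col,row)
        side = "left" if cross > 0 else "right"
        out[side] = float(ang)
    if "left" not in out or "right" not in out:
        return EyeMeasurement(left_rad=None, right_rad=None, missing=True)
    return EyeMeasurement(left_rad=out["left"], right_rad=out["right"], missing=False)


# --------------------------------------------------------------------------
# optical flow


def optical_flow_activity(
    frame_sequence,
    block_px: int = 16,
    search_px: int = 4,
    texture_threshold: float = 1e-4,
    epochs: dict[str, list[tuple[int, int]]] | None = None,
):
    """Arena-wide activity from dense block-matching optical flow.

    For each consecutive frame pair, every ``block_px`` square block is
    matched to the next frame by exhaustive SSD search within ``+-search_px``;
    activity is the mean displacement magnitude (px/frame) over blocks whose
    intensity variance exceeds ``texture_threshold``.  ``epochs`` maps labels
    to lists of [start, end) frame-pair intervals; per-epoch mean activity is
    returned alongside the per-frame series.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frame_sequence]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    h, w = frames[0].shape
    if any(f.shape != (h, w) for f in frames):
        raise ValueError("frames must share dimensions")
    if block_px > min(h, w):
        raise ValueError("block larger than frame")
    s = search_px
    ys = np.arange(s, h - s - block_px + 1, block_px)
    xs = np.arange(s, w - s - block_px + 1, block_px)
    if len(ys) == 0 or len(xs) == 0:
        raise ValueError("frame too small for the requested block and search sizes")

    def block_reduce(img2):
        # sum over block_px x block_px tiles anchored at (ys, xs)
        cs = img2.cumsum(axis=0).cumsum(axis=1)
        csp = np.pad(cs, ((1, 0), (1, 0)))
        return (
            csp[np.ix_(ys + block_px, xs + block_px)]
            - csp[np.ix_(ys, xs + block_px)]
            - csp[np.ix_(ys + block_px, xs)]
            + csp[np.ix_(ys, xs)]
        )

    activity = []
    for f0, f1 in zip(frames[:-1], frames[1:]):
        best = np.full((len(ys), len(xs)), np.inf)
        bdx = np.zeros((len(ys), len(xs)))
        bdy = np.zeros((len(ys), len(xs)))
        for dy in range(-s, s + 1):
            for dx in range(-s, s + 1):
                shifted = f1[s + dy : h - s + dy, s + dx : w - s + dx]
                base = f0[s : h - s, s : w - s]
                ssd_img = (base - shifted) ** 2
                # embed back so block anchors line up
                full = np.zeros((h, w))
                full[s : h - s, s : w - s] = ssd_img
                ssd = block_reduce(full)
                improved = ssd < best - 1e-12
                best[improved] = ssd[improved]
                bdx[improved] = dx
                bdy[improved] = dy
        var = block_reduce(np.pad(f0[s : h - s, s : w - s] ** 2, ((s, s), (s, s)))) / block_px**2 - (
            block_reduce(np.pad(f0[s : h - s, s : w - s], ((s, s), (s, s)))) / block_px**2
        ) ** 2
        textured = var > texture_threshold
        mag = np.hypot(bdx, bdy)
        activity.append(float(mag[textured].mean()) if textured.any() else 0.0)
    activity = np.asarray(activity)
    result = {"per_frame": activity}
    if epochs:
        result["epoch_means"] = {
            label: float(np.mean([activity[a:b].mean() for a, b in spans]))
            for label, spans in epochs.items()
        }
    return result


# --------------------------------------------------------------------------
# segmentation counting


def reference_segmenter(image: np.ndarray, opening_px: int = 1) -> np.ndarray:
    """Classical mask producer: Otsu threshold (dark foreground) + opening."""
    img = np.asarray(image, dtype=np.float64)
    thr = threshold_otsu(img)
    mask = img < thr
    if opening_px > 0:
        mask = ndimage.binary_opening(mask, iterations=opening_px)
    return mask


def segment_count(
    mosaic: np.ndarray,
    segmenter=None,
    min_area_px: int = 50,
    swarm_area_threshold_px: float | None = None,
    connectivity: int = 8,
    um_per_px: float | None = None,
    arena_area_cm2: float | None = None,
) -> SegmentationCounts:
    """Count individuals and swarms by connected-component labeling.

    ``segmenter`` maps the image to a boolean foreground mask (default: the
    classical reference segmenter); a boolean ``mosaic`` is used directly.
    Components below ``min_area_px`` are discarded; components at or above
    ``swarm_area_threshold_px`` (default 5x the median component area) count
    as swarms, the rest as individuals.  Densities are filled in when an
    arena area (or scale) is available.
    """
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    if mosaic.dtype == bool:
        mask = mosaic
    else:
        mask = (segmenter or reference_segmenter)(mosaic)
        mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        areas = np.array([], dtype=int)
    else:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1)).astype(int)
    areas = areas[areas >= min_area_px]
    if swarm_area_threshold_px is None:
        swarm_area_threshold_px = 5.0 * (np.median(areas) if len(areas) else np.inf)
    ind = sorted(int(a) for a in areas[areas < swarm_area_threshold_px])
    swarm = sorted(int(a) for a in areas[areas >= swarm_area_threshold_px])
    if arena_area_cm2 is None and um_per_px is not None:
        arena_area_cm2 = mask.size * (um_per_px * 1e-4) ** 2
    d_ind = d_swarm = None
    if arena_area_cm2:
        d_ind = len(ind) / arena_area_cm2
        d_swarm = len(swarm) / arena_area_cm2
    return SegmentationCounts(
        n_individuals=len(ind),
        n_swarms=len(swarm),
        individual_areas_px=ind,
        swarm_areas_px=swarm,
        density_individuals_per_cm2=d_ind,
        density_swarms_per_cm2=d_swarm,
    )


def density_per_area(
    count: int,
    area_cm2: float,
    centroids_px: np.ndarray | None = None,
    mosaic_shape_px: tuple[int, int] | None = None,
    block_grid: tuple[int, int] = (4, 4),
):
    """Objects per cm^2 with a standard error across spatial blocks.

    The arena is partitioned into ``block_grid`` rectangles; the SEM is the
    standard error of the per-block densities (requires ``centroids_px`` and
    ``mosaic_shape_px``; otherwise SEM is reported as None).
    """
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    density = count / area_cm2
    sem = None
    if centroids_px is not None and mosaic_shape_px is not None:
        gx, gy = block_grid
        w, h = mosaic_shape_px
        block_area = area_cm2 / (gx * gy)
        counts = np.zeros((gy, gx))
        pts = np.atleast_2d(np.asarray(centroids_px, dtype=np.float64)) if len(centroids_px) else np.zeros((0, 2))
        for x, y in pts:
            bx = min(int(x / w * gx), gx - 1)
            by = min(int(y / h * gy), gy - 1)
            counts[by, bx] += 1
        block_density = counts.ravel() / block_area
        n_blocks = gx * gy
        sem = float(block_density.std(ddof=1) / math.sqrt(n_blocks)) if n_blocks > 1 else 0.0
        if count == 0:
            sem = 0.0
    return {"density_per_cm2": float(density), "sem_per_cm2": sem, "block_grid": list(block_grid)}
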