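"""Stereoscopic depth from adjacent-camera image pairs.

Because adjacent cameras share more than half of their field of view along
the long sensor axis, any object is seen by at least two cameras.  Depth is
recovered per object, not per pixel: corner-like keypoints are described by a
256-bit binary intensity-comparison descriptor, matched across the pair by
minimum Hamming distance (mutual-best, ratio-tested), the per-match
displacement along the baseline axis is robustly averaged (median-absolute-
deviation outlier rejection) into a single object disparity, and the
disparity is inverted to object distance with the thin-lens relation
``u = f * (1 + B / s)``.

Feature positions are measured in 180-degree-rotated (world-oriented) camera
images, where the displacement of a feature between the two cameras of a
pair directly equals the sensor-plane binocular disparity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import corner_peaks, corner_shi_tomasi

from .optics import DepthGeometry, disparity_to_depth

__all__ = [
    "FeatureMatchSet",
    "DepthEstimate",
    "extract_features",
    "match_features",
    "hamming_distances",
    "object_disparity",
    "estimate_depth",
    "calibrate_depth_scale",
    "pair_disparity",
    "track_3d",
]

DESCRIPTOR_BITS = 256
PATCH_RADIUS = 12
_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.int32)


def _sampling_pattern() -> tuple[np.ndarray, np.ndarray]:
    """Fixed pseudo-random pattern of 256 point pairs within the patch."""
    rng = np.random.default_rng(20230517)
    pts = rng.normal(0.0, PATCH_RADIUS / 2.5, size=(2, DESCRIPTOR_BITS, 2))
    pts = np.clip(np.round(pts), -PATCH_RADIUS, PATCH_RADIUS).astype(np.int64)
    return pts[0], pts[1]


_PAT_A, _PAT_B = _sampling_pattern()


@dataclass
class FeatureMatchSet:
    """Accepted keypoint correspondences between one camera pair."""

    matches: list[tuple[tuple[float, float], tuple[float, float], int]]
    camera_pair: tuple[tuple[int, int], tuple[int, int]] | None = None
    region_box: tuple[float, float, float, float] | None = None

    def displacements(self) -> np.ndarray:
        """(n, 2) array of (dx, dy) = point_b - point_a."""
        if not self.matches:
            return np.zeros((0, 2))
        a = np.array([m[0] for m in self.matches], dtype=np.float64)
        b = np.array([m[1] for m in self.matches], dtype=np.float64)
        return b - a


@dataclass
class DepthEstimate:
    xy_mm: tuple[float, float]
    z_mm: float
    object_distance_mm: float
    n_features: int = 1
    dispersion_mm: float = 0.0

    def __post_init__(self):
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.dispersion_mm < 0:
            raise ValueError("dispersion must be >= 0")


def extract_features(
    image: np.ndarray,
    region: tuple[int, int, int, int] | None = None,
    max_keypoints: int = 400,
    min_distance: int = 4,
    threshold_rel: float = 0.02,
    smoothing_sigma: float = 1.5,
):
    """Detect corner keypoints and compute 256-bit binary descriptors.

    Keypoints are Shi-Tomasi corner-response maxima inside ``region``
    (x0, y0, x1, y1; whole image by default); each descriptor holds 256
    pairwise intensity comparisons of the Gaussian-smoothed image on a fixed
    sampling pattern around the keypoint.  Fully deterministic.

    Returns ``(keypoints, descriptors)``: float (n, 2) array of (x, y) image
    coordinates and a packed uint8 array of shape (n, 32).
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    if region is None:
        region = (0, 0, w, h)
    x0, y0, x1, y1 = (int(region[0]), int(region[1]), int(math.ceil(region[2])), int(math.ceil(region[3])))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    if x1 - x0 < 2 * PATCH_RADIUS + 3 or y1 - y0 < 2 * PATCH_RADIUS + 3:
        raise ValueError("region smaller than the descriptor patch")
    crop = img[y0:y1, x0:x1]
    response = corner_shi_tomasi(crop)
    # the corner response spikes spuriously at crop borders; zero out the
    # strip that the descriptor patch cannot cover anyway
    border = PATCH_RADIUS + 1
    interior = np.zeros_like(response)
    interior[border:-border, border:-border] = response[border:-border, border:-border]
    peaks = corner_peaks(
        interior,
        min_distance=min_distance,
        threshold_rel=threshold_rel,
    )
    if len(peaks) == 0:
        return np.zeros((0, 2)), np.zeros((0, DESCRIPTOR_BITS // 8), dtype=np.uint8)
    if len(peaks) > max_keypoints:
        vals = response[peaks[:, 0], peaks[:, 1]]
        peaks = peaks[np.argsort(-vals)[:max_keypoints]]
        peaks = peaks[np.lexsort((peaks[:, 1], peaks[:, 0]))]

    smooth = gaussian_filter(crop, smoothing_sigma)
    ky, kx = peaks[:, 0], peaks[:, 1]
    ia = smooth[ky[:, None] + _PAT_A[None, :, 0], kx[:, None] + _PAT_A[None, :, 1]]
    ib = smooth[ky[:, None] + _PAT_B[None, :, 0], kx[:, None] + _PAT_B[None, :, 1]]
    bits = (ia < ib).astype(np.uint8)
    desc = np.packbits(bits, axis=1)
    keypoints = np.stack([kx + x0, ky + y0], axis=1).astype(np.float64)
    return keypoints, desc


def hamming_distances(desc_a: np.ndarray, desc_b: np.ndarray) -> np.ndarray:
    """Full (na, nb) Hamming distance matrix between packed descriptors."""
    a = np.asarray(desc_a, dtype=np.uint8)
    b = np.asarray(desc_b, dtype=np.uint8)
    return _POPCOUNT[np.bitwise_xor(a[:, None, :], b[None, :, :])].sum(axis=2)


def match_features(
    features_a,
    features_b,
    max_hamming: int = 64,
    ratio_threshold: float = 0.8,
    camera_pair=None,
    region_box=None,
) -> FeatureMatchSet:
    """Mutual-best Hamming matching with a best/second-best ratio test.

    ``features_*`` are (keypoints, descriptors) pairs from
    :func:`extract_features`.  A match is accepted iff it is each side's
    nearest descriptor, its distance is at most ``max_hamming`` and the
    best/second-best distance ratio is at most ``ratio_threshold`` (the
    ratio test is waived when there is no second candidate).
    """
    kps_a, da = features_a
    kps_b, db = features_b
    if len(da) == 0 or len(db) == 0:
        return FeatureMatchSet(matches=[], camera_pair=camera_pair, region_box=region_box)
    dist = hamming_distances(da, db)
    best_b = np.argmin(dist, axis=1)
    best_a = np.argmin(dist, axis=0)
    matches = []
    for i, j in enumerate(best_b):
        if best_a[j] != i:
            continue
        d = int(dist[i, j])
        if d > max_hamming:
            continue
        if dist.shape[1] > 1:
            second = np.partition(dist[i], 1)[1]
            if second > 0 and d / second > ratio_threshold:
                continue
        matches.append(((float(kps_a[i, 0]), float(kps_a[i, 1])), (float(kps_b[j, 0]), float(kps_b[j, 1])), d))
    return FeatureMatchSet(matches=matches, camera_pair=camera_pair, region_box=region_box)


def object_disparity(match_set: FeatureMatchSet, outlier_mad_k: float = 3.0):
    """Robust mean feature displacement along the baseline (long) axis.

    Median-absolute-deviation rejection at ``outlier_mad_k`` scaled MADs is
    applied to both the baseline-axis and the orthogonal displacement
    component (the latter carries no disparity and is pure noise).  Returns
    ``(disparity_px, n_survivors, dispersion_px)``; raises if fewer than 3
    matches survive.
    """
    disp = match_set.displacements()
    if len(disp) < 3:
        raise ValueError(f"insufficient features: {len(disp)} matches (need >= 3)")
    dx, dy = disp[:, 0], disp[:, 1]

    def _keep(v):
        med = np.median(v)
        mad = 1.4826 * np.median(np.abs(v - med))
        return np.abs(v - med) <= outlier_mad_k * max(mad, 0.35)

    keep = _keep(dx) & _keep(dy)
    if keep.sum() < 3:
        raise ValueError(f"insufficient features after outlier rejection: {int(keep.sum())}")
    survivors = dx[keep]
    return float(survivors.mean()), int(keep.sum()), float(survivors.std())


def estimate_depth(
    disparity_px,
    geometry: DepthGeometry,
    xy_mm: tuple[float, float] = (0.0, 0.0),
    n_features: int | None = None,
) -> DepthEstimate:
    """Convert disparity (px, scalar or per-feature array) to a depth estimate.

    Object distance ``u = f * (1 + B / s)`` with ``s`` the absolute
    sensor-plane disparity; ``z = u0 - u`` under the z-toward-camera-positive
    convention.
    """
    disp = np.atleast_1d(np.asarray(disparity_px, dtype=np.float64))
    disp = np.abs(disp)
    if (disp <= 0).any():
        raise ValueError("disparity must be positive")
    u = np.array([disparity_to_depth(d, geometry, units="px") for d in disp])
    z = np.array([geometry.z_from_object_distance(ui) for ui in u])
    return DepthEstimate(
        xy_mm=xy_mm,
        z_mm=float(z.mean()),
        object_distance_mm=float(u.mean()),
        n_features=int(n_features if n_features is not None else len(disp)),
        dispersion_mm=float(z.std()),
    )


def calibrate_depth_scale(
    observed_disparity_px: float,
    known_z_mm: float,
    geometry: DepthGeometry,
) -> DepthGeometry:
    """One-point depth calibration: rescale the baseline from a known target.

    The absolute thin-lens model predicts disparity ``s = B * m(u)``; an
    observed disparity of a target at known z rescales the effective
    baseline (equivalently B*f) so prediction matches observation,
    summarizing a multi-position calibration by a single scale factor.
    """
    u = geometry.focus_distance_mm - (
        known_z_mm if geometry.z_sign == "toward_camera_positive" else -known_z_mm
    )
    from dataclasses import replace

    from .optics import depth_to_disparity

    predicted = depth_to_disparity(u, geometry, units="px")
    if observed_disparity_px <= 0:
        raise ValueError("observed disparity must be positive")
    scale = abs(observed_disparity_px) / predicted
    return replace(geometry, baseline_mm=geometry.baseline_mm * scale)


def pair_disparity(
    image_a: np.ndarray,
    image_b: np.ndarray,
    region_a=None,
    region_b=None,
    outlier_mad_k: float = 3.0,
    camera_pair=None,
    **feature_kwargs,
):
    """Extract, match and robustly average: images -> (disparity_px, n, spread)."""
    fa = extract_features(image_a, region_a, **feature_kwargs)
    fb = extract_features(image_b, region_b, **feature_kwargs)
    ms = match_features(fa, fb, camera_pair=camera_pair, region_box=region_a)
    return object_disparity(ms, outlier_mad_k)


def _stereo_pair_for_box(template, box, grid):
    """Pick the same-row adjacent-column camera pair best covering a box center."""
    cx, cy = (box[0] + box[2]) / 2.0, (box[1] + box[3]) / 2.0
    covering = []
    for key in template.global_offset_px:
        x0, y0, x1, y1 = template.camera_footprint(key)
        if x0 <= cx < x1 and y0 <= cy < y1:
            margin = min(cx - x0, x1 - cx, cy - y0, y1 - cy)
            covering.append((key, margin))
    best = None
    for (ka, ma) in covering:
        for (kb, mb) in covering:
            if ka[0] == kb[0] and kb[1] == ka[1] + 1:
                score = min(ma, mb)
                if best is None or score > best[0]:
                    best = (score, (ka, kb))
    return None if best is None else best[1]


def track_3d(
    detections_per_frame,
    framesets,
    template,
    geometry: DepthGeometry,
    max_displacement_px: float = 80.0,
    max_gap: int = 2,
    min_region_px: int = 2 * PATCH_RADIUS + 8,
    **feature_kwargs,
):
    """3-D trajectories: link detections over time, add stereoscopic z.

    For each linked detection the pair of adjacent same-row cameras covering
    its box (via the template's camera footprints) provides the stereo views;
    the object's features are matched between the two 180-degree-rotated raw
    frames and the MAD-filtered mean displacement is converted to depth.
    Detections outside any two-camera overlap get ``z_mm = NaN`` with quality
    ``"no_stereo"``; xy is always reported.

    Returns a pandas DataFrame with columns
    ``track_id, frame, x_mm, y_mm, z_mm, n_features, quality``.
    """
    import pandas as pd

    from .stitch import mosaic_to_world
    from .track import link_detections

    tracks = []
    rows = []
    rot_cache = {}
    for t, detections in enumerate(detections_per_frame):
        tracks = link_detections(tracks, detections, max_displacement_px, max_gap)
        fs = framesets[t]
        if t not in rot_cache:
            rot_cache = {t: {k: fs.frames[k][::-1, ::-1] for k in fs.camera_keys()}}
        rot = rot_cache[t]
        for tr in tracks:
            if tr.state != "active" or not tr.detections or tr.detections[-1].frame_index != t:
                continue
            det = tr.detections[-1]
            cx_px, cy_px = det.center
            x_mm, y_mm = mosaic_to_world(template, cx_px, cy_px)
            pair = _stereo_pair_for_box(template, det.box_px, fs.array_config.grid)
            z_mm, nfeat, quality = float("nan"), 0, "no_stereo"
            if pair is not None:
                regions = []
                for key in pair:
                    ox, oy = template.global_offset_px[key]
                    x0 = det.box_px[0] - ox
                    y0 = det.box_px[1] - oy
                    x1 = det.box_px[2] - ox
                    y1 = det.box_px[3] - oy
                    pad = max((min_region_px - (x1 - x0)) / 2.0, (min_region_px - (y1 - y0)) / 2.0, 8.0)
                    regions.append((x0 - pad, y0 - pad, x1 + pad, y1 + pad))
                try:
                    disparity, nfeat, _ = pair_disparity(
                        rot[pair[0]],
                        rot[pair[1]],
                        regions[0],
                        regions[1],
                        camera_pair=pair,
                        **feature_kwargs,
                    )
                    est = estimate_depth(disparity, geometry, xy_mm=(float(x_mm), float(y_mm)), n_features=nfeat)
                    z_mm, quality = est.z_mm, "ok"
                except ValueError as exc:
                    quality = f"failed:{exc}"[:40]
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": t,
                    "x_mm": float(x_mm),
                    "y_mm": float(y_mm),
                    "z_mm": z_mm,
                    "n_features": nfeat,
                    "quality": quality,
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_mm", "y_mm", "z_mm", "n_features", "quality"])
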