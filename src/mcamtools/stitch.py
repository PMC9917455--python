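"""Fourier stitching: calibrate a reusable template, then mosaic every frame.

Workflow (calibrate once, apply many):

1. A feature-rich calibration frameset is registered pairwise: every
   rook-adjacent camera pair is aligned by normalized cross-power-spectrum
   (phase) correlation on the predicted overlap crops, with quadratic
   sub-pixel peak refinement and a peak-ratio confidence.
2. Global per-camera translations are solved by weighted least squares over
   all pairwise constraints, camera (0, 0) anchored at the origin; low
   confidence pairs are down-weighted (floored, never dropped while the
   confident-pair graph stays connected).
3. The resulting :class:`StitchTemplate` is frame-independent and is applied
   to every subsequent frameset: raw frames (inverted by the optics) are
   rotated 180 degrees, placed at their offsets with bilinear sub-pixel
   shifts, and blended by linear feathering normalized to a partition of
   unity.

The camera model is translation-only; residual rotations of rigidly mounted
sensors show up in the per-pair residual report (flagged above 2 px).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as nd_shift
from scipy.signal.windows import tukey

from .optics import ArrayConfig
from .simulate import RawFrameSet

__all__ = [
    "StitchTemplate",
    "MosaicFrame",
    "register_pair",
    "calibrate_template",
    "apply_template",
    "predicted_pair_offsets",
    "world_to_mosaic",
    "mosaic_to_world",
]

MIN_OVERLAP_PX = 32
RESIDUAL_FLAG_PX = 2.0
CONF_FLOOR = 0.05


@dataclass
class StitchTemplate:
    """Per-camera global placement in mosaic coordinates (pixels).

    ``global_offset_px[(r, c)]`` is the (x, y) mosaic position of that
    camera's (180-degree-rotated) image origin; the anchor camera (0, 0)
    defines the reference, offsets are shifted so the mosaic origin is 0.
    ``origin_mm``/``um_per_px`` tie mosaic pixels to world coordinates.
    """

    global_offset_px: dict[tuple[int, int], tuple[float, float]]
    mosaic_shape_px: tuple[int, int]  # (width, height)
    um_per_px: float
    origin_mm: tuple[float, float]
    sensor_px: tuple[int, int]
    blend: dict = field(default_factory=lambda: {"feather_px": 40.0})
    source_hash: str = ""
    residuals: list[dict] = field(default_factory=list)

    def camera_footprint(self, key) -> tuple[float, float, float, float]:
        """Mosaic-coordinate box (x0, y0, x1, y1) covered by a camera."""
        ox, oy = self.global_offset_px[key]
        w, h = self.sensor_px
        return (ox, oy, ox + w, oy + h)

    def to_dict(self) -> dict:
        return {
            "global_offset_px": {f"{r},{c}": list(v) for (r, c), v in self.global_offset_px.items()},
            "mosaic_shape_px": list(self.mosaic_shape_px),
            "um_per_px": self.um_per_px,
            "origin_mm": list(self.origin_mm),
            "sensor_px": list(self.sensor_px),
            "blend": self.blend,
            "source_hash": self.source_hash,
            "residuals": self.residuals,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StitchTemplate":
        offs = {
            tuple(int(s) for s in k.split(",")): tuple(v)
            for k, v in d["global_offset_px"].items()
        }
        return cls(
            global_offset_px=offs,
            mosaic_shape_px=tuple(d["mosaic_shape_px"]),
            um_per_px=d["um_per_px"],
            origin_mm=tuple(d["origin_mm"]),
            sensor_px=tuple(d["sensor_px"]),
            blend=d.get("blend", {"feather_px": 40.0}),
            source_hash=d.get("source_hash", ""),
            residuals=d.get("residuals", []),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "StitchTemplate":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class MosaicFrame:
    """One stitched frame with its object-space sampling."""

    image: np.ndarray
    scale_um_per_px: float
    frame_index: int = 0
    template_id: str = ""
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be > 0")


def _signed_peak(idx: int, n: int) -> int:
    return idx - n if idx > n // 2 else idx


def register_pair(
    image_a: np.ndarray,
    image_b: np.ndarray,
    predicted_offset_px: tuple[float, float],
    search_window_px: float = 30.0,
):
    """Estimate the translation placing image_b relative to image_a.

    The returned offset ``(ox, oy)`` means content at pixel ``(x, y)`` of
    image_b appears at ``(x + ox, y + oy)`` in image_a's frame; it should be
    near ``predicted_offset_px`` (within ``search_window_px``).  Registration
    runs phase correlation on the overlap crops implied by the prediction,
    with Hann windowing, quadratic sub-pixel refinement, and a confidence
    equal to the ratio of the highest to second-highest correlation peak.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN values in registration input")
    ox, oy = (int(round(predicted_offset_px[0])), int(round(predicted_offset_px[1])))
    ha, wa = a.shape
    hb, wb = b.shape
    # overlap in a's frame
    x0, x1 = max(0, ox), min(wa, ox + wb)
    y0, y1 = max(0, oy), min(ha, oy + hb)
    if x1 - x0 < MIN_OVERLAP_PX or y1 - y0 < MIN_OVERLAP_PX:
        raise ValueError(
            f"predicted overlap {x1 - x0}x{y1 - y0} px smaller than {MIN_OVERLAP_PX} px"
        )
    ca = a[y0:y1, x0:x1]
    cb = b[y0 - oy : y1 - oy, x0 - ox : x1 - ox]

    # Tukey tapering: suppresses wrap-around edges while keeping most of the
    # (often thin) overlap strip at full weight
    win = np.outer(tukey(ca.shape[0], 0.4), tukey(ca.shape[1], 0.4))
    fa = np.fft.fft2((ca - ca.mean()) * win)
    fb = np.fft.fft2((cb - cb.mean()) * win)
    cross = fa * np.conj(fb)
    # regularized whitening: pure phase normalization lets noise-dominated
    # high frequencies swamp band-limited scenes; the floor keeps them quiet
    mag = np.abs(cross)
    cross /= mag + 0.03 * mag.mean() + 1e-12
    corr = np.fft.ifft2(cross).real

    h, w = corr.shape
    sw = int(min(search_window_px, h // 2 - 1, w // 2 - 1))
    sw = max(sw, 1)
    # restrict the peak search to +-sw around zero shift (wrapped corners)
    mask = np.zeros_like(corr, dtype=bool)
    mask[: sw + 1, : sw + 1] = True
    mask[: sw + 1, -sw:] = True
    mask[-sw:, : sw + 1] = True
    mask[-sw:, -sw:] = True
    masked = np.where(mask, corr, -np.inf)
    py, px = np.unravel_index(np.argmax(masked), corr.shape)
    peak = corr[py, px]

    # quadratic sub-pixel refinement per axis (wrap-around neighbors)
    def _sub(p, axis_len, cm, c0, cp):
        denom = cm - 2 * c0 + cp
        frac = 0.0 if abs(denom) < 1e-12 else 0.5 * (cm - cp) / denom
        return _signed_peak(p, axis_len) + float(np.clip(frac, -1, 1))

    dy = _sub(py, h, corr[(py - 1) % h, px], peak, corr[(py + 1) % h, px])
    dx = _sub(px, w, corr[py, (px - 1) % w], peak, corr[py, (px + 1) % w])

    # confidence: main peak vs best peak outside a 3-px exclusion zone
    excl = np.ones_like(corr, dtype=bool)
    yy = (np.arange(h)[:, None] - py + h // 2) % h - h // 2
    xx = (np.arange(w)[None, :] - px + w // 2) % w - w // 2
    excl[(np.abs(yy) <= 3) & (np.abs(xx) <= 3)] = False
    second = float(np.max(np.where(mask & excl, corr, -np.inf)))
    confidence = float(peak / max(second, 1e-9)) if second > 0 else float(peak / 1e-9)
    confidence = min(confidence, 1e3)

    # peak (dy, dx) means cb displaced by (dy, dx) matches ca, i.e. image_b
    # must move by +(dx, dy) relative to the prediction
    return (ox + dx, oy + dy), confidence


def predicted_pair_offsets(config: ArrayConfig):
    """Ideal-geometry offsets between rook-adjacent cameras (mosaic px)."""
    pitch_px = config.pitch_mm * 1e3 / config.object_pixel_um
    n_rows, n_cols = config.grid
    pairs = {}
    for r in range(n_rows):
        for c in range(n_cols):
            if c + 1 < n_cols:
                pairs[((r, c), (r, c + 1))] = (pitch_px, 0.0)
            if r + 1 < n_rows:
                pairs[((r, c), (r + 1, c))] = (0.0, pitch_px)
    return pairs


def _frameset_hash(frameset: RawFrameSet) -> str:
    md = hashlib.md5()
    for k in frameset.camera_keys():
        md.update(frameset.frames[k].tobytes()[:65536])
    return md.hexdigest()[:16]


def calibrate_template(
    calibration_frameset: RawFrameSet,
    config: ArrayConfig | None = None,
    search_window_px: float = 30.0,
    min_confidence: float = 1.5,
    feather_px: float | None = None,
) -> StitchTemplate:
    """Estimate the stitching template from a feature-rich frameset.

    Registers all rook-adjacent pairs, then solves global per-camera offsets
    by confidence-weighted least squares with camera (0, 0) anchored.  Raises
    if any camera has no confident path to the anchor.
    """
    config = config or calibration_frameset.array_config
    keys = calibration_frameset.camera_keys()
    n_rows, n_cols = config.grid
    if len(keys) != n_rows * n_cols:
        raise ValueError("calibration frameset does not cover the camera grid")
    rot = {k: calibration_frameset.frames[k][::-1, ::-1].astype(np.float64) for k in keys}
    w_px, h_px = config.camera.sensor_px

    measured = {}
    if len(keys) > 1:
        for (ka, kb), pred in predicted_pair_offsets(config).items():
            try:
                off, conf = register_pair(rot[ka], rot[kb], pred, search_window_px)
            except ValueError:
                continue  # no geometric overlap for this pair
            measured[(ka, kb)] = (off, conf)

    index = {k: i for i, k in enumerate(keys)}
    n = len(keys)
    if measured:
        # connectivity of the confident-pair graph
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for (ka, kb), (_, conf) in measured.items():
            if conf >= min_confidence:
                ra, rb = find(index[ka]), find(index[kb])
                parent[ra] = rb
        root = find(index[(0, 0)])
        for k in keys:
            if find(index[k]) != root:
                raise ValueError(f"camera {k} has no confident registration path to the anchor")

        rows, rhs_x, rhs_y, weights = [], [], [], []
        for (ka, kb), ((mx, my), conf) in measured.items():
            row = np.zeros(n)
            row[index[kb]] = 1.0
            row[index[ka]] = -1.0
            rows.append(row)
            rhs_x.append(mx)
            rhs_y.append(my)
            weights.append(max(min(conf, 50.0), CONF_FLOOR))
        # anchor constraint
        row = np.zeros(n)
        row[index[(0, 0)]] = 1.0
        rows.append(row)
        rhs_x.append(0.0)
        rhs_y.append(0.0)
        weights.append(1e3)
        A = np.asarray(rows) * np.asarray(weights)[:, None]
        sol_x = np.linalg.lstsq(A, np.asarray(rhs_x) * weights, rcond=None)[0]
        sol_y = np.linalg.lstsq(A, np.asarray(rhs_y) * weights, rcond=None)[0]
    else:
        sol_x = np.zeros(n)
        sol_y = np.zeros(n)

    residuals = []
    for (ka, kb), ((mx, my), conf) in measured.items():
        rx = mx - (sol_x[index[kb]] - sol_x[index[ka]])
        ry = my - (sol_y[index[kb]] - sol_y[index[ka]])
        residuals.append(
            {
                "pair": [list(ka), list(kb)],
                "residual_px": [float(rx), float(ry)],
                "confidence": float(conf),
                "flagged": bool(math.hypot(rx, ry) > RESIDUAL_FLAG_PX),
            }
        )

    sol_x -= sol_x.min()
    sol_y -= sol_y.min()
    offsets = {k: (float(sol_x[index[k]]), float(sol_y[index[k]])) for k in keys}
    mosaic_w = int(math.ceil(max(sol_x) + w_px))
    mosaic_h = int(math.ceil(max(sol_y) + h_px))

    obj_px_mm = config.object_pixel_um * 1e-3
    c00 = config.camera_centers_mm()[(0, 0)]
    o00 = offsets[(0, 0)]
    origin = (
        c00[0] - (o00[0] + (w_px - 1) / 2.0) * obj_px_mm,
        c00[1] - (o00[1] + (h_px - 1) / 2.0) * obj_px_mm,
    )
    overlap_px = max((config.fov_xy_mm()[0] - config.pitch_mm) / obj_px_mm, 16.0)
    return StitchTemplate(
        global_offset_px=offsets,
        mosaic_shape_px=(mosaic_w, mosaic_h),
        um_per_px=config.object_pixel_um,
        origin_mm=origin,
        sensor_px=(w_px, h_px),
        blend={"feather_px": float(feather_px if feather_px is not None else overlap_px / 2.0)},
        source_hash=_frameset_hash(calibration_frameset),
        residuals=residuals,
    )


def _feather_weight(shape, feather_px: float) -> np.ndarray:
    h, w = shape
    fx = np.minimum(np.arange(w) + 1.0, w - np.arange(w))
    fy = np.minimum(np.arange(h) + 1.0, h - np.arange(h))
    wx = np.clip(fx / max(feather_px, 1.0), 0.0, 1.0)
    wy = np.clip(fy / max(feather_px, 1.0), 0.0, 1.0)
    return wy[:, None] * wx[None, :]


def apply_template(
    frameset: RawFrameSet,
    template: StitchTemplate,
    blend_mode: str = "feather",
) -> MosaicFrame:
    """Place every (180-degree-rotated) camera image at its template offset.

    ``blend_mode="feather"`` combines overlaps with linear feather weights
    normalized to a partition of unity; ``"overwrite"`` pastes images in
    camera order.
    """
    keys = frameset.camera_keys()
    if sorted(template.global_offset_px) != keys:
        raise ValueError("template camera grid does not match frameset")
    mw, mh = template.mosaic_shape_px
    num = np.zeros((mh, mw), dtype=np.float64)
    den = np.zeros((mh, mw), dtype=np.float64)
    feather = template.blend.get("feather_px", 40.0)

    for k in keys:
        img = frameset.frames[k][::-1, ::-1].astype(np.float64)
        if (img.shape[1], img.shape[0]) != template.sensor_px:
            raise ValueError(f"camera {k} image shape does not match template sensor size")
        ox, oy = template.global_offset_px[k]
        ix, iy = int(math.floor(ox)), int(math.floor(oy))
        frac = (ox - ix, oy - iy)
        if frac != (0.0, 0.0):
            img = nd_shift(img, (frac[1], frac[0]), order=1, mode="nearest")
        h, w = img.shape
        x0, y0 = max(ix, 0), max(iy, 0)
        x1, y1 = min(ix + w, mw), min(iy + h, mh)
        if x0 >= x1 or y0 >= y1:
            continue
        sub = img[y0 - iy : y1 - iy, x0 - ix : x1 - ix]
        if blend_mode == "overwrite":
            num[y0:y1, x0:x1] = sub
            den[y0:y1, x0:x1] = 1.0
        elif blend_mode == "feather":
            wgt = _feather_weight(img.shape, feather)[y0 - iy : y1 - iy, x0 - ix : x1 - ix]
            num[y0:y1, x0:x1] += sub * wgt
            den[y0:y1, x0:x1] += wgt
        else:
            raise ValueError(f"unknown blend_mode {blend_mode!r}")

    mosaic = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0).astype(np.float32)
    return MosaicFrame(
        image=mosaic,
        scale_um_per_px=template.um_per_px,
        frame_index=frameset.frame_index,
        template_id=template.source_hash,
        origin_mm=template.origin_mm,
    )


def world_to_mosaic(template: StitchTemplate, x_mm, y_mm):
    """World (mm) to mosaic pixel coordinates."""
    s = template.um_per_px * 1e-3
    return (
        (np.asarray(x_mm) - template.origin_mm[0]) / s,
        (np.asarray(y_mm) - template.origin_mm[1]) / s,
    )


def mosaic_to_world(template: StitchTemplate, x_px, y_px):
    s = template.um_per_px * 1e-3
    return (
        template.origin_mm[0] + np.asarray(x_px) * s,
        template.origin_mm[1] + np.asarray(y_px) * s,
    )
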