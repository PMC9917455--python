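"""Per-camera preprocessing: flat-field correction and demosaicing.

Flat-field correction divides every raw image by a unit-mean per-pixel gain
map built from the mean of several out-of-focus white-diffuser images (five
by default), removing vignetting and pixel-to-pixel sensitivity variation
within and between cameras.  No dark-frame subtraction is performed (the
division-only model; a dark-frame hook is left as a no-op extension point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import RawFrameSet

__all__ = ["FlatFieldReference", "build_flatfield_reference", "flat_field_correct", "demosaic_bilinear"]

GAIN_FLOOR = 1e-3  # relative to the per-camera mean


@dataclass
class FlatFieldReference:
    """Per-camera unit-mean gain maps.

    ``per_camera_gain[(row, col)]`` is a float image with mean 1 (to 1e-6) and
    strictly positive entries; dividing a raw image by it flattens the field.
    ``floored_pixels`` reports, per camera, how many near-zero pixels were
    clamped to the gain floor (dead-pixel flag).
    """

    per_camera_gain: dict[tuple[int, int], np.ndarray]
    n_source_frames: int
    floored_pixels: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        for key, g in self.per_camera_gain.items():
            if abs(float(g.mean()) - 1.0) > 1e-6:
                raise ValueError(f"gain for camera {key} is not unit-mean")
            if not (g > 0).all():
                raise ValueError(f"gain for camera {key} has non-positive entries")


def build_flatfield_reference(diffuser_framesets: list[RawFrameSet]) -> FlatFieldReference:
    """Build the flat-field reference from diffuser framesets.

    Per camera: the pixelwise mean across framesets is normalized by its own
    global mean, yielding a unit-mean gain map.  The result is invariant to a
    global brightness rescaling of the inputs.  Pixels below ``GAIN_FLOOR``
    of the camera mean (dead pixels) are floored and counted.
    """
    if not diffuser_framesets:
        raise ValueError("need at least one diffuser frameset")
    keys = diffuser_framesets[0].camera_keys()
    shape = diffuser_framesets[0].frames[keys[0]].shape
    for fs in diffuser_framesets:
        if fs.camera_keys() != keys:
            raise ValueError("diffuser framesets cover different camera grids")
        if any(fs.frames[k].shape != shape for k in keys):
            raise ValueError("diffuser framesets have inconsistent image shapes")

    gains, floored = {}, {}
    for k in keys:
        acc = np.zeros(shape, dtype=np.float64)
        for fs in diffuser_framesets:
            acc += fs.frames[k].astype(np.float64)
        mean_img = acc / len(diffuser_framesets)
        g = mean_img / max(mean_img.mean(), 1e-12)
        low = g < GAIN_FLOOR
        floored[k] = int(low.sum())
        if low.any():
            g = np.where(low, GAIN_FLOOR, g)
        g = g / g.mean()  # restore unit mean after flooring
        gains[k] = g
    return FlatFieldReference(
        per_camera_gain=gains,
        n_source_frames=len(diffuser_framesets),
        floored_pixels=floored,
    )


def flat_field_correct(frameset: RawFrameSet, reference: FlatFieldReference) -> RawFrameSet:
    """Divide each image by its camera's gain map; dtype and range preserved."""
    keys = frameset.camera_keys()
    if sorted(reference.per_camera_gain) != keys:
        raise ValueError("reference camera grid does not match frameset")
    out = {}
    for k in keys:
        img = frameset.frames[k]
        g = reference.per_camera_gain[k]
        if g.shape != img.shape:
            raise ValueError(f"gain shape {g.shape} != image shape {img.shape} for camera {k}")
        info = np.iinfo(img.dtype)
        corrected = np.clip(np.round(img.astype(np.float64) / g), info.min, info.max)
        out[k] = corrected.astype(img.dtype)
    return RawFrameSet(
        frames=out,
        array_config=frameset.array_config,
        frame_index=frameset.frame_index,
        bayer_pattern=frameset.bayer_pattern,
        ground_truth=frameset.ground_truth,
        timestamp_s=frameset.timestamp_s,
    )


def demosaic_bilinear(bayer_image: np.ndarray, pattern: str = "RGGB") -> np.ndarray:
    """Bilinear demosaic of an RGGB Bayer mosaic to a float RGB image.

    Each channel is interpolated at its missing sites from the nearest
    sampled neighbors (edge-replicated).  Output has the input's spatial size
    with 3 channels, float64 in the input's value range.
    """
    if pattern != "RGGB":
        raise ValueError(f"unsupported Bayer pattern {pattern!r}")
    img = np.asarray(bayer_image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] % 2 or img.shape[1] % 2:
        raise ValueError("Bayer image must be 2-D with even dimensions")

    h, w = img.shape
    pad = np.pad(img, 2, mode="reflect")

    def avg(*offsets):
        return sum(pad[2 + dy : 2 + dy + h, 2 + dx : 2 + dx + w] for dy, dx in offsets) / len(offsets)

    r_mask = np.zeros((h, w), bool)
    r_mask[0::2, 0::2] = True
    b_mask = np.zeros((h, w), bool)
    b_mask[1::2, 1::2] = True
    g_mask = ~(r_mask | b_mask)

    # green: average of 4-neighbors at R/B sites
    g = np.where(g_mask, img, avg((0, -1), (0, 1), (-1, 0), (1, 0)))
    # red: same-row neighbors on G(R-row) sites, same-column on G(B-row) sites,
    # diagonals on B sites
    r = img.copy()
    gr = np.zeros((h, w), bool)
    gr[0::2, 1::2] = True  # green on red rows
    gb = np.zeros((h, w), bool)
    gb[1::2, 0::2] = True  # green on blue rows
    r = np.where(gr, avg((0, -1), (0, 1)), r)
    r = np.where(gb, avg((-1, 0), (1, 0)), r)
    r = np.where(b_mask, avg((-1, -1), (-1, 1), (1, -1), (1, 1)), r)
    b = img.copy()
    b = np.where(gb, avg((0, -1), (0, 1)), b)
    b = np.where(gr, avg((-1, 0), (1, 0)), b)
    b = np.where(r_mask, avg((-1, -1), (-1, 1), (1, -1), (1, 1)), b)
    return np.stack([r, g, b], axis=-1)
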