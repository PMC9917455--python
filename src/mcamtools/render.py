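"""Per-camera image formation for simulated scenes.

The optical model is deliberately minimal but geometrically exact where it
matters for the pipeline:

* Each camera projects world points through a thin lens: a point ``p`` at
  object distance ``u`` maps to sensor coordinate ``-m(u) * (p - c)`` about
  the image center, where ``c`` is the camera's optical-axis position and
  ``m(u) = f / (u - f)``.  The image inversion means raw frames are rotated
  180 degrees relative to the world; the stitcher un-rotates them.
* Perspective parallax within a single camera is neglected (telecentric-like
  local model, exact on the camera axis); parallax enters only *between*
  cameras through the baseline, which is exactly the disparity model the
  depth pipeline inverts.
* Defocus is a Gaussian blur with object-space sigma
  ``defocus_coeff * |z| * NA`` (sigma in the same units as z), a linear
  small-defocus model.
* Vignetting multiplies intensity by cos^4 of the field angle.
* Noise: Poisson shot noise at a configurable full-scale photon count plus
  Gaussian read noise, then quantization to 8 or 16 bits.

All randomness flows from a single integer seed; identical seeds give
bit-identical framesets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .optics import ArrayConfig, magnification, object_space_fov
from .simulate import OrganismSpec, RawFrameSet, SceneSpec

__all__ = [
    "NoiseParams",
    "RenderOptions",
    "render_frameset",
    "make_diffuser_frames",
    "render_organism_crop",
    "rasterize_scene",
    "organism_world_bbox",
    "draw_organism",
    "vignette_profile",
]


@dataclass(frozen=True)
class NoiseParams:
    """Sensor noise model: Poisson shot noise + Gaussian read noise."""

    enabled: bool = True
    photon_full_scale: float = 30000.0
    read_noise_dn8: float = 1.0  # read noise in 8-bit DN


@dataclass(frozen=True)
class RenderOptions:
    vignetting: bool = True
    vignetting_scale: float = 1.0  # multiplies the field angle (test knob)
    defocus: bool = True
    defocus_coeff: float = 0.5


# --------------------------------------------------------------------------
# organism geometry and drawing


def _radius_profile(kind: str, s: np.ndarray, half_width: float) -> np.ndarray:
    """Body half-width as a function of normalized arc position s in [0, 1]."""
    if kind == "fish":
        knots_s = np.array([0.0, 0.10, 0.30, 0.55, 0.80, 1.0])
        knots_r = np.array([0.45, 1.00, 0.92, 0.55, 0.28, 0.10])
        return half_width * np.interp(s, knots_s, knots_r)
    # worm: near-constant with rounded tips
    taper = np.sqrt(np.clip(4.0 * s * (1.0 - s) * 6.0, 0.0, 1.0))
    return half_width * taper


def organism_spine(org: OrganismSpec) -> np.ndarray:
    """Spine polyline in the organism's local frame (head at +x), shape (n+1, 2)."""
    n_seg = len(org.articulation) + 1
    seg = org.length_mm / n_seg
    pts = [np.array([org.length_mm / 2.0, 0.0])]
    phi = math.pi  # tail-ward
    bends = list(org.articulation) + [0.0]
    for i in range(n_seg):
        pts.append(pts[-1] + seg * np.array([math.cos(phi), math.sin(phi)]))
        phi += bends[i]
    return np.stack(pts)


def _polyline_dist(px: np.ndarray, py: np.ndarray, pts: np.ndarray):
    """Min distance of points to a polyline plus normalized arc position."""
    A, B = pts[:-1], pts[1:]
    AB = B - A
    seg_len = np.hypot(AB[:, 0], AB[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = max(cum[-1], 1e-12)
    P = np.stack([px.ravel(), py.ravel()], axis=1)
    dx = P[:, None, 0] - A[None, :, 0]
    dy = P[:, None, 1] - A[None, :, 1]
    L2 = np.maximum(seg_len**2, 1e-12)
    t = np.clip((dx * AB[None, :, 0] + dy * AB[None, :, 1]) / L2, 0.0, 1.0)
    ex = dx - t * AB[None, :, 0]
    ey = dy - t * AB[None, :, 1]
    d2 = ex**2 + ey**2
    k = np.argmin(d2, axis=1)
    idx = np.arange(len(P))
    dist = np.sqrt(d2[idx, k])
    s = (cum[k] + t[idx, k] * seg_len[k]) / total
    return dist.reshape(px.shape), s.reshape(px.shape)


def _identity_texture(org: OrganismSpec):
    """Fixed per-identity speckle raster in the local frame.

    Anchored to the organism so the same individual shows the same pattern in
    every camera and frame (melanophore-pattern stand-in).  Fish carry coarse
    blotches (resolvable in small identity crops); beads and worms carry fine
    speckle (dense corner features for stereo matching).
    """
    if org.kind == "fish":
        scale_mm = max(0.08, 0.28 * org.width_mm)
    else:
        scale_mm = max(0.05, 0.12 * org.width_mm)
    half = 0.75 * org.length_mm
    tex_mm = scale_mm / 2.5
    n = max(16, int(math.ceil(2 * half / tex_mm)))
    rng = np.random.default_rng([int(org.identity_texture_seed) % (2**31), 777])
    raw = rng.normal(size=(n, n))
    tex = gaussian_filter(raw, scale_mm / tex_mm, mode="wrap")
    tex /= max(tex.std(), 1e-9)
    return tex, half, tex_mm


def _sample_texture(org: OrganismSpec, xl: np.ndarray, yl: np.ndarray) -> np.ndarray:
    tex, half, tex_mm = _identity_texture(org)
    ci = (yl + half) / tex_mm - 0.5
    cj = (xl + half) / tex_mm - 0.5
    return map_coordinates(tex, [ci, cj], order=1, mode="wrap")


def draw_organism(org: OrganismSpec, x_mm: np.ndarray, y_mm: np.ndarray, soft_mm: float):
    """Evaluate organism coverage and intensity at world coordinates.

    Returns ``(alpha, value)`` arrays shaped like ``x_mm``: alpha is a soft
    [0, 1] coverage mask (edge softness ``soft_mm``), value the organism
    surface intensity in [0, 1].
    """
    cx, cy = org.position_mm
    ch, sh = math.cos(org.heading_rad), math.sin(org.heading_rad)
    xl = ch * (x_mm - cx) + sh * (y_mm - cy)
    yl = -sh * (x_mm - cx) + ch * (y_mm - cy)
    soft = max(soft_mm, 1e-6)

    if org.kind == "blob":
        a, b = org.length_mm / 2.0, org.width_mm / 2.0
        e = np.sqrt((xl / a) ** 2 + (yl / b) ** 2)
        alpha = np.clip((1.0 - e) * (b / soft) + 0.5, 0.0, 1.0)
        value = np.full_like(xl, 0.30)
        return alpha, value

    if org.kind == "point_bead":
        r = org.length_mm / 2.0
        d = np.hypot(xl, yl)
        alpha = np.clip((r - d) / soft + 0.5, 0.0, 1.0)
        t = _sample_texture(org, xl, yl)
        value = np.clip(0.45 + 0.30 * t, 0.02, 0.95)
        return alpha, value

    pts = organism_spine(org)
    dist, s = _polyline_dist(xl, yl, pts)
    rho = _radius_profile(org.kind, s, org.width_mm / 2.0)
    alpha = np.clip((rho - dist) / soft + 0.5, 0.0, 1.0)
    t = _sample_texture(org, xl, yl)
    if org.kind == "fish":
        # body speckle floor (0.10) stays clearly above the eye value (0.02)
        # so the eyes remain the darkest head structures
        value = np.clip(0.40 - 0.16 * np.clip(t, -1.8, 1.8), 0.10, 0.9)
        if org.eye_angles_rad is not None:
            L, w = org.length_mm, org.width_mm
            a_e, b_e = 0.055 * L, 0.030 * L
            for side, ang in zip((+1.0, -1.0), org.eye_angles_rad):
                ex_c, ey_c = 0.32 * L, side * 0.22 * w / 0.9 * 0.9
                ca, sa = math.cos(ang), math.sin(ang)
                u = ca * (xl - ex_c) + sa * (yl - ey_c)
                v = -sa * (xl - ex_c) + ca * (yl - ey_c)
                e = np.sqrt((u / a_e) ** 2 + (v / b_e) ** 2)
                ea = np.clip((1.0 - e) * (b_e / soft) + 0.5, 0.0, 1.0)
                value = value * (1 - ea) + 0.02 * ea
                alpha = np.maximum(alpha, ea)
    else:  # worm
        value = np.clip(0.35 + 0.08 * t, 0.05, 0.9)
    return alpha, value


def organism_world_bbox(org: OrganismSpec, margin_mm: float = 0.0):
    """Axis-aligned world bounding box (x0, y0, x1, y1) of the organism."""
    cx, cy = org.position_mm
    if org.kind in ("blob", "point_bead"):
        hx = org.length_mm / 2.0
        hy = org.width_mm / 2.0 if org.kind == "blob" else hx
        ch, sh = abs(math.cos(org.heading_rad)), abs(math.sin(org.heading_rad))
        ex = ch * hx + sh * hy
        ey = sh * hx + ch * hy
        return (cx - ex - margin_mm, cy - ey - margin_mm, cx + ex + margin_mm, cy + ey + margin_mm)
    pts = organism_spine(org)
    ch, sh = math.cos(org.heading_rad), math.sin(org.heading_rad)
    wx = cx + ch * pts[:, 0] - sh * pts[:, 1]
    wy = cy + sh * pts[:, 0] + ch * pts[:, 1]
    r = org.width_mm / 2.0 + margin_mm
    return (wx.min() - r, wy.min() - r, wx.max() + r, wy.max() + r)


# --------------------------------------------------------------------------
# background


def background_raster(scene: SceneSpec, seed_salt: int = 0) -> tuple[np.ndarray, float]:
    """Deterministic background raster over the scene extent.

    Generated at the fixed resolution stated in the background descriptor so
    every camera (and the ground-truth rasterizer) samples the *same* world
    pattern.  Returns (raster, raster_px_mm).
    """
    bg = scene.background
    level = bg.get("level", 0.85)
    res_mm = bg.get("raster_um_per_px", 25.0) * 1e-3
    ex, ey = scene.extent_mm
    w = max(2, int(round(ex / res_mm)))
    h = max(2, int(round(ey / res_mm)))
    raster = np.full((h, w), level, dtype=np.float64)
    amp = bg.get("texture_amp", 0.0)
    rng = np.random.default_rng([int(bg.get("seed", 0)) % (2**31), 31337 + seed_salt])
    if amp > 0:
        sigma = max(bg.get("texture_scale_mm", 0.5) / res_mm, 0.5)
        t = gaussian_filter(rng.normal(size=(h, w)), sigma)
        t /= max(t.std(), 1e-9)
        raster *= 1.0 + amp * t
    n_feat = int(bg.get("n_features", 0))
    if n_feat > 0:
        fr = bg.get("feature_size_mm", 1.5) / 2.0 / res_mm
        yy, xx = np.mgrid[0:h, 0:w]
        for k in range(n_feat):
            fx, fy = rng.uniform(0, w), rng.uniform(0, h)
            rad = fr * rng.uniform(0.5, 1.4)
            contrast = (0.35 if k % 2 == 0 else -0.45) * level
            mask = np.clip(rad - np.hypot(xx - fx, yy - fy) + 0.5, 0.0, 1.0)
            raster += contrast * mask
    return np.clip(raster, 0.0, 1.2), res_mm


def _sample_background(raster, res_mm, scene, x_mm, y_mm):
    ex, ey = scene.extent_mm
    ci = (y_mm + ey / 2.0) / res_mm - 0.5
    cj = (x_mm + ex / 2.0) / res_mm - 0.5
    return map_coordinates(raster, [ci, cj], order=1, mode="nearest")


def vignette_profile(shape, pixel_mm: float, focal_mm: float, scale: float = 1.0) -> np.ndarray:
    """cos^4 falloff over a sensor of the given (h, w) shape."""
    h, w = shape
    jj = (np.arange(w) - (w - 1) / 2.0) * pixel_mm * scale
    ii = (np.arange(h) - (h - 1) / 2.0) * pixel_mm * scale
    r2 = ii[:, None] ** 2 + jj[None, :] ** 2
    return (focal_mm**2 / (focal_mm**2 + r2)) ** 2


# --------------------------------------------------------------------------
# rendering


def _quantize(img, bit_depth, rng, noise: NoiseParams):
    img = np.clip(img, 0.0, 1.0)
    if noise.enabled:
        n = noise.photon_full_scale
        img = rng.poisson(img * n).astype(np.float64) / n
        img = img + rng.normal(0.0, noise.read_noise_dn8 / 255.0, img.shape)
    full = (1 << bit_depth) - 1
    return np.clip(np.round(img * full), 0, full).astype(np.uint8 if bit_depth == 8 else np.uint16)


def render_frameset(
    scene: SceneSpec,
    config: ArrayConfig,
    seed: int = 0,
    noise: NoiseParams | None = None,
    options: RenderOptions | None = None,
    cameras: list[tuple[int, int]] | None = None,
    bit_depth: int = 8,
    bayer: bool = False,
    frame_index: int = 0,
) -> RawFrameSet:
    """Render one scene into a per-camera raw frameset.

    ``cameras`` restricts rendering to a subset of grid positions (all by
    default).  With ``bayer=True`` the (grayscale) scene is sampled through an
    RGGB mosaic with unit channel gains; the returned frameset records the
    pattern.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    if config.long_axis != "grid_x":
        raise NotImplementedError("renderer assumes long_axis='grid_x'")
    noise = noise if noise is not None else NoiseParams()
    options = options or RenderOptions()
    cam = config.camera
    f = cam.focal_length_mm
    u0 = config.working_distance_mm
    m0 = config.magnification
    px_mm = cam.pixel_pitch_um * 1e-3
    w, h = cam.sensor_px
    centers = config.camera_centers_mm()
    keys = cameras if cameras is not None else sorted(centers)

    bg = scene.background
    has_texture = bg.get("texture_amp", 0.0) > 0 or int(bg.get("n_features", 0)) > 0
    raster = res_mm = None
    if has_texture:
        raster, res_mm = background_raster(scene)

    frames = {}
    for key in keys:
        cx, cy = centers[key]
        delta0 = px_mm / m0  # object-space pixel at the focal plane, mm
        jj = np.arange(w, dtype=np.float64)
        ii = np.arange(h, dtype=np.float64)
        xw = cx - (jj - (w - 1) / 2.0) * delta0
        yw = cy - (ii - (h - 1) / 2.0) * delta0
        if has_texture:
            Xw, Yw = np.meshgrid(xw, yw)
            img = _sample_background(raster, res_mm, scene, Xw, Yw)
        else:
            img = np.full((h, w), bg.get("level", 0.85), dtype=np.float64)
        img = img * scene.illumination
        if options.vignetting:
            img *= vignette_profile((h, w), px_mm, f, options.vignetting_scale)

        for org in scene.organisms:
            u = u0 - org.z_mm
            if u <= f:
                raise ValueError(f"organism z={org.z_mm} puts it inside the focal length")
            m = magnification(f, u)
            delta = px_mm / m
            blur_obj_mm = (
                options.defocus_coeff * abs(org.z_mm) * cam.numerical_aperture
                if options.defocus
                else 0.0
            )
            x0, y0, x1, y1 = organism_world_bbox(org, margin_mm=3 * blur_obj_mm + 3 * delta)
            # world -> pixel (decreasing): j = (cx - x)/delta + (w-1)/2
            j0 = int(math.floor((cx - x1) / delta + (w - 1) / 2.0))
            j1 = int(math.ceil((cx - x0) / delta + (w - 1) / 2.0)) + 1
            i0 = int(math.floor((cy - y1) / delta + (h - 1) / 2.0))
            i1 = int(math.ceil((cy - y0) / delta + (h - 1) / 2.0)) + 1
            j0, j1 = max(j0, 0), min(j1, w)
            i0, i1 = max(i0, 0), min(i1, h)
            if j0 >= j1 or i0 >= i1:
                continue  # outside this camera's FOV: rendered absent
            jx = cx - (np.arange(j0, j1) - (w - 1) / 2.0) * delta
            iy = cy - (np.arange(i0, i1) - (h - 1) / 2.0) * delta
            Xc, Yc = np.meshgrid(jx, iy)
            alpha, value = draw_organism(org, Xc, Yc, soft_mm=delta)
            if blur_obj_mm > 0:
                sig_px = blur_obj_mm / delta
                va = gaussian_filter(value * alpha, sig_px)
                alpha = gaussian_filter(alpha, sig_px)
                value_alpha = va
            else:
                value_alpha = value * alpha
            crop = img[i0:i1, j0:j1]
            img[i0:i1, j0:j1] = crop * (1.0 - alpha) + value_alpha

        rng = np.random.default_rng(
            [int(seed) % (2**31), frame_index, 7000 + key[0], key[1]]
        )
        frames[key] = _quantize(img, bit_depth, rng, noise)

    return RawFrameSet(
        frames=frames,
        array_config=config,
        frame_index=frame_index,
        bayer_pattern="RGGB" if bayer else "none",
        ground_truth=scene,
        timestamp_s=scene.timestamp_s,
    )


def make_diffuser_frames(
    config: ArrayConfig,
    n: int = 5,
    seed: int = 0,
    noise: NoiseParams | None = None,
    options: RenderOptions | None = None,
    level: float = 0.85,
    cameras: list[tuple[int, int]] | None = None,
) -> list[RawFrameSet]:
    """Render n featureless bright-field framesets (white-diffuser images).

    These pass through the same vignetting and noise model as real frames and
    are the inputs to flat-field reference construction.  Default n=5.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .simulate import make_diffuser_scene

    _, (sx, sy) = object_space_fov(config)
    scene = make_diffuser_scene((sx + 10.0, sy + 10.0), level=level)
    return [
        render_frameset(
            scene, config, seed=seed, noise=noise, options=options,
            cameras=cameras, frame_index=k,
        )
        for k in range(n)
    ]


def render_organism_crop(
    org: OrganismSpec,
    um_per_px: float,
    pad_mm: float = 0.5,
    level: float = 0.85,
    centered: bool = True,
) -> np.ndarray:
    """Object-space float image of one organism (world-oriented, x right).

    Used for identity-crop generation and kinematics tests; no optics, noise
    or inversion.
    """
    res = um_per_px * 1e-3
    x0, y0, x1, y1 = organism_world_bbox(org, margin_mm=pad_mm)
    if centered:
        cx, cy = org.position_mm
        half = max(x1 - x0, y1 - y0) / 2.0
        x0, x1, y0, y1 = cx - half, cx + half, cy - half, cy + half
    nx = int(math.ceil((x1 - x0) / res))
    ny = int(math.ceil((y1 - y0) / res))
    xs = x0 + (np.arange(nx) + 0.5) * res
    ys = y0 + (np.arange(ny) + 0.5) * res
    X, Y = np.meshgrid(xs, ys)
    alpha, value = draw_organism(org, X, Y, soft_mm=res)
    return np.clip(level * (1.0 - alpha) + value * alpha, 0.0, 1.0)


def rasterize_scene(scene: SceneSpec, um_per_px: float) -> np.ndarray:
    """Ground-truth object-space raster of the whole scene (world-oriented).

    z offsets and all per-camera optics are ignored; this is the reference
    image a perfect stitcher would reproduce.
    """
    res = um_per_px * 1e-3
    ex, ey = scene.extent_mm
    w = int(round(ex / res))
    h = int(round(ey / res))
    xs = -ex / 2.0 + (np.arange(w) + 0.5) * res
    ys = -ey / 2.0 + (np.arange(h) + 0.5) * res
    bg = scene.background
    if bg.get("texture_amp", 0.0) > 0 or int(bg.get("n_features", 0)) > 0:
        raster, res_mm = background_raster(scene)
        X, Y = np.meshgrid(xs, ys)
        img = _sample_background(raster, res_mm, scene, X, Y)
    else:
        img = np.full((h, w), bg.get("level", 0.85), dtype=np.float64)
    for org in scene.organisms:
        x0, y0, x1, y1 = organism_world_bbox(org, margin_mm=3 * res)
        j0 = max(int((x0 + ex / 2) / res), 0)
        j1 = min(int(math.ceil((x1 + ex / 2) / res)) + 1, w)
        i0 = max(int((y0 + ey / 2) / res), 0)
        i1 = min(int(math.ceil((y1 + ey / 2) / res)) + 1, h)
        if j0 >= j1 or i0 >= i1:
            continue
        X, Y = np.meshgrid(xs[j0:j1], ys[i0:i1])
        alpha, value = draw_organism(org, X, Y, soft_mm=res)
        img[i0:i1, j0:j1] = img[i0:i1, j0:j1] * (1 - alpha) + value * alpha
    return np.clip(img, 0.0, 1.2)
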