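"""Ground-truthed scene synthesis for camera-array imaging.

A :class:`SceneSpec` is a complete world description -- arena extent,
background texture, illumination and a list of organisms with known 3-D poses
-- from which the renderer (:mod:`mcamtools.render`) produces per-camera raw
framesets.  Because the world is known exactly, every downstream stage
(stitching, detection, depth, identity, kinematics) can be scored against
ground truth without any recorded data.

Organism kinds:

fish
    Articulated tapered body with per-joint tail-bend angles, two dark
    elliptical eyes, and a per-identity speckle texture emulating the
    idiosyncratic melanophore pigmentation pattern that makes individual
    larval zebrafish visually distinguishable.
worm
    Thin undulating capsule (nematode-like).
blob
    Featureless dark ellipse (debris, aggregates).
point_bead
    Speckle-textured disc used as a stereo-depth and resolution target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .optics import ArrayConfig

__all__ = [
    "OrganismSpec",
    "SceneSpec",
    "RawFrameSet",
    "MotionParams",
    "make_calibration_scene",
    "make_diffuser_scene",
    "simulate_session",
]

ORGANISM_KINDS = ("fish", "worm", "blob", "point_bead")


@dataclass
class OrganismSpec:
    """Pose and appearance of a single organism.

    ``position_mm`` is the body center in world coordinates (origin at the
    array center); ``z_mm`` is the signed offset from the plane of best focus,
    positive toward the cameras.  ``articulation`` holds tail-joint bend
    angles (radians) ordered head to tail.  ``identity_texture_seed`` selects
    the individual's fixed speckle texture.
    """

    kind: str = "fish"
    position_mm: tuple[float, float] = (0.0, 0.0)
    z_mm: float = 0.0
    heading_rad: float = 0.0
    length_mm: float = 4.0
    width_mm: float = 0.9
    articulation: tuple[float, ...] = ()
    identity_texture_seed: int = 0
    eye_angles_rad: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ORGANISM_KINDS:
            raise ValueError(f"unknown organism kind {self.kind!r}")
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("organism sizes must be > 0")
        if any(abs(a) >= math.pi for a in self.articulation):
            raise ValueError("articulation angles must satisfy |angle| < pi")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "position_mm": list(self.position_mm),
            "z_mm": self.z_mm,
            "heading_rad": self.heading_rad,
            "length_mm": self.length_mm,
            "width_mm": self.width_mm,
            "articulation": list(self.articulation),
            "identity_texture_seed": self.identity_texture_seed,
            "eye_angles_rad": None if self.eye_angles_rad is None else list(self.eye_angles_rad),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrganismSpec":
        d = dict(d)
        d["position_mm"] = tuple(d["position_mm"])
        d["articulation"] = tuple(d.get("articulation", ()))
        ea = d.get("eye_angles_rad")
        d["eye_angles_rad"] = None if ea is None else tuple(ea)
        return cls(**d)


def default_background(level: float = 0.85) -> dict:
    """Background descriptor: uniform bright field, no texture."""
    return {
        "level": level,
        "texture_amp": 0.0,
        "texture_scale_mm": 0.5,
        "n_features": 0,
        "feature_size_mm": 1.5,
        "raster_um_per_px": 25.0,
        "seed": 0,
    }


@dataclass
class SceneSpec:
    """World description at one instant.

    ``extent_mm`` is the (x, y) size of the world rectangle, centered on the
    origin; organisms must lie inside it.  ``illumination`` is a global gain
    applied on top of per-camera vignetting.
    """

    extent_mm: tuple[float, float] = (60.0, 40.0)
    background: dict = field(default_factory=default_background)
    organisms: list[OrganismSpec] = field(default_factory=list)
    illumination: float = 1.0
    timestamp_s: float = 0.0

    def __post_init__(self):
        ex, ey = self.extent_mm
        if ex <= 0 or ey <= 0:
            raise ValueError("extent must be positive")
        for org in self.organisms:
            x, y = org.position_mm
            if abs(x) > ex / 2 or abs(y) > ey / 2:
                raise ValueError(
                    f"organism at {org.position_mm} outside extent {self.extent_mm}"
                )

    def to_dict(self) -> dict:
        return {
            "extent_mm": list(self.extent_mm),
            "background": dict(self.background),
            "organisms": [o.to_dict() for o in self.organisms],
            "illumination": self.illumination,
            "timestamp_s": self.timestamp_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            extent_mm=tuple(d["extent_mm"]),
            background=dict(d["background"]),
            organisms=[OrganismSpec.from_dict(o) for o in d.get("organisms", [])],
            illumination=d.get("illumination", 1.0),
            timestamp_s=d.get("timestamp_s", 0.0),
        )


@dataclass
class RawFrameSet:
    """Time-indexed per-camera raw images plus acquisition metadata.

    ``frames`` maps grid index (row, col) to a 2-D uint8/uint16 image; all
    images share the sensor dimensions of ``array_config``.
    """

    frames: dict[tuple[int, int], np.ndarray]
    array_config: ArrayConfig
    frame_index: int = 0
    bayer_pattern: str = "none"
    ground_truth: SceneSpec | None = None
    timestamp_s: float = 0.0

    def __post_init__(self):
        shapes = {im.shape for im in self.frames.values()}
        if len(shapes) > 1:
            raise ValueError(f"frames have inconsistent shapes: {shapes}")

    def camera_keys(self) -> list[tuple[int, int]]:
        return sorted(self.frames)


def make_calibration_scene(
    extent_mm: tuple[float, float],
    feature_density: float = 1.0,
    seed: int = 0,
    level: float = 0.75,
) -> SceneSpec:
    """A feature-rich target scene used to estimate the stitching template.

    The background carries band-limited random texture plus scattered
    high-contrast features (alternating dark/bright discs), emulating the
    complex natural-scene targets captured at the start of a session to
    calibrate stitching.  ``feature_density`` is features per cm^2; 0 gives a
    uniform background.  Deterministic given ``seed``.
    """
    if feature_density < 0:
        raise ValueError("feature_density must be >= 0")
    bg = default_background(level)
    if feature_density > 0:
        area_cm2 = extent_mm[0] * extent_mm[1] / 100.0
        bg.update(
            texture_amp=0.18,
            texture_scale_mm=0.35,
            n_features=int(round(feature_density * area_cm2)),
            feature_size_mm=1.2,
            seed=int(seed),
        )
    return SceneSpec(extent_mm=extent_mm, background=bg, organisms=[])


def make_diffuser_scene(extent_mm: tuple[float, float], level: float = 0.85) -> SceneSpec:
    """Featureless bright field (out-of-focus white diffuser)."""
    return SceneSpec(extent_mm=extent_mm, background=default_background(level), organisms=[])


@dataclass
class MotionParams:
    """Per-organism random-walk motion model.

    Headings follow a wrapped diffusion (``heading_diffusion_rad`` per sqrt
    second); speeds are gamma-distributed with the stated mean and coefficient
    of variation; centers reflect off arena walls; z performs a clipped random
    walk within ``z_range_mm``; tail articulation follows a smooth
    Ornstein-Uhlenbeck bend process.
    """

    mean_speed_mm_s: float = 5.0
    speed_cv: float = 0.35
    heading_diffusion_rad: float = 0.8
    z_walk_std_mm: float = 0.15
    z_range_mm: float = 2.5
    n_joints: int = 5
    bend_std_rad: float = 0.35
    bend_relaxation: float = 0.5
    min_separation_mm: float = 0.0


def _reflect(value: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2 * span)
    return lo + (span - abs(v - span))


def simulate_session(
    n_organisms: int,
    kind: str = "fish",
    arena_mm: tuple[float, float, float, float] = (-25.0, -15.0, 25.0, 15.0),
    motion: MotionParams | None = None,
    n_frames: int = 10,
    dt_s: float = 1.0,
    seed: int = 0,
    extent_mm: tuple[float, float] | None = None,
    length_mm: float = 4.0,
    width_mm: float = 0.9,
    z_enabled: bool = False,
) -> list[SceneSpec]:
    """Simulate a freely behaving cohort; returns one SceneSpec per frame.

    ``arena_mm`` is (x0, y0, x1, y1) and must fit inside the scene extent
    (default: extent equals the arena plus a 2 mm margin).  Identities
    (``identity_texture_seed``) persist across frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    motion = motion or MotionParams()
    x0, y0, x1, y1 = arena_mm
    if extent_mm is None:
        extent_mm = (2 * max(abs(x0), abs(x1)) + 4.0, 2 * max(abs(y0), abs(y1)) + 4.0)
    if x1 - x0 > extent_mm[0] or y1 - y0 > extent_mm[1]:
        raise ValueError("arena larger than scene extent")

    rng = np.random.default_rng([int(seed), 2718])
    n = int(n_organisms)

    def _resolve_separation(p):
        """Push violating pairs apart symmetrically until separated (or give up)."""
        sep = motion.min_separation_mm
        if sep <= 0 or n < 2:
            return p
        for _ in range(60):
            dx = p[:, None, 0] - p[None, :, 0]
            dy = p[:, None, 1] - p[None, :, 1]
            r = np.hypot(dx, dy)
            iu, ju = np.triu_indices(n, k=1)
            bad = r[iu, ju] < sep
            if not bad.any():
                break
            for i, j in zip(iu[bad], ju[bad]):
                rij = r[i, j]
                if rij < 1e-9:
                    ang = rng.uniform(0, 2 * math.pi)
                    u = np.array([math.cos(ang), math.sin(ang)])
                    rij = 0.0
                else:
                    u = (p[i] - p[j]) / rij
                push = 0.55 * (sep - rij)
                p[i] = np.clip(p[i] + push * u, [x0, y0], [x1, y1])
                p[j] = np.clip(p[j] - push * u, [x0, y0], [x1, y1])
        return p

    pos = rng.uniform([x0, y0], [x1, y1], size=(n, 2)) if n else np.empty((0, 2))
    pos = _resolve_separation(pos)
    heading = rng.uniform(0, 2 * math.pi, n)
    z = np.zeros(n)
    bend = np.zeros((n, motion.n_joints))

    scenes: list[SceneSpec] = []
    for t in range(n_frames):
        if t > 0:
            speed = rng.gamma(
                1.0 / motion.speed_cv**2,
                motion.mean_speed_mm_s * motion.speed_cv**2,
                n,
            )
            heading = heading + motion.heading_diffusion_rad * math.sqrt(dt_s) * rng.normal(size=n)
            pos = pos + (speed * dt_s)[:, None] * np.c_[np.cos(heading), np.sin(heading)]
            for i in range(n):
                nx, ny = pos[i]
                if not (x0 <= nx <= x1):
                    heading[i] = math.pi - heading[i]
                if not (y0 <= ny <= y1):
                    heading[i] = -heading[i]
                pos[i] = (_reflect(nx, x0, x1), _reflect(ny, y0, y1))
            if motion.min_separation_mm > 0:
                pos = _resolve_separation(pos)
            if z_enabled:
                z = np.clip(
                    z + motion.z_walk_std_mm * math.sqrt(dt_s) * rng.normal(size=n),
                    -motion.z_range_mm,
                    motion.z_range_mm,
                )
            bend = bend * math.exp(-motion.bend_relaxation * dt_s) + (
                motion.bend_std_rad
                * math.sqrt(1 - math.exp(-2 * motion.bend_relaxation * dt_s))
                * rng.normal(size=bend.shape)
            )

        organisms = []
        for i in range(n):
            organisms.append(
                OrganismSpec(
                    kind=kind,
                    position_mm=(float(pos[i, 0]), float(pos[i, 1])),
                    z_mm=float(z[i]),
                    heading_rad=float(heading[i] % (2 * math.pi)),
                    length_mm=length_mm,
                    width_mm=width_mm,
                    articulation=tuple(np.clip(bend[i] / motion.n_joints, -0.5, 0.5))
                    if kind in ("fish", "worm")
                    else (),
                    identity_texture_seed=i,
                    eye_angles_rad=(0.15, -0.15) if kind == "fish" else None,
                )
            )
        scenes.append(
            SceneSpec(
                extent_mm=extent_mm,
                background=default_background(),
                organisms=organisms,
                timestamp_s=t * dt_s,
            )
        )
    return scenes
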