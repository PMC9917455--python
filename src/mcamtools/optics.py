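"""Thin-lens geometry for multi-camera array microscopes.

All geometric conversions used by the simulator, stitcher and depth pipeline
live here.  The model is a thin lens per micro-camera: an object at distance
``u`` from a lens of focal length ``f`` is imaged with linear magnification
``m = f / (u - f)``.  Cameras sit on a regular rectangular grid with
center-to-center spacing (pitch) ``P``; adjacent cameras with parallel optical
axes see a feature displaced on the sensor by the binocular disparity
``s = m(u) * B`` (baseline ``B`` equals the pitch), which is inverted to depth
by ``u = f * (1 + B / s)``.

Units: millimetres for object space and sensor physical dimensions,
micrometres for pixel pitch and wavelength, pixels for image coordinates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import yaml

__all__ = [
    "CameraSpec",
    "ArrayConfig",
    "DepthGeometry",
    "magnification",
    "object_space_fov",
    "overlap_fractions",
    "raw_frame_bytes",
    "resolution_metrics",
    "disparity_to_depth",
    "depth_to_disparity",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("mcam96", "mcam96_u150")


@dataclass(frozen=True)
class CameraSpec:
    """A single micro-camera: lens plus sensor.

    Parameters
    ----------
    focal_length_mm : lens focal length (mm).
    numerical_aperture : object-side NA, in (0, 1).
    pixel_pitch_um : sensor pixel size (µm).
    sensor_px : (width_px, height_px); width is the long sensor axis.
    wavelength_um : illumination wavelength used in resolution formulas
        (default 0.50 µm, mid-visible green).
    """

    focal_length_mm: float = 25.0
    numerical_aperture: float = 0.03
    pixel_pitch_um: float = 1.4
    sensor_px: tuple[int, int] = (4320, 2432)
    wavelength_um: float = 0.50

    def __post_init__(self):
        if self.focal_length_mm <= 0:
            raise ValueError("focal_length_mm must be > 0")
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("numerical_aperture must be in (0, 1)")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")
        w, h = self.sensor_px
        if w < 1 or h < 1:
            raise ValueError("sensor_px entries must be >= 1")

    @property
    def sensor_size_mm(self) -> tuple[float, float]:
        """Physical (width, height) of the active sensor area in mm."""
        w, h = self.sensor_px
        s = self.pixel_pitch_um * 1e-3
        return (w * s, h * s)


@dataclass(frozen=True)
class ArrayConfig:
    """Geometry of the full camera array.

    ``grid`` is (n_rows, n_cols); world x runs along columns, y along rows.
    ``long_axis`` states which grid axis carries the long (width) sensor
    dimension: ``"grid_x"`` (columns, default) or ``"grid_y"`` (rows).
    ``working_distance_mm`` is the lens-to-object distance u.
    """

    camera: CameraSpec = field(default_factory=CameraSpec)
    grid: tuple[int, int] = (8, 12)
    pitch_mm: float = 19.0
    working_distance_mm: float = 165.0
    long_axis: str = "grid_x"

    def __post_init__(self):
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be > 0")
        if self.working_distance_mm <= self.camera.focal_length_mm:
            raise ValueError("working_distance_mm must exceed focal length")
        if min(self.grid) < 1:
            raise ValueError("grid dims must be >= 1")
        if self.long_axis not in ("grid_x", "grid_y"):
            raise ValueError("long_axis must be 'grid_x' or 'grid_y'")

    @property
    def n_cameras(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def magnification(self) -> float:
        return magnification(self.camera.focal_length_mm, self.working_distance_mm)

    @property
    def object_pixel_um(self) -> float:
        """Object-space sampling of one sensor pixel at the plane of best focus."""
        return self.camera.pixel_pitch_um / self.magnification

    def fov_xy_mm(self) -> tuple[float, float]:
        """Per-camera object-space FOV along world (x, y)."""
        long_mm, short_mm = object_space_fov(self)[0]
        if self.long_axis == "grid_x":
            return (long_mm, short_mm)
        return (short_mm, long_mm)

    def camera_centers_mm(self) -> dict[tuple[int, int], tuple[float, float]]:
        """World (x, y) of each camera's optical axis; array centered on origin."""
        n_rows, n_cols = self.grid
        out = {}
        for r in range(n_rows):
            for c in range(n_cols):
                x = (c - (n_cols - 1) / 2.0) * self.pitch_mm
                y = (r - (n_rows - 1) / 2.0) * self.pitch_mm
                out[(r, c)] = (x, y)
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["camera"]["sensor_px"] = list(self.camera.sensor_px)
        d["grid"] = list(self.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayConfig":
        cam = d.get("camera", {})
        camera = CameraSpec(
            focal_length_mm=cam.get("focal_length_mm", 25.0),
            numerical_aperture=cam.get("numerical_aperture", 0.03),
            pixel_pitch_um=cam.get("pixel_pitch_um", 1.4),
            sensor_px=tuple(cam.get("sensor_px", (4320, 2432))),
            wavelength_um=cam.get("wavelength_um", 0.50),
        )
        return cls(
            camera=camera,
            grid=tuple(d.get("grid", (8, 12))),
            pitch_mm=d.get("pitch_mm", 19.0),
            working_distance_mm=d.get("working_distance_mm", 165.0),
            long_axis=d.get("long_axis", "grid_x"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArrayConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class DepthGeometry:
    """Parameters of one adjacent-camera stereo pair.

    ``baseline_mm`` is the center spacing B of the two cameras,
    ``focus_distance_mm`` the object distance u0 of the plane of best focus.
    With ``z_sign="toward_camera_positive"`` (default) an object nearer the
    cameras than the focal plane has z > 0.
    """

    baseline_mm: float = 19.0
    focal_length_mm: float = 25.0
    focus_distance_mm: float = 150.0
    pixel_pitch_um: float = 1.4
    z_sign: str = "toward_camera_positive"

    def __post_init__(self):
        if self.baseline_mm <= 0:
            raise ValueError("baseline_mm must be > 0")
        if self.focus_distance_mm <= self.focal_length_mm:
            raise ValueError("focus_distance_mm must exceed focal length")
        if self.z_sign not in ("toward_camera_positive", "away_positive"):
            raise ValueError("bad z_sign")

    @classmethod
    def from_array_config(cls, config: ArrayConfig) -> "DepthGeometry":
        return cls(
            baseline_mm=config.pitch_mm,
            focal_length_mm=config.camera.focal_length_mm,
            focus_distance_mm=config.working_distance_mm,
            pixel_pitch_um=config.camera.pixel_pitch_um,
        )

    def z_from_object_distance(self, u_mm: float) -> float:
        z = self.focus_distance_mm - u_mm
        return z if self.z_sign == "toward_camera_positive" else -z


def magnification(focal_length_mm: float, object_distance_mm: float) -> float:
    """Thin-lens linear magnification m = f / (u - f).

    Raises ValueError if the object is at or inside the focal length (no real
    image is formed).
    """
    if object_distance_mm <= focal_length_mm:
        raise ValueError(
            f"object distance {object_distance_mm} mm must exceed focal length "
            f"{focal_length_mm} mm (no real image)"
        )
    return focal_length_mm / (object_distance_mm - focal_length_mm)


def object_space_fov(config: ArrayConfig):
    """Per-camera FOV and full-array span in object space.

    Returns ``((fov_long_mm, fov_short_mm), (span_x_mm, span_y_mm))``.
    Per-camera FOV is the sensor's physical dimension divided by the
    magnification; the array span per world axis is
    ``(n - 1) * pitch + FOV_axis``.
    """
    m = config.magnification
    sw, sh = config.camera.sensor_size_mm  # width = long axis
    fov_long, fov_short = sw / m, sh / m
    n_rows, n_cols = config.grid
    if config.long_axis == "grid_x":
        fov_x, fov_y = fov_long, fov_short
    else:
        fov_x, fov_y = fov_short, fov_long
    span_x = (n_cols - 1) * config.pitch_mm + fov_x
    span_y = (n_rows - 1) * config.pitch_mm + fov_y
    return (fov_long, fov_short), (span_x, span_y)


def overlap_fractions(config: ArrayConfig):
    """Fractional FOV overlap of adjacent cameras along each sensor axis.

    Per axis the overlap fraction is ``(FOV_axis - pitch) / FOV_axis``; it is
    negative when the pitch exceeds the FOV (a coverage gap -- reported
    honestly, never clipped).  Returns a dict with ``long``, ``short`` and
    ``two_camera_guarantee`` -- the latter is True iff the long-axis fraction
    is >= 0.5, i.e. every object-plane point along that axis is seen by at
    least two cameras.
    """
    (fov_long, fov_short), _ = object_space_fov(config)
    long_frac = (fov_long - config.pitch_mm) / fov_long
    short_frac = (fov_short - config.pitch_mm) / fov_short
    return {
        "long": long_frac,
        "short": short_frac,
        "two_camera_guarantee": bool(long_frac >= 0.5),
    }


def raw_frame_bytes(config: ArrayConfig, bit_depth: int = 8, n_cameras: int | None = None):
    """Raw (Bayer: one value per pixel) data volume of one array snapshot.

    Returns a dict with ``bytes``, ``mib`` (MiB) and ``pixels``.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if n_cameras is None:
        n_cameras = config.n_cameras
    w, h = config.camera.sensor_px
    nbytes = n_cameras * w * h * (bit_depth // 8)
    return {
        "bytes": nbytes,
        "mib": nbytes / 2**20,
        "pixels": n_cameras * w * h,
    }


def resolution_metrics(camera: CameraSpec, object_distance_mm: float) -> dict:
    """Diffraction- and sampling-limited resolution figures.

    lateral_rayleigh_um  : 0.61 * lambda / NA
    axial_rayleigh_mm    : lambda / (2 * NA^2)  (incoherent Rayleigh criterion)
    object_pixel_um      : pixel pitch mapped to object space, pitch / m
    nyquist_full_pitch_um: 2 * object_pixel (one bright + one dark bar)
    """
    na = camera.numerical_aperture
    if na <= 0:
        raise ValueError("numerical aperture must be > 0")
    lam = camera.wavelength_um
    m = magnification(camera.focal_length_mm, object_distance_mm)
    obj_px = camera.pixel_pitch_um / m
    return {
        "lateral_rayleigh_um": 0.61 * lam / na,
        "axial_rayleigh_mm": lam * 1e-3 / (2.0 * na**2),
        "object_pixel_um": obj_px,
        "nyquist_full_pitch_um": 2.0 * obj_px,
    }


def _disparity_mm(disparity, geometry: DepthGeometry, units: str) -> float:
    if units == "mm":
        return float(disparity)
    if units == "px":
        return float(disparity) * geometry.pixel_pitch_um * 1e-3
    raise ValueError("units must be 'mm' or 'px'")


def disparity_to_depth(disparity, geometry: DepthGeometry, units: str = "mm") -> float:
    """Object distance u (mm) from absolute sensor-plane disparity.

    ``u = f * (1 + B / s)`` with s the disparity between adjacent
    parallel-axis cameras, in mm (or pixels with ``units="px"``).
    """
    s = _disparity_mm(disparity, geometry, units)
    if s <= 0:
        raise ValueError("disparity must be > 0 (zero disparity means infinity)")
    return geometry.focal_length_mm * (1.0 + geometry.baseline_mm / s)


def depth_to_disparity(object_distance_mm: float, geometry: DepthGeometry, units: str = "mm") -> float:
    """Inverse of :func:`disparity_to_depth`: s = B * f / (u - f)."""
    m = magnification(geometry.focal_length_mm, object_distance_mm)
    s_mm = geometry.baseline_mm * m
    if units == "mm":
        return s_mm
    if units == "px":
        return s_mm / (geometry.pixel_pitch_um * 1e-3)
    raise ValueError("units must be 'mm' or 'px'")


def load_preset(name: str) -> ArrayConfig:
    """Load a packaged array-geometry preset by name (see PRESET_NAMES)."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    ref = importlib.resources.files("mcamtools") / "presets" / f"{name}.yaml"
    with ref.open() as fh:
        return ArrayConfig.from_dict(yaml.safe_load(fh))
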