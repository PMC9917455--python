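"""Shared fixtures: desk-scale array configs and expensive pipeline artifacts.

Everything is generated programmatically from seeds; session scope is used
for renders and trained models that several tests score against.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mcamtools import identity, optics, render, simulate, stitch

# Desk-scale array: same optics (f, NA, u) as the full instrument but coarse
# 10 um pixels and small sensors so a 3x3 grid mosaic is ~1 Mpx.
DESK_SENSOR = (400, 300)
DESK_PITCH_UM = 10.0


@pytest.fixture(scope="session")
def desk_config() -> optics.ArrayConfig:
    cam = optics.CameraSpec(
        focal_length_mm=25.0, numerical_aperture=0.03,
        pixel_pitch_um=DESK_PITCH_UM, sensor_px=DESK_SENSOR,
    )
    return optics.ArrayConfig(camera=cam, grid=(3, 3), pitch_mm=13.0, working_distance_mm=150.0)


@pytest.fixture(scope="session")
def stereo_config() -> optics.ArrayConfig:
    """Adjacent-camera pair with the full instrument's depth geometry
    (f=25 mm, B=19 mm, u0=150 mm, 1.4 um pixels); the sensor is cropped to
    the strip where both cameras see the test target."""
    cam = optics.CameraSpec(
        focal_length_mm=25.0, numerical_aperture=0.03,
        pixel_pitch_um=1.4, sensor_px=(3600, 512),
    )
    return optics.ArrayConfig(camera=cam, grid=(1, 2), pitch_mm=19.0, working_distance_mm=150.0)


@pytest.fixture(scope="session")
def calibration_scene(desk_config):
    _, (sx, sy) = optics.object_space_fov(desk_config)
    return simulate.make_calibration_scene((sx + 4, sy + 4), feature_density=4.0, seed=5)


@pytest.fixture(scope="session")
def calibration_frameset(calibration_scene, desk_config):
    return render.render_frameset(
        calibration_scene, desk_config, seed=2,
        options=render.RenderOptions(vignetting=False),
    )


@pytest.fixture(scope="session")
def desk_template(calibration_frameset):
    return stitch.calibrate_template(calibration_frameset)


@pytest.fixture(scope="session")
def fish_session(desk_config):
    """10 frames of 50 separated fish inside the 3x3 desk arena."""
    _, (sx, sy) = optics.object_space_fov(desk_config)
    arena = (-20.0, -17.0, 20.0, 17.0)
    return simulate.simulate_session(
        50, "fish", arena, n_frames=10, seed=11,
        extent_mm=(sx + 4, sy + 4), length_mm=2.0, width_mm=0.55,
        motion=simulate.MotionParams(min_separation_mm=3.5),
    )


def render_fish_frame(scene, config, seed):
    return render.render_frameset(
        scene, config, seed=seed, options=render.RenderOptions(vignetting=False)
    )


def bead_pair_frames(config, z_mm, xy_mm=(0.0, 0.0), seed=0, texture_seed=0):
    """Render a textured bead seen by both cameras of a stereo pair."""
    bead = simulate.OrganismSpec(
        kind="point_bead", position_mm=xy_mm, z_mm=z_mm,
        length_mm=1.2, width_mm=1.2, identity_texture_seed=texture_seed,
    )
    scene = simulate.SceneSpec(extent_mm=(40.0, 20.0), organisms=[bead])
    fs = render.render_frameset(scene, config, seed=seed)
    a = fs.frames[(0, 0)][::-1, ::-1].astype(np.float64) / 255.0
    b = fs.frames[(0, 1)][::-1, ::-1].astype(np.float64) / 255.0
    return a, b


def locate_bead(img, half=120):
    """Detection-box stand-in: box around the strongest deviation from background."""
    dev = np.abs(img - np.median(img))
    iy, ix = np.unravel_index(np.argmax(dev), img.shape)
    return (ix - half, iy - half, ix + half, iy + half)


def make_identity_crops(n_identities=8, n_frames=12, seed=7, um_per_px=110.0):
    """Per-identity time-stamped crops in canonical (head-right) orientation."""
    rng = np.random.default_rng(seed)
    per_id = {}
    for ident in range(n_identities):
        crops = []
        for t in range(n_frames):
            org = simulate.OrganismSpec(
                kind="fish", position_mm=(0.0, 0.0),
                heading_rad=float(rng.normal(0.0, 0.1)),
                length_mm=5.0, width_mm=1.2,
                articulation=tuple(rng.normal(0.0, 0.10, 4)),
                eye_angles_rad=(0.15, -0.15),
                identity_texture_seed=ident,
            )
            crops.append((float(t), render.render_organism_crop(org, um_per_px=um_per_px, pad_mm=0.8)))
        per_id[ident] = crops
    return per_id


@pytest.fixture(scope="session")
def identity_data():
    per_id = make_identity_crops()
    train, test = identity.build_identity_dataset(
        per_id, n_augmented_per_id=100, temporal_split_fraction=0.8, seed=3, crop_px=48
    )
    return per_id, train, test


@pytest.fixture(scope="session")
def trained_embedder(identity_data):
    _, train, _ = identity_data
    spec = identity.EmbedderSpec(input_px=48, epochs=10, seed=5)
    return identity.train_embedder(train, spec)
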