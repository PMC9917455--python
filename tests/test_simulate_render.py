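"""Scene synthesis and image formation: projection geometry, determinism,
motion statistics, diffuser/vignetting model."""

import math

import numpy as np
import pytest

from mcamtools import optics, render, simulate
from mcamtools.optics import depth_to_disparity, DepthGeometry


def _bead_scene(xy=(0.0, 0.0), z=0.0, seed=3):
    bead = simulate.OrganismSpec(
        kind="point_bead", position_mm=xy, z_mm=z, length_mm=1.2, width_mm=1.2,
        identity_texture_seed=seed,
    )
    return simulate.SceneSpec(extent_mm=(40.0, 20.0), organisms=[bead])


def _weighted_centroid(img):
    """Centroid of deviation from background (bead locator, sub-pixel)."""
    dev = np.abs(img.astype(np.float64) - np.median(img))
    dev = np.where(dev > 0.25 * dev.max(), dev, 0.0)
    ii, jj = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return (dev * jj).sum() / dev.sum(), (dev * ii).sum() / dev.sum()


class TestProjectionGeometry:
    def test_on_axis_bead_lands_at_image_center(self, stereo_config):
        # uniform dark disc on camera (0,0)'s optical axis (no texture bias)
        cx, cy = stereo_config.camera_centers_mm()[(0, 0)]
        disc = simulate.OrganismSpec(
            kind="blob", position_mm=(cx, cy), length_mm=1.2, width_mm=1.2
        )
        scene = simulate.SceneSpec(extent_mm=(40.0, 20.0), organisms=[disc])
        fs = render.render_frameset(
            scene, stereo_config, seed=0,
            noise=render.NoiseParams(enabled=False), cameras=[(0, 0)],
        )
        img = fs.frames[(0, 0)]
        w, h = stereo_config.camera.sensor_px
        bx, by = _weighted_centroid(img)
        assert bx == pytest.approx((w - 1) / 2, abs=1.0)
        assert by == pytest.approx((h - 1) / 2, abs=1.0)

    def test_neighbor_camera_displacement_equals_mB(self, stereo_config):
        # at u0 the inter-camera image displacement is m*B = 3.8 mm = 2714.3 px
        fs = render.render_frameset(
            _bead_scene((0.0, 0.0)), stereo_config, seed=0,
            noise=render.NoiseParams(enabled=False),
        )
        xa, _ = _weighted_centroid(fs.frames[(0, 0)])
        xb, _ = _weighted_centroid(fs.frames[(0, 1)])
        assert abs(xb - xa) == pytest.approx(2714.3, abs=1.0)

    @pytest.mark.parametrize("z", [1.0, -1.5])
    def test_off_focus_disparity_matches_thin_lens_oracle(self, stereo_config, z):
        geom = DepthGeometry.from_array_config(stereo_config)
        fs = render.render_frameset(
            _bead_scene((0.0, 0.0), z=z), stereo_config, seed=1,
            noise=render.NoiseParams(enabled=False),
            options=render.RenderOptions(defocus=False),
        )
        xa, _ = _weighted_centroid(fs.frames[(0, 0)])
        xb, _ = _weighted_centroid(fs.frames[(0, 1)])
        expected = depth_to_disparity(150.0 - z, geom, units="px")
        assert abs(xb - xa) == pytest.approx(expected, abs=1.0)

    def test_projection_round_trip(self, stereo_config):
        # world -> pixel -> world is identity to well below 1e-6 mm
        cfg = stereo_config
        m = cfg.magnification
        delta = cfg.camera.pixel_pitch_um * 1e-3 / m
        w, _ = cfg.camera.sensor_px
        cx = -9.5
        for x_world in (-11.0, -9.5, -2.0, 1.5):
            j = (cx - x_world) / delta + (w - 1) / 2
            back = cx - (j - (w - 1) / 2) * delta
            assert back == pytest.approx(x_world, abs=1e-9)

    def test_organism_outside_all_fovs_rendered_absent(self, stereo_config):
        scene = _bead_scene((0.0, 0.0))
        scene.organisms[0].position_mm = (0.0, 9.0)  # beyond the 512 px strip
        fs = render.render_frameset(
            scene, stereo_config, seed=0, noise=render.NoiseParams(enabled=False)
        )
        for img in fs.frames.values():
            assert img.std() < 2.0  # background only

    def test_invalid_seed_type_raises(self, stereo_config):
        with pytest.raises(TypeError):
            render.render_frameset(_bead_scene(), stereo_config, seed="abc")


class TestDeterminism:
    def test_identical_seed_gives_bit_identical_frames(self, desk_config, calibration_scene):
        a = render.render_frameset(calibration_scene, desk_config, seed=9, cameras=[(0, 0), (1, 1)])
        b = render.render_frameset(calibration_scene, desk_config, seed=9, cameras=[(0, 0), (1, 1)])
        for k in a.frames:
            assert np.array_equal(a.frames[k], b.frames[k])

    def test_different_seed_changes_noise(self, desk_config, calibration_scene):
        a = render.render_frameset(calibration_scene, desk_config, seed=9, cameras=[(0, 0)])
        b = render.render_frameset(calibration_scene, desk_config, seed=10, cameras=[(0, 0)])
        assert not np.array_equal(a.frames[(0, 0)], b.frames[(0, 0)])


class TestCalibrationScene:
    def test_zero_density_is_uniform(self, desk_config):
        scene = simulate.make_calibration_scene((30, 30), feature_density=0.0, seed=1)
        fs = render.render_frameset(
            scene, desk_config, seed=0, cameras=[(1, 1)],
            noise=render.NoiseParams(enabled=False),
            options=render.RenderOptions(vignetting=False),
        )
        img = fs.frames[(1, 1)].astype(float)
        gy, gx = np.gradient(img)
        assert np.hypot(gy, gx).mean() == pytest.approx(0.0, abs=1e-6)

    def test_default_density_much_sharper_than_uniform(self, desk_config, calibration_scene):
        kwargs = dict(
            seed=2, cameras=[(1, 1)],
            noise=render.NoiseParams(enabled=False),
            options=render.RenderOptions(vignetting=False),
        )
        img = render.render_frameset(calibration_scene, desk_config, **kwargs).frames[(1, 1)].astype(float)
        gy, gx = np.gradient(img)
        textured = np.hypot(gy, gx).mean()
        uniform_scene = simulate.make_calibration_scene(
            calibration_scene.extent_mm, feature_density=0.0
        )
        u = render.render_frameset(uniform_scene, desk_config, **kwargs).frames[(1, 1)].astype(float)
        gy, gx = np.gradient(u)
        assert textured > 5 * max(np.hypot(gy, gx).mean(), 1e-9)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            simulate.make_calibration_scene((10, 10), feature_density=-1)


class TestDiffuserFrames:
    def test_noise_free_framesets_identical_and_count_default(self, desk_config):
        frames = render.make_diffuser_frames(
            desk_config, seed=1, noise=render.NoiseParams(enabled=False), cameras=[(0, 0)]
        )
        assert len(frames) == 5  # matches the five-image flat-field procedure
        for fs in frames[1:]:
            assert np.array_equal(fs.frames[(0, 0)], frames[0].frames[(0, 0)])

    def test_vignetting_falloff_matches_cos4_within_1pct(self, desk_config):
        opts = render.RenderOptions(vignetting=True, vignetting_scale=3.5)
        fs = render.make_diffuser_frames(
            desk_config, n=1, seed=1, noise=render.NoiseParams(enabled=False),
            options=opts, cameras=[(0, 0)],
        )[0]
        img = fs.frames[(0, 0)].astype(float)
        h, w = img.shape
        vig = render.vignette_profile((h, w), 0.01, 25.0, 3.5)
        measured = img[0, 0] / img[h // 2, w // 2]
        expected = vig[0, 0] / vig[h // 2, w // 2]
        assert measured == pytest.approx(expected, rel=0.01)

    def test_n_must_be_positive(self, desk_config):
        with pytest.raises(ValueError):
            render.make_diffuser_frames(desk_config, n=0)


class TestSession:
    def test_zero_organisms_gives_empty_scenes(self):
        scenes = simulate.simulate_session(0, "fish", (-5, -5, 5, 5), n_frames=3, seed=0)
        assert all(len(s.organisms) == 0 for s in scenes)

    def test_mean_step_length_matches_configured_speed(self):
        motion = simulate.MotionParams(mean_speed_mm_s=5.0, heading_diffusion_rad=0.3)
        scenes = simulate.simulate_session(
            1, "fish", (-200, -200, 200, 200), motion=motion,
            n_frames=501, dt_s=1.0, seed=4, extent_mm=(404, 404),
        )
        pos = np.array([s.organisms[0].position_mm for s in scenes])
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        # wall reflections fold a few steps; large arena keeps that rare
        assert steps.mean() == pytest.approx(5.0, rel=0.10)

    def test_wall_reflection_keeps_centers_inside(self):
        arena = (-8.0, -6.0, 8.0, 6.0)
        scenes = simulate.simulate_session(
            12, "fish", arena, n_frames=40, seed=2,
            motion=simulate.MotionParams(mean_speed_mm_s=8.0),
        )
        for s in scenes:
            for o in s.organisms:
                x, y = o.position_mm
                assert arena[0] <= x <= arena[2]
                assert arena[1] <= y <= arena[3]

    def test_identities_persist_across_frames(self):
        scenes = simulate.simulate_session(5, "fish", (-10, -10, 10, 10), n_frames=4, seed=0)
        for s in scenes:
            assert [o.identity_texture_seed for o in s.organisms] == list(range(5))

    def test_arena_larger_than_extent_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_session(1, "fish", (-30, -30, 30, 30), extent_mm=(20, 20))

    def test_min_separation_enforced(self):
        scenes = simulate.simulate_session(
            30, "fish", (-20, -15, 20, 15), n_frames=6, seed=1,
            motion=simulate.MotionParams(min_separation_mm=3.0),
        )
        for s in scenes:
            pos = np.array([o.position_mm for o in s.organisms])
            d = np.hypot(pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1])
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 3.0 - 1e-6


class TestSceneSpecs:
    def test_organism_outside_extent_rejected(self):
        with pytest.raises(ValueError):
            simulate.SceneSpec(
                extent_mm=(10, 10),
                organisms=[simulate.OrganismSpec(position_mm=(8.0, 0.0))],
            )

    def test_articulation_bounds(self):
        with pytest.raises(ValueError):
            simulate.OrganismSpec(articulation=(math.pi,))

    def test_scene_json_round_trip(self):
        scenes = simulate.simulate_session(3, "fish", (-5, -5, 5, 5), n_frames=1, seed=0)
        d = scenes[0].to_dict()
        back = simulate.SceneSpec.from_dict(d)
        assert back.to_dict() == d
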