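"""Behavior metrics: occupancy, tail/eye kinematics, optical flow, counting."""

import math

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import chisquare

from mcamtools import behavior, render, simulate
from mcamtools.behavior import (
    density_per_area,
    eye_angles,
    occupancy_heatmap,
    optical_flow_activity,
    segment_count,
    tail_trace,
)


def _fish_crop(heading=0.0, articulation=(0, 0, 0, 0, 0), eyes=(0.17, -0.17), seed=4, um=15.0):
    org = simulate.OrganismSpec(
        kind="fish", position_mm=(0, 0), heading_rad=heading,
        length_mm=6.0, width_mm=1.3, articulation=articulation,
        eye_angles_rad=eyes, identity_texture_seed=seed,
    )
    return render.render_organism_crop(org, um_per_px=um, pad_mm=1.0)


class TestOccupancy:
    def test_stationary_fish_concentrates_in_one_bin(self):
        pos = np.tile([[3.0, 4.0]], (100, 1))
        occ = occupancy_heatmap(pos, (0, 0, 20, 20), bin_size_mm=5.0)
        assert occ.grid.max() == 1.0
        assert occ.n_samples == 100

    def test_grid_sums_to_one_exactly(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 30, size=(500, 2))
        occ = occupancy_heatmap(pos, (0, 0, 30, 30), bin_size_mm=4.0)
        assert occ.grid.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_positions_pass_chi_square(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 40, size=(10_000, 2))
        occ = occupancy_heatmap(pos, (0, 0, 40, 40), bin_size_mm=10.0)
        counts = occ.grid.ravel() * occ.n_samples
        _, p = chisquare(counts)
        assert p > 0.01

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 20, size=(300, 2))
        a = occupancy_heatmap(pos, (0, 0, 20, 20), 5.0)
        b = occupancy_heatmap(pos + [100, -50], (100, -50, 120, -30), 5.0)
        assert np.allclose(a.grid, b.grid)

    def test_outside_positions_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            occ = occupancy_heatmap(np.array([[25.0, 5.0]]), (0, 0, 20, 20), 5.0)
        assert occ.grid.sum() == 1.0

    def test_zero_positions_is_an_error(self):
        with pytest.raises(ValueError):
            occupancy_heatmap(np.zeros((0, 2)), (0, 0, 10, 10), 5.0)


class TestTailTrace:
    def test_straight_fish_angles_near_zero(self):
        tt = tail_trace(_fish_crop(heading=0.3), n_segments=6)
        assert np.abs(np.degrees(tt.segment_angles_rad)).max() <= 3.0

    def test_single_30deg_bend_recovered_distally(self):
        bend = math.radians(30)
        tt = tail_trace(_fish_crop(articulation=(0, 0, bend, 0, 0)), n_segments=6)
        assert math.degrees(tt.segment_angles_rad[-1]) == pytest.approx(30.0, abs=3.0)
        assert np.abs(np.degrees(tt.segment_angles_rad[:2])).max() <= 3.0

    def test_articulation_sweep_slope_near_unity(self):
        bends = np.radians([-60, -40, -20, 0, 20, 40, 60])
        tips = []
        for b in bends:
            tt = tail_trace(_fish_crop(heading=0.5, articulation=(0, 0, float(b), 0, 0), seed=2), n_segments=6)
            tips.append(tt.segment_angles_rad[-1])
        slope = np.polyfit(bends, tips, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_rotation_equivariance(self):
        base = tail_trace(_fish_crop(heading=0.2, articulation=(0, 0, 0.4, 0, 0)), n_segments=6)
        rot = tail_trace(_fish_crop(heading=0.2 + math.pi / 2, articulation=(0, 0, 0.4, 0, 0)), n_segments=6)
        assert math.degrees(abs((rot.body_axis_rad - base.body_axis_rad) % (2 * math.pi) - math.pi / 2)) < 3.0
        assert np.degrees(np.abs(rot.segment_angles_rad - base.segment_angles_rad)).max() <= 3.0

    def test_blob_below_minimum_area_rejected(self):
        with pytest.raises(ValueError):
            tail_trace(np.full((50, 50), 0.8), n_segments=5)


class TestEyeAngles:
    def test_rendered_convergence_recovered_within_3deg(self):
        em = eye_angles(_fish_crop(eyes=(math.radians(10), math.radians(-10))))
        assert not em.missing
        assert math.degrees(em.left_rad) == pytest.approx(10.0, abs=3.0)
        assert math.degrees(em.right_rad) == pytest.approx(-10.0, abs=3.0)

    def test_mirror_symmetric_eyes_give_opposite_angles(self):
        em = eye_angles(_fish_crop(eyes=(0.2, -0.2), seed=11))
        assert not em.missing
        assert em.left_rad == pytest.approx(-em.right_rad, abs=math.radians(3.0))

    def test_eyeless_blob_flagged_missing(self):
        org = simulate.OrganismSpec(
            kind="blob", position_mm=(0, 0), length_mm=5.0, width_mm=2.0
        )
        crop = render.render_organism_crop(org, um_per_px=20.0, pad_mm=1.0)
        em = eye_angles(crop)
        assert em.missing
        assert em.left_rad is None and em.right_rad is None


class TestOpticalFlow:
    def _texture(self, shape=(120, 160), seed=0):
        rng = np.random.default_rng(seed)
        return ndimage.gaussian_filter(rng.random(shape), 2.0)

    def test_static_sequence_has_zero_activity(self):
        img = self._texture()
        out = optical_flow_activity([img, img, img], block_px=16, search_px=3)
        assert np.allclose(out["per_frame"], 0.0)

    def test_global_two_pixel_shift_measured(self):
        img = self._texture((140, 180), seed=1)
        seq = [np.roll(img, (0, 2 * t), axis=(0, 1)) for t in range(4)]
        out = optical_flow_activity(seq, block_px=16, search_px=4)
        assert out["per_frame"] == pytest.approx(2.0, abs=0.1)

    def test_epoch_contrast_ratio(self):
        img = self._texture((140, 180), seed=2)
        # slow epoch: 1 px/frame; fast epoch: 3 px/frame
        seq = [img]
        shift = 0
        for t in range(8):
            shift += 1 if t < 4 else 3
            seq.append(np.roll(img, shift, axis=1))
        out = optical_flow_activity(
            seq, block_px=16, search_px=4,
            epochs={"slow": [(0, 4)], "fast": [(4, 8)]},
        )
        ratio = out["epoch_means"]["fast"] / out["epoch_means"]["slow"]
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_block_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            optical_flow_activity([np.zeros((20, 20))] * 2, block_px=64)


def flood_fill_count(mask, connectivity):
    """Independent oracle: BFS flood fill with explicit neighbor sets."""
    nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        nbrs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack, size = [(i, j)], 0
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                sizes.append(size)
    return sorted(sizes)


class TestSegmentCount:
    def test_five_small_blobs_are_individuals(self):
        mask = np.zeros((100, 100), bool)
        for k in range(5):
            mask[10 * k + 5 : 10 * k + 9, 60:66] = True
        out = segment_count(mask, min_area_px=5, swarm_area_threshold_px=1000)
        assert out.n_individuals == 5
        assert out.n_swarms == 0

    def test_large_blob_is_a_swarm(self):
        mask = np.zeros((200, 200), bool)
        mask[50:150, 50:150] = True  # 10^4 px
        out = segment_count(mask, min_area_px=50, swarm_area_threshold_px=1000)
        assert out.n_individuals == 0
        assert out.n_swarms == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_counts_match_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(12)
        for _ in range(20):
            mask = rng.random((40, 50)) < 0.35
            out = segment_count(mask, min_area_px=1, swarm_area_threshold_px=10**9, connectivity=connectivity)
            assert sorted(out.individual_areas_px) == flood_fill_count(mask, connectivity)

    def test_counts_invariant_to_block_tiling(self):
        # components wholly inside blocks: tiled counting sums to the total
        rng = np.random.default_rng(4)
        mask = np.zeros((120, 120), bool)
        for _ in range(12):
            y, x = rng.integers(5, 50, 2)
            by, bx = rng.integers(0, 2, 2)
            mask[60 * by + y : 60 * by + y + 4, 60 * bx + x : 60 * bx + x + 4] = True
        total = segment_count(mask, min_area_px=1, swarm_area_threshold_px=10**9).n_individuals
        by_block = sum(
            segment_count(mask[60 * r : 60 * r + 60, 60 * c : 60 * c + 60], min_area_px=1,
                          swarm_area_threshold_px=10**9).n_individuals
            for r in range(2) for c in range(2)
        )
        assert total == by_block

    def test_reference_segmenter_on_rendered_worms(self):
        scenes = simulate.simulate_session(
            8, "worm", (-12, -12, 12, 12), n_frames=1, seed=3,
            length_mm=3.0, width_mm=0.35,
            motion=simulate.MotionParams(min_separation_mm=4.0),
        )
        img = render.rasterize_scene(scenes[0], um_per_px=60.0)
        out = segment_count(img, min_area_px=30, swarm_area_threshold_px=10**6, um_per_px=60.0)
        assert out.n_individuals == 8
        assert out.density_individuals_per_cm2 == pytest.approx(
            8 / (img.size * (60.0e-4) ** 2), rel=1e-6
        )

    def test_unknown_connectivity_rejected(self):
        with pytest.raises(ValueError):
            segment_count(np.zeros((10, 10), bool), connectivity=6)


class TestDensity:
    def test_plain_density(self):
        out = density_per_area(100, 10.0)
        assert out["density_per_cm2"] == 10.0

    def test_sem_is_consistent_poisson_uncertainty_across_block_grids(self):
        # for N uniform points over area A, the SEM of the mean block density
        # is ~ sqrt(N)/A regardless of the block partition (Poisson scatter)
        rng = np.random.default_rng(8)
        n, area = 800, 16.0
        pts = rng.uniform(0, 400, size=(n, 2))
        expected = math.sqrt(n) / area
        for grid in [(2, 2), (4, 4)]:
            out = density_per_area(n, area, pts, (400, 400), block_grid=grid)
            assert out["sem_per_cm2"] == pytest.approx(expected, rel=0.35)

    def test_empty_mosaic_zero_density_zero_sem(self):
        out = density_per_area(0, 10.0, np.zeros((0, 2)), (100, 100))
        assert out["density_per_cm2"] == 0.0
        assert out["sem_per_cm2"] == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            density_per_area(5, 0.0)
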