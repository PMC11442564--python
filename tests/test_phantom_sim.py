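"""Simulator geometry, kinematics, rendering and protocol structure."""

import numpy as np
import pytest

from needletrack import (
    MediumSpec,
    NeedleSpec,
    TrajectorySpec,
    VolumeGrid,
    generate_dataset,
    make_trajectory,
    render_volume,
    simulate_insertion,
)
from needletrack.coords import RigidTranslation
from needletrack.phantom_sim import (
    DEFAULT_TRANSFORM,
    ConfigurationError,
    InvalidSpecError,
    TransducerSpec,
    dataset_manifest,
    render_background,
)


class TestVolumeGrid:
    def test_fov_implies_depth_voxel_count(self):
        # 5-40 mm depth at 0.3 mm pitch spans 117 voxels
        assert VolumeGrid.from_fov((5.0, 40.0), pitch=0.3).shape[0] == 117

    def test_default_shape(self):
        assert VolumeGrid().shape == (117, 134, 134)

    def test_index_mm_round_trip(self):
        g = VolumeGrid()
        p = np.array([12.3, 24.6, 17.7])
        assert np.allclose(g.index_to_mm(g.mm_to_index(p)), p)

    def test_invalid(self):
        with pytest.raises(InvalidSpecError):
            VolumeGrid(shape=(0, 10, 10))
        with pytest.raises(InvalidSpecError):
            VolumeGrid(pitch=-0.3)

    def test_matrix_transducer_channels(self):
        # 16 x 16 elements, one system channel each: no multiplexing needed
        assert TransducerSpec(elements=(16, 16)).channels == 256


class TestTrajectory:
    def test_parallel_protocol_pose_count(self):
        spec = TrajectorySpec(start_H=(0, 0, 0), velocity=1.5, distance=15, frame_rate=4)
        poses = make_trajectory(spec)
        assert len(poses) == 41
        steps = [np.linalg.norm(poses[i + 1][1] - poses[i][1]) for i in range(40)]
        assert np.allclose(steps, 0.375, atol=1e-12)

    def test_non_divisible_travel_overshoots_to_cover_distance(self):
        spec = TrajectorySpec(start_H=(0, 0, 0), velocity=1.6, distance=15, frame_rate=4)
        poses = make_trajectory(spec)
        travel = np.linalg.norm(poses[-1][1] - poses[0][1])
        assert travel >= 15.0
        assert travel - 0.4 < 15.0  # previous pose had not yet covered it

    def test_untilted_direction_is_negative_y(self):
        d = TrajectorySpec(start_H=(0, 0, 0)).direction()
        # (x, y, z) = (0, -1, 0) i.e. (0, 0, -1) in (depth, x, y) array order
        assert np.allclose(d, [0.0, -1.0, 0.0])
        assert np.allclose([d[2], d[0], d[1]], [0.0, 0.0, -1.0])

    @pytest.mark.parametrize("ax,az", [(0.0, 5.0), (0.0, -5.0), (-5.0, 0.0)])
    def test_tilt_angle_geometry(self, ax, az):
        d0 = TrajectorySpec(start_H=(0, 0, 0)).direction()
        d = TrajectorySpec(start_H=(0, 0, 0), alpha_x=ax, alpha_z=az).direction()
        angle = max(abs(ax), abs(az))
        assert np.dot(d, d0) == pytest.approx(np.cos(np.deg2rad(angle)), abs=1e-12)

    def test_timestamps_spacing(self):
        poses = make_trajectory(TrajectorySpec(start_H=(0, 0, 0), frame_rate=4))
        ts = np.array([t for t, _ in poses])
        assert np.allclose(np.diff(ts), 0.25)

    @pytest.mark.parametrize(
        "kw", [{"velocity": 0.0}, {"distance": -1.0}, {"frame_rate": 0.0}, {"velocity": np.nan}]
    )
    def test_invalid_kinematics_rejected(self, kw):
        with pytest.raises(InvalidSpecError):
            TrajectorySpec(start_H=(0, 0, 0), **kw)


class TestRendering:
    def test_determinism_bit_identical(self, coarse_grid):
        tip = np.array([-20.0, 0.0, -13.0])
        v1, _ = render_volume(
            coarse_grid, MediumSpec.water(), NeedleSpec(), tip, DEFAULT_TRANSFORM,
            np.random.default_rng(3),
        )
        v2, _ = render_volume(
            coarse_grid, MediumSpec.water(), NeedleSpec(), tip, DEFAULT_TRANSFORM,
            np.random.default_rng(3),
        )
        assert v1.dtype == np.uint8 and np.array_equal(v1, v2)

    @pytest.mark.parametrize("medium", [MediumSpec.water(), MediumSpec.liver()])
    def test_tip_voxel_brighter_than_background(self, coarse_grid, medium):
        tip = np.array([-20.0, -7.0, -13.0])
        bg = render_background(coarse_grid, medium, np.random.default_rng(11))
        vol, meta = render_volume(
            coarse_grid, medium, NeedleSpec(), tip, DEFAULT_TRANSFORM, np.random.default_rng(11)
        )
        assert meta["tip_in_fov"] and meta["tip_margin_voxels"] >= 2
        idx = tuple(np.round(coarse_grid.mm_to_index(tip + DEFAULT_TRANSFORM.offset)).astype(int))
        assert vol[idx] > np.percentile(bg, 99)

    def test_far_outside_fov_is_pure_background(self, coarse_grid):
        tip = np.array([-90.0, 0.0, -13.0])  # 50+ mm beyond the lateral FOV
        bg = render_background(coarse_grid, MediumSpec.water(), np.random.default_rng(5))
        vol, meta = render_volume(
            coarse_grid, MediumSpec.water(), NeedleSpec(), tip, DEFAULT_TRANSFORM,
            np.random.default_rng(5),
        )
        assert not meta["tip_in_fov"]
        assert vol.max() <= np.percentile(bg, 99.9) + 10

    def test_reverberation_adds_deep_echoes(self, coarse_grid):
        tip = np.array([-20.0, -7.0, -13.0])
        clean, _ = render_volume(
            coarse_grid, MediumSpec.water(), NeedleSpec(reverb_strength=0.0), tip,
            DEFAULT_TRANSFORM, np.random.default_rng(2),
        )
        rev, _ = render_volume(
            coarse_grid, MediumSpec.water(), NeedleSpec(reverb_strength=0.5), tip,
            DEFAULT_TRANSFORM, np.random.default_rng(2),
        )
        assert rev.astype(int).sum() > clean.astype(int).sum()


class TestInsertionSimulation:
    def test_frame_count_and_timestamps(self, water_insertion_coarse):
        rec = water_insertion_coarse
        assert rec.n_frames == 41
        ts = np.array([f.timestamp for f in rec.frames])
        assert np.all(np.diff(ts) > 0)
        assert np.allclose(np.diff(ts), 1.0 / rec.trajectory.frame_rate)

    def test_tip_us_is_translated_tip_h(self, water_insertion_coarse):
        for f in water_insertion_coarse.frames[::10]:
            assert np.allclose(f.tip_US, f.tip_H + DEFAULT_TRANSFORM.offset)

    def test_kinematic_step_norm(self, water_insertion_coarse):
        tips = np.array([f.tip_H for f in water_insertion_coarse.frames])
        steps = np.linalg.norm(np.diff(tips, axis=0), axis=1)
        spec = water_insertion_coarse.trajectory
        assert np.allclose(steps, spec.velocity / spec.frame_rate, atol=1e-12)

    def test_reproducible_from_seed(self, coarse_grid):
        spec = TrajectorySpec(start_H=(-15.0, 0.0, -10.0))
        a = simulate_insertion(coarse_grid, MediumSpec.water(), NeedleSpec(), spec, seed=9)
        b = simulate_insertion(coarse_grid, MediumSpec.water(), NeedleSpec(), spec, seed=9)
        for fa, fb in zip(a.frames[::13], b.frames[::13]):
            assert np.array_equal(fa.volume, fb.volume)

    def test_ground_truth_containment_along_insertion(self, mid_grid):
        # every frame whose tip lies >= 2 voxels inside the FOV renders the
        # tip voxel inside the bright needle (above the background's 99th
        # percentile); checked at 0.6 mm pitch, where the 2.15 mm needle
        # spans several voxels (at much coarser pitches it is sub-voxel and
        # the rounded tip voxel can fall just outside the cylinder)
        rec = simulate_insertion(
            mid_grid, MediumSpec.water(), NeedleSpec(),
            TrajectorySpec(start_H=(-20.0, 0.0, -13.0)), seed=42,
        )
        bg = render_background(mid_grid, MediumSpec.water(), np.random.default_rng(1))
        p99 = np.percentile(bg, 99)
        checked = 0
        for f in rec.frames:
            if mid_grid.margin_voxels(f.tip_US) >= 2:
                idx = tuple(np.round(mid_grid.mm_to_index(f.tip_US)).astype(int))
                assert f.volume[idx] > p99
                checked += 1
        assert checked > 30

    def test_liver_noisier_than_water(self, coarse_grid):
        spec = TrajectorySpec(start_H=(-20.0, 0.0, -13.0), frame_rate=1.0)
        water = simulate_insertion(coarse_grid, MediumSpec.water(), NeedleSpec(), spec, seed=4)
        liver = simulate_insertion(coarse_grid, MediumSpec.liver(), NeedleSpec(), spec, seed=4)
        vw = np.mean([f.volume.astype(float).var() for f in water.frames])
        vl = np.mean([f.volume.astype(float).var() for f in liver.frames])
        assert vl > vw

    def test_liver_has_more_superthreshold_background_components(self, full_grid):
        # at acquisition scale the liver speckle and boundary sheets push
        # scattered voxel clusters above the detection threshold; water never
        from scipy import ndimage

        n = {}
        for medium in (MediumSpec.water(), MediumSpec.liver()):
            bg = render_background(full_grid, medium, np.random.default_rng(21))
            _, count = ndimage.label(bg > 128, structure=np.ones((3, 3, 3)))
            n[medium.kind] = count
        assert n["liver"] > n["water"]
        assert n["water"] == 0


class TestProtocols:
    def test_parallel_protocol_structure(self, parallel_records_coarse):
        recs = parallel_records_coarse
        assert len(recs) == 12
        starts = {(r.trajectory.start_H[0], r.trajectory.start_H[2]) for r in recs}
        assert len(starts) == 12  # 4 heights x 3 horizontal positions
        assert all(r.trajectory.velocity == 1.5 for r in recs)

    def test_parallel_frame_total_at_4hz(self, coarse_grid):
        recs = generate_dataset("parallel", grid=coarse_grid, seed=1, frame_rate=4.0)
        assert sum(r.n_frames for r in recs) == 12 * 41 == 492

    def test_tilted_protocol_structure(self, coarse_grid):
        recs = generate_dataset("tilted", grid=coarse_grid, seed=1, frame_rate=0.5)
        assert len(recs) == 27
        angles = {}
        for r in recs:
            key = (r.trajectory.alpha_x, r.trajectory.alpha_z)
            angles[key] = angles.get(key, 0) + 1
        assert angles == {(0.0, 5.0): 9, (0.0, -5.0): 9, (-5.0, 0.0): 9}
        assert all(r.trajectory.velocity == 1.0 for r in recs)

    def test_out_of_fov_start_grid_rejected(self, coarse_grid):
        bad = RigidTranslation(np.array([500.0, 500.0, 500.0]))
        with pytest.raises(ConfigurationError):
            generate_dataset("parallel", grid=coarse_grid, transform=bad, frame_rate=1.0)

    def test_unknown_protocol_rejected(self, coarse_grid):
        with pytest.raises(ConfigurationError):
            generate_dataset("sideways", grid=coarse_grid)

    def test_manifest_columns_and_units(self, parallel_records_coarse, coarse_grid):
        m = dataset_manifest(parallel_records_coarse, pitch=coarse_grid.pitch)
        assert len(m) == sum(r.n_frames for r in parallel_records_coarse)
        px = m[["tip_US_x_px", "tip_US_y_px", "tip_US_z_px"]].to_numpy()
        mm = m[["tip_US_x_mm", "tip_US_y_mm", "tip_US_z_mm"]].to_numpy()
        assert np.allclose(px * coarse_grid.pitch, mm)

    def test_dataset_reproducible_from_seed(self, coarse_grid):
        a = generate_dataset("parallel", grid=coarse_grid, seed=7, frame_rate=1.0)
        b = generate_dataset("parallel", grid=coarse_grid, seed=7, frame_rate=1.0)
        ma = dataset_manifest(a, pitch=coarse_grid.pitch)
        mb = dataset_manifest(b, pitch=coarse_grid.pitch)
        assert ma.equals(mb)
        assert np.array_equal(a[3].frames[5].volume, b[3].frames[5].volume)
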