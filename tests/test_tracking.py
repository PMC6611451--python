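"""ROI construction, intensity rebalance, seeding, flow stepping and the
attrition/reseed logic."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from fasctrack.geometry import FrameSpec, Line2D, Segment2D, StructureRole, fit_line
from fasctrack.tracking import (
    OrientedROI,
    PointCloud,
    TrackerConfig,
    TrackingLostError,
    TrackState,
    build_roi,
    rebalance_intensity,
    seed_points,
    track_step,
    track_video,
    update_structure,
)

SPEC = FrameSpec(width_px=256, height_px=256, mm_per_px=60.0 / 256, frame_rate_hz=60.0)


def textured_image(seed=0, shape=(256, 256)):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.uniform(0, 1, shape), 2.0)
    img = (img - img.min()) / (img.max() - img.min())
    return (img * 255).astype(np.uint8)


class TestTrackerConfig:
    def test_defaults_reproduce_validated_parameters(self):
        cfg = TrackerConfig()
        assert cfg.n_seed_points == 100
        assert cfg.block_size_mm == 3.0
        assert cfg.pyramid_levels == 4
        assert cfg.fb_error_mm == 2.0
        assert cfg.max_iterations == 30
        assert cfg.reseed_fraction == 0.10
        assert cfg.roi_axial_fraction_fascicle == 0.90

    @pytest.mark.parametrize(
        "mm_per_px, block_mm, expected",
        [
            (1.0, 3.0, 3),  # exact odd
            (1.0, 4.0, 3),  # tie between 3 and 5 -> smaller
            (0.5, 3.0, 5),  # 6 px -> nearest odd
            (60.0 / 512, 3.0, 25),  # 25.6 px -> 25
            (2.0, 1.0, 3),  # floor of 3
        ],
    )
    def test_block_size_to_odd_window(self, mm_per_px, block_mm, expected):
        spec = FrameSpec(100, 100, mm_per_px, 60.0)
        assert TrackerConfig(block_size_mm=block_mm).window_px(spec) == expected

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TrackerConfig(reseed_fraction=0.0)
        with pytest.raises(ValueError):
            TrackerConfig(n_seed_points=0)
        with pytest.raises(ValueError):
            TrackerConfig(fit="quadratic")


class TestBuildROI:
    def test_middle_90_percent_of_fascicle(self):
        seg = Segment2D((0, 0), (40, 0))
        roi = build_roi(seg, 0.90, 2.5)
        np.testing.assert_allclose(roi.center, (20, 0))
        assert roi.half_length_mm == pytest.approx(18.0)
        assert roi.half_width_mm == 2.5

    def test_full_fraction_spans_segment(self):
        roi = build_roi(Segment2D((0, 0), (40, 0)), 1.0, 2.5)
        assert roi.half_length_mm == pytest.approx(20.0)
        assert roi.contains(np.array([[0.0, 0.0], [40.0, 0.0]])).all()

    def test_rotation_equivariance_of_corners(self):
        a = np.radians(30)
        r = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        seg = Segment2D((0, 0), (40, 0))
        seg_r = Segment2D(tuple(r @ [0, 0]), tuple(r @ [40, 0]))
        corners = build_roi(seg, 0.9, 2.5).corners()
        corners_r = build_roi(seg_r, 0.9, 2.5).corners()
        np.testing.assert_allclose(corners_r, corners @ r.T, atol=1e-12)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            build_roi(Segment2D((0, 0), (1, 0)), 0.0, 2.5)


class TestRebalance:
    def roi(self):
        return OrientedROI(center=(30, 30), axis=(1, 0), half_length_mm=20,
                           half_width_mm=5)

    def test_constant_roi_unchanged(self):
        img = np.full((256, 256), 77, dtype=np.uint8)
        out = rebalance_intensity(img, self.roi(), SPEC)
        np.testing.assert_array_equal(out, img)

    def test_two_gray_levels_stretch_to_dtype_bounds(self):
        img = np.full((256, 256), 120, dtype=np.uint8)
        mask = self.roi().pixel_mask(SPEC)
        rows, cols = np.where(mask)
        img[rows[::2], cols[::2]] = 50
        img[rows[1::2], cols[1::2]] = 200
        out = rebalance_intensity(img, self.roi(), SPEC)
        vals = np.unique(out[mask])
        np.testing.assert_array_equal(vals, [0, 255])

    def test_percentiles_hit_dtype_bounds(self):
        rng = np.random.default_rng(1)
        img = rng.integers(40, 200, size=(256, 256)).astype(np.uint8)
        out = rebalance_intensity(img, self.roi(), SPEC)
        mask = self.roi().pixel_mask(SPEC)
        lo, hi = np.percentile(out[mask].astype(float), [1, 99])
        assert lo <= 2.0  # within quantisation of the stretch
        assert hi >= 253.0

    def test_outside_pixels_untouched(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(256, 256)).astype(np.uint8)
        out = rebalance_intensity(img, self.roi(), SPEC)
        mask = self.roi().pixel_mask(SPEC)
        np.testing.assert_array_equal(out[~mask], img[~mask])

    def test_roi_outside_image_rejected(self):
        roi = OrientedROI(center=(500, 500), axis=(1, 0), half_length_mm=5,
                          half_width_mm=2)
        with pytest.raises(ValueError):
            rebalance_intensity(np.zeros((256, 256), np.uint8), roi, SPEC)


class TestSeedPoints:
    def roi(self):
        return OrientedROI(center=(30, 30), axis=(1, 0), half_length_mm=18,
                           half_width_mm=2.5)

    def test_featureless_image_falls_back_to_even_grid(self):
        """In corners mode a uniform image has no corner responses, so
        seeding degrades to exactly the even grid."""
        img = np.full((256, 256), 100, dtype=np.uint8)
        corners = TrackerConfig(seeding="corners")
        cloud = seed_points(img, self.roi(), 100, SPEC, corners)
        assert cloud.positions.shape == (100, 2)
        assert cloud.valid.all()
        assert self.roi().contains(cloud.positions).all()
        # grid evenness: unique axis offsets are equally spaced
        u = np.unique(np.round(self.roi().local_coords(cloud.positions)[:, 0], 9))
        steps = np.diff(u)
        np.testing.assert_allclose(steps, steps[0], atol=1e-9)
        # and identical to default grid seeding
        grid = seed_points(img, self.roi(), 100, SPEC)
        np.testing.assert_array_equal(np.sort(cloud.positions, axis=0),
                                      np.sort(grid.positions, axis=0))

    def test_grid_cloud_refits_to_drawn_line(self):
        cloud = seed_points(textured_image(9), self.roi(), 100, SPEC)
        line = fit_line(cloud.positions)
        axis_line = Line2D(self.roi().center, self.roi().axis)
        assert line.isclose(axis_line, atol=1e-9)

    def test_gain_invariance_of_grid_fallback(self):
        img = np.full((256, 256), 100, dtype=np.uint8)
        corners = TrackerConfig(seeding="corners")
        a = seed_points(img, self.roi(), 60, SPEC, corners)
        b = seed_points((img * 0.5).astype(np.uint8), self.roi(), 60, SPEC, corners)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_isolated_blob_is_detected_in_corners_mode(self):
        img = np.full((256, 256), 20.0)
        yy, xx = np.mgrid[0:256, 0:256]
        cy, cx = 128, 128  # mm (30, 30) on this raster
        img += 200 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 3.0**2))
        img = img.astype(np.uint8)
        cloud = seed_points(img, self.roi(), 20, SPEC, TrackerConfig(seeding="corners"))
        blob_mm = np.array([cx, cy]) * SPEC.mm_per_px
        dmin = np.linalg.norm(cloud.positions - blob_mm, axis=1).min()
        assert dmin < 2 * SPEC.mm_per_px

    def test_all_points_inside_roi_in_both_modes(self):
        for mode in ("grid", "corners"):
            cloud = seed_points(
                textured_image(3), self.roi(), 100, SPEC, TrackerConfig(seeding=mode)
            )
            assert self.roi().contains(cloud.positions).all()
            assert cloud.positions.shape[0] == 100


class TestTrackStep:
    def make_cloud(self, pts_mm):
        return PointCloud(
            positions=np.asarray(pts_mm, float),
            valid=np.ones(len(pts_mm), bool),
            frame_index=0,
            structure=StructureRole.FASCICLE,
        )

    def grid_cloud(self):
        g = np.linspace(15, 45, 6)
        pts = np.array([[x, y] for x in g for y in g])
        return self.make_cloud(pts)

    def test_static_pair_zero_displacement(self):
        img = textured_image(0)
        cloud = self.grid_cloud()
        out = track_step(img, img, cloud, TrackerConfig(), SPEC)
        assert out.valid.all()
        disp = np.linalg.norm(out.positions - cloud.positions, axis=1)
        assert disp.max() < 0.05

    def test_integer_shift_recovered(self):
        img = textured_image(1)
        shifted = np.roll(img, 3, axis=1)  # +3 px in x
        cloud = self.grid_cloud()
        out = track_step(img, shifted, cloud, TrackerConfig(), SPEC)
        disp = out.positions - cloud.positions
        expected = np.array([3 * SPEC.mm_per_px, 0.0])
        err = np.linalg.norm(disp[out.valid] - expected, axis=1)
        assert np.median(err) < 0.1
        assert out.valid.mean() > 0.9

    def test_point_leaving_frame_invalidated(self):
        img = textured_image(2)
        shifted = np.roll(img, -5, axis=1)  # content moves toward x = 0
        near_edge = self.make_cloud([[2 * SPEC.mm_per_px, 30.0]])
        out = track_step(img, shifted, near_edge, TrackerConfig(), SPEC)
        assert not out.valid[0]

    def test_invalid_inputs_stay_invalid(self):
        img = textured_image(0)
        cloud = self.grid_cloud()
        cloud.valid[::2] = False
        out = track_step(img, img, cloud, TrackerConfig(), SPEC)
        assert not out.valid[::2].any()
        np.testing.assert_array_equal(out.positions[::2], cloud.positions[::2])


class TestUpdateStructure:
    def make_state(self, n=100):
        img = textured_image(5)
        roi = OrientedROI(center=(30, 30), axis=(1, 0), half_length_mm=18,
                          half_width_mm=2.5)
        cloud = seed_points(img, roi, n, SPEC, structure=StructureRole.FASCICLE)
        line = fit_line(cloud.positions)
        return img, TrackState(
            role=StructureRole.FASCICLE, cloud=cloud, line=line, roi=roi,
            prior_count=cloud.positions.shape[0],
        )

    def invalidate(self, cloud, k):
        new = PointCloud(
            positions=cloud.positions.copy(),
            valid=cloud.valid.copy(),
            frame_index=cloud.frame_index + 1,
            structure=cloud.structure,
        )
        new.valid[:k] = False
        return new

    def test_five_percent_loss_keeps_cloud(self):
        img, state = self.make_state()
        new = self.invalidate(state.cloud, 5)
        out = update_structure(state, new, img, TrackerConfig(), SPEC)
        assert out.reseed_count == 0
        assert out.cloud.positions.shape[0] == 95

    def test_eleven_percent_loss_triggers_reseed_to_full_count(self):
        img, state = self.make_state()
        new = self.invalidate(state.cloud, 11)
        out = update_structure(state, new, img, TrackerConfig(), SPEC)
        assert out.reseed_count == 1
        assert out.cloud.positions.shape[0] == 100

    def test_exactly_ten_percent_does_not_reseed(self):
        img, state = self.make_state()
        new = self.invalidate(state.cloud, 10)
        out = update_structure(state, new, img, TrackerConfig(), SPEC)
        assert out.reseed_count == 0

    def test_total_loss_is_fatal(self):
        img, state = self.make_state()
        new = self.invalidate(state.cloud, 100)
        with pytest.raises(TrackingLostError, match="fascicle.*frame 1"):
            update_structure(state, new, img, TrackerConfig(), SPEC)

    def test_too_few_survivors_triggers_reseed(self):
        img, state = self.make_state()
        new = self.invalidate(state.cloud, 97)  # 3 survivors < min_points_for_fit
        out = update_structure(state, new, img, TrackerConfig(), SPEC)
        assert out.reseed_count == 1
        assert out.cloud.positions.shape[0] == 100


class TestTrackVideo:
    def test_deterministic_given_seed(self, small_static_video):
        cfg, frames, annotation = small_static_video
        r1 = track_video(frames, annotation, TrackerConfig(), cfg.frame_spec)
        r2 = track_video(frames, annotation, TrackerConfig(), cfg.frame_spec)
        np.testing.assert_array_equal(r1.series.lengths_mm, r2.series.lengths_mm)
        np.testing.assert_array_equal(r1.series.pennations_deg, r2.series.pennations_deg)

    def test_static_video_measurements_constant(self, small_static_video):
        cfg, frames, annotation = small_static_video
        res = track_video(frames, annotation, TrackerConfig(), cfg.frame_spec)
        assert np.ptp(res.series.lengths_mm) < 0.1
        assert np.ptp(res.series.pennations_deg) < 0.1

    def test_every_frame_has_three_lines_and_counts_bounded(self, small_static_video):
        cfg, frames, annotation = small_static_video
        res = track_video(frames, annotation, TrackerConfig(), cfg.frame_spec)
        for lines, clouds in zip(res.lines, res.clouds):
            assert set(lines) == set(StructureRole)
            for cloud in clouds.values():
                assert cloud.positions.shape[0] <= 100

    def test_point_count_non_increasing_between_reseeds(self, small_static_video):
        cfg, frames, annotation = small_static_video
        res = track_video(frames, annotation, TrackerConfig(), cfg.frame_spec)
        reseed_frames = {(t, role) for t, role in res.reseed_events}
        for role in StructureRole:
            counts = [c[role].positions.shape[0] for c in res.clouds]
            for t in range(1, len(counts)):
                if (t, role) not in reseed_frames:
                    assert counts[t] <= counts[t - 1]

    def test_rigid_translation_equivariance(self, small_static_video):
        cfg, frames, annotation = small_static_video
        base = track_video(frames, annotation, TrackerConfig(), cfg.frame_spec)
        dx_px = 6
        dx_mm = dx_px * cfg.frame_spec.mm_per_px
        shifted_frames = np.roll(frames, dx_px, axis=2)
        shifted_ann = {
            role: Segment2D(
                (seg.p0[0] + dx_mm, seg.p0[1]), (seg.p1[0] + dx_mm, seg.p1[1])
            )
            for role, seg in annotation.items()
        }
        shifted = track_video(shifted_frames, shifted_ann, TrackerConfig(),
                              cfg.frame_spec)
        assert np.abs(shifted.series.lengths_mm - base.series.lengths_mm).max() < 0.1
        assert np.abs(
            shifted.series.pennations_deg - base.series.pennations_deg
        ).max() < 0.1

    def test_global_gain_leaves_measurements_stable(self, small_static_video):
        cfg, frames, annotation = small_static_video
        base_frames = frames.astype(np.float64) / 255.0
        gained = 0.6 * base_frames
        r1 = track_video(base_frames, annotation, TrackerConfig(), cfg.frame_spec)
        r2 = track_video(gained, annotation, TrackerConfig(), cfg.frame_spec)
        assert np.abs(r1.series.lengths_mm - r2.series.lengths_mm).max() < 0.2
        assert np.abs(r1.series.pennations_deg - r2.series.pennations_deg).max() < 0.2

    def test_input_validation(self, small_static_video):
        cfg, frames, annotation = small_static_video
        with pytest.raises(ValueError, match="two frames"):
            track_video(frames[:1], annotation, TrackerConfig(), cfg.frame_spec)
        incomplete = dict(annotation)
        incomplete.pop(StructureRole.FASCICLE)
        with pytest.raises(ValueError, match="fascicle"):
            track_video(frames, incomplete, TrackerConfig(), cfg.frame_spec)
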