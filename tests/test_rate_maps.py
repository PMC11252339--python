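"""Rate maps, place fields and map statistics against hand-built oracles."""
import numpy as np
import pytest

from reomap import geometry as geom
from reomap.errors import GeometryError
from reomap.rate_maps import (ActivityTrain, PlaceField, RateMap, Trajectory,
                              align_positions, center_out_angle,
                              compress_to_square, compute_rate_map,
                              detect_place_fields, masked_pearson,
                              spatial_information, trial_rate_stats)


def _still_then_move(x_path, y_path, dt=1.0):
    """Trajectory visiting the listed points, one per second, fast enough to
    pass the 2 cm/s speed filter (steps >= 3 cm apart or forced via speed)."""
    t = np.arange(len(x_path)) * dt
    return Trajectory(t=t, x=np.asarray(x_path, float), y=np.asarray(y_path, float))


def _manual_map(rate, mask=None, bin_x=1.0, bin_y=1.0):
    rate = np.asarray(rate, float)
    mask = np.ones_like(rate, bool) if mask is None else np.asarray(mask, bool)
    grid = np.where(mask, rate, np.nan)
    return RateMap(rate=grid, occupancy=np.where(mask, 1.0, 0.0),
                   sampled_mask=mask, bin_x_cm=bin_x, bin_y_cm=bin_y,
                   sigma_cm=0.0)


class TestComputeRateMap:
    def test_no_events_gives_zero_rates_on_sampled_pixels(self):
        t = np.arange(600) * 0.1
        traj = Trajectory(t=t, x=geom.fold_into_interval(3.0 * t, 20.0),
                          y=geom.fold_into_interval(4.5 * t, 30.0))
        act = ActivityTrain(cell_id=0, times=np.array([]))
        m = compute_rate_map(traj, act)
        assert not m.empty
        assert np.all(m.sampled_rates() == 0.0)

    def test_unsmoothed_ratio_definition(self):
        # pixel visited for 2 s with one unit event -> 0.5 Hz (sigma -> 0)
        x = [5.5] * 3 + list(np.linspace(8, 16, 6))
        y = [5.5] * 3 + list(np.linspace(8, 26, 6))
        traj = Trajectory(t=np.arange(len(x), dtype=float),
                          x=np.array(x), y=np.array(y))
        # speeds: frames 0,1 are 0 cm/s (still) -> filtered out; use a moving
        # crossing instead: single fast pass through pixel (5,5)
        traj = _still_then_move([3.0, 5.5, 9.0, 12.0], [5.5, 5.5, 5.5, 5.5])
        act = ActivityTrain(cell_id=0, times=np.array([1.0]))
        m = compute_rate_map(traj, act, sigma_cm=0.0, occupancy_min_s=0.0)
        row, col = 5, 5
        assert m.occupancy[row, col] == pytest.approx(1.0)
        assert m.rate[row, col] == pytest.approx(1.0)

    def test_slow_samples_and_their_events_are_excluded(self):
        # stationary frames (speed 0) contribute neither time nor events;
        # the forward-difference convention keeps the departing frame only
        x = [5.5, 5.5, 5.5, 9.0, 12.0, 15.0]
        y = [5.5, 5.5, 5.5, 5.5, 5.5, 5.5]
        traj = _still_then_move(x, y)
        act = ActivityTrain(cell_id=0, times=np.array([0.5, 1.5]))
        m = compute_rate_map(traj, act, sigma_cm=0.0, occupancy_min_s=0.0)
        assert m.occupancy[5, 5] == 1.0     # two still frames of three dropped
        assert np.nansum(np.where(m.sampled_mask, m.rate, 0)) == 0.0

    def test_zero_filtered_occupancy_flags_empty(self):
        traj = _still_then_move([5.0] * 5, [5.0] * 5)  # never moves
        act = ActivityTrain(cell_id=0, times=np.array([1.0]))
        m = compute_rate_map(traj, act)
        assert m.empty and not m.sampled_mask.any()

    def test_homogeneous_poisson_mean_rate(self, rng):
        # uniform-ish coverage, events at 5 Hz: mean sampled rate ~ 5 Hz
        n = 4000
        t = np.arange(n) / 10.0
        x = geom.fold_into_interval(np.cumsum(rng.normal(0, 0.8, n)) + 10, 20.0)
        y = geom.fold_into_interval(np.cumsum(rng.normal(0, 0.8, n)) + 15, 30.0)
        traj = Trajectory(t=t, x=x, y=y)
        keep = traj.speed > 2.0
        lam = 5.0
        counts = rng.poisson(lam * traj.frame_dt)
        times = np.repeat(traj.t, counts)
        m = compute_rate_map(traj, ActivityTrain(cell_id=0, times=times))
        total_t = traj.frame_dt[keep].sum()
        se = 3 * np.sqrt(lam / total_t)
        occ = m.occupancy[m.sampled_mask]
        mean_rate = np.average(m.sampled_rates(), weights=occ)
        assert abs(mean_rate - lam) < max(3 * se, 0.5)


class TestCompressToSquare:
    def test_shape_and_bin_arithmetic(self, day1_tables):
        cid = day1_tables.cell_ids[0]
        sq = day1_tables.square_maps[cid][0]
        assert sq.shape == (20, 20)
        assert sq.bin_y_cm == 1.5

    def test_single_pixel_lands_in_expected_bin(self):
        traj = _still_then_move([3.0, 7.4, 11.0, 15.0], [20.0, 20.0, 20.0, 20.0])
        act = ActivityTrain(cell_id=0, times=np.array([1.0]))
        native = compute_rate_map(traj, act, sigma_cm=0.0, occupancy_min_s=0.0)
        sq = compress_to_square(native)
        # event at (x=7.4, y=20.0): x bin 7, y bin floor(20/1.5)=13
        assert sq.raw.ev_x[0] == 7.4
        assert sq.rate[13, 7] > 0

    def test_event_weight_conserved_before_normalization(self, day1_tables):
        cid = day1_tables.cell_ids[1]
        nm = day1_tables.native_maps[cid][0]
        sq = day1_tables.square_maps[cid][0]
        assert nm.raw.ev_w.sum() == pytest.approx(sq.raw.ev_w.sum())

    def test_double_compression_rejected(self, day1_tables):
        cid = day1_tables.cell_ids[0]
        with pytest.raises(GeometryError):
            compress_to_square(day1_tables.square_maps[cid][0])


class TestAlignPositions:
    def test_identity_when_already_canonical(self):
        pts = np.array([[3.0, 4.0], [10.0, 20.0]])
        out = align_positions(pts, geom.CANONICAL_CORNERS)
        assert np.allclose(out, pts, atol=1e-9)

    def test_rotated_chamber_maps_back(self):
        # chamber rotated 90 deg in the video frame
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        video_corners = geom.CANONICAL_CORNERS @ R.T + 100.0
        video_pts = np.array([[5.0, 7.0], [12.0, 25.0]]) @ R.T + 100.0
        out = align_positions(video_pts, video_corners)
        assert np.allclose(out, [[5.0, 7.0], [12.0, 25.0]], atol=1e-9)

    def test_synthetic_homography_round_trip(self, rng):
        # a known projective warp applied to the corners is exactly inverted
        H = np.array([[1.1, 0.05, 2.0], [-0.03, 0.95, 1.0], [1e-3, -5e-4, 1.0]])

        def warp(p):
            q = np.c_[p, np.ones(len(p))] @ H.T
            return q[:, :2] / q[:, 2:]

        pts = rng.uniform([0, 0], [20, 30], size=(50, 2))
        out = align_positions(warp(pts), warp(geom.CANONICAL_CORNERS))
        assert np.max(np.abs(out - pts)) < 1e-6

    def test_collinear_corners_rejected(self):
        bad = np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]])
        with pytest.raises(GeometryError):
            align_positions(np.zeros((1, 2)), bad)


class TestPlaceFields:
    def test_single_bump_detected_with_peak_inside(self):
        yy, xx = np.mgrid[0:30, 0:20]
        bump = np.exp(-((xx - 14) ** 2 + (yy - 22) ** 2) / 8.0)
        m = _manual_map(bump)
        fields = detect_place_fields(m)
        assert len(fields) == 1
        assert any((r, c) == (22, 14) for r, c in fields[0].pixels)

    def test_two_bumps_sorted_by_area(self):
        grid = np.zeros((30, 20))
        grid[4:9, 3:8] = 10.0       # 25 px
        grid[20:22, 14:16] = 12.0   # 4 px, higher peak
        m = _manual_map(grid)
        fields = detect_place_fields(m, percentile=80.0)
        assert len(fields) == 2
        assert fields[0].area > fields[1].area

    def test_toy_grid_matches_bruteforce_percentile_floodfill(self):
        rng = np.random.default_rng(5)
        grid = rng.uniform(0, 1, size=(6, 6))
        grid[1, 1] = grid[1, 2] = 5.0
        grid[4, 4] = 6.0
        m = _manual_map(grid)
        fields = detect_place_fields(m)
        thr = np.percentile(grid.ravel(), 95)
        expect = {(r, c) for r in range(6) for c in range(6) if grid[r, c] > thr}
        got = {tuple(p) for f in fields for p in f.pixels}
        assert got == expect

    def test_all_zero_map_has_no_fields(self):
        assert detect_place_fields(_manual_map(np.zeros((6, 6)))) == []

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(8)
        grid = rng.uniform(0, 2, size=(10, 10))
        a = detect_place_fields(_manual_map(grid))
        b = detect_place_fields(_manual_map(grid * 7.3))
        assert [set(map(tuple, f.pixels)) for f in a] == \
               [set(map(tuple, f.pixels)) for f in b]


class TestCenterOutAngle:
    def _field_at(self, centroid):
        return PlaceField(pixels=np.zeros((1, 2), int), rates=np.ones(1),
                          area=1, weighted_centroid_cm=centroid, peak_rate=1.0)

    def test_axis_conventions(self):
        cx, cy = geom.CHAMBER_CENTER
        assert center_out_angle(self._field_at((cx + 5, cy))) == pytest.approx(0.0)
        assert center_out_angle(self._field_at((cx, cy + 5))) == pytest.approx(90.0)
        assert center_out_angle(self._field_at((cx - 5, cy))) == pytest.approx(180.0)

    def test_centroid_at_center_is_undefined(self):
        assert center_out_angle(self._field_at(geom.CHAMBER_CENTER)) is None

    def test_weighted_centroid_arithmetic(self):
        # pixels (row, col) = (10,5), (10,6), (10,7) with rates (1, 2, 1)
        grid = np.zeros((30, 20))
        grid[10, 5:8] = [1.0, 2.0, 1.0]
        f = detect_place_fields(_manual_map(grid), percentile=50.0)[0]
        cx = (5.5 * 1 + 6.5 * 2 + 7.5 * 1) / 4
        assert f.weighted_centroid_cm == pytest.approx((cx, 10.5))
        expected = np.degrees(np.arctan2(10.5 - 15.0, cx - 10.0)) % 360
        assert center_out_angle(f) == pytest.approx(expected)


class TestRateStats:
    def test_mean_rate_ratio(self):
        traj = _still_then_move(np.linspace(1, 16, 6), [10.0] * 6)
        # all 6 frames moving (last dt repeated -> 6 s); 10 events kept
        act = ActivityTrain(cell_id=0, times=np.repeat([1.2, 2.2], 5))
        assert trial_rate_stats(act, traj, "mean") == pytest.approx(10 / 6)

    def test_empty_train_rate_zero(self):
        traj = _still_then_move(np.linspace(1, 16, 6), [10.0] * 6)
        act = ActivityTrain(cell_id=0, times=np.array([]))
        assert trial_rate_stats(act, traj, "mean") == 0.0

    def test_zero_filtered_time_undefined(self):
        traj = _still_then_move([5.0] * 4, [5.0] * 4)
        act = ActivityTrain(cell_id=0, times=np.array([1.0]))
        assert trial_rate_stats(act, traj, "mean") is None

    def test_peak_at_least_mean_map_rate(self, day1_tables):
        cid = day1_tables.cell_ids[0]
        m = day1_tables.native_maps[cid][0]
        assert np.nanmax(m.sampled_rates()) >= np.nanmean(m.sampled_rates())


class TestSpatialInformation:
    def test_uniform_map_carries_zero_bits(self):
        assert spatial_information(_manual_map(np.full((4, 4), 3.0))) == \
            pytest.approx(0.0)

    def test_point_mass_in_four_pixels_is_two_bits(self):
        grid = np.zeros((2, 2))
        grid[0, 0] = 4.0
        assert spatial_information(_manual_map(grid)) == pytest.approx(2.0)

    def test_three_pixel_toy_matches_formula(self):
        # p = (.5, .25, .25), lambda = (2, 1, 0)
        m = _manual_map(np.array([[2.0, 1.0, 0.0]]))
        m.occupancy = np.array([[2.0, 1.0, 1.0]])
        lam_bar = 0.5 * 2 + 0.25 * 1
        expected = 0.5 * (2 / lam_bar) * np.log2(2 / lam_bar) + \
            0.25 * (1 / lam_bar) * np.log2(1 / lam_bar)
        assert spatial_information(m) == pytest.approx(expected)

    def test_silent_map_undefined(self):
        assert spatial_information(_manual_map(np.zeros((3, 3)))) is None


class TestMaskedPearson:
    def test_masked_pixels_never_enter(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 5, 5))
        mask = np.ones((5, 5), bool)
        mask[0, 0] = False
        r1, n = masked_pearson(a, b, mask, mask)
        a2 = a.copy()
        a2[0, 0] = 1e6
        r2, _ = masked_pearson(a2, b, mask, mask)
        assert r1 == r2 and n == 24

    def test_zero_variance_is_undefined(self):
        a = np.ones((3, 3))
        b = np.arange(9.0).reshape(3, 3)
        mask = np.ones((3, 3), bool)
        r, _ = masked_pearson(a, b, mask, mask)
        assert np.isnan(r)
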