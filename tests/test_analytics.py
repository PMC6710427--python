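import math

import numpy as np
import pytest

from animtrack.analytics import (NoDetectionsError, RegionSpec, bin_distances,
                                 instantaneous_velocity, normalise_path,
                                 region_occupancy, segment_cv, stride_analysis)
from animtrack.tracking import total_distance
from animtrack.video_io import calibrate_scale

from conftest import build_path


def constant_motion_path(n=60, speed=2.0, fps=30.0):
    t = np.arange(n, dtype=float)
    return build_path(np.column_stack([10 + speed * t, np.full(n, 50.0)]),
                      fps=fps)


class TestVelocity:
    def test_constant_speed_recovered_at_every_window(self):
        series = instantaneous_velocity(constant_motion_path(), window_frames=10)
        # 2 px/frame at 30 fps and 1 px/mm = 60 mm/s
        assert series.velocity_mm_per_s.size == 5
        assert np.allclose(series.velocity_mm_per_s, 60.0, rtol=1e-9)

    def test_stationary_path_gives_zeros(self):
        p = build_path(np.tile([30.0, 30.0], (40, 1)))
        series = instantaneous_velocity(p)
        assert series.velocity_mm_per_s.size > 0
        assert np.allclose(series.velocity_mm_per_s, 0.0)

    def test_window_longer_than_path_gives_empty_series(self):
        series = instantaneous_velocity(constant_motion_path(n=8), window_frames=10)
        assert series.velocity_mm_per_s.size == 0

    def test_windows_containing_gaps_are_omitted(self):
        xy = np.column_stack([np.arange(40.0), np.zeros(40)])
        xy[17] = np.nan  # breaks the second window
        series = instantaneous_velocity(build_path(xy), window_frames=10)
        assert series.frame_index.tolist() == [0, 18, 28]

    def test_default_window_at_30fps_spans_one_third_second(self):
        series = instantaneous_velocity(constant_motion_path(fps=30.0))
        window_ms = series.window_frames / 30.0 * 1000
        assert window_ms == pytest.approx(333, abs=0.5)

    def test_scaled_velocity(self):
        p = build_path(np.column_stack([np.arange(0, 120, 2.0), np.zeros(60)]),
                       fps=30.0, scale=calibrate_scale(2.0, 1.0))
        series = instantaneous_velocity(p)
        assert np.allclose(series.velocity_mm_per_s, 30.0)


class TestBins:
    def test_uniform_steps_fall_in_first_bin(self):
        bins = bin_distances(constant_motion_path(), bin_width_mm=10.0)
        assert len(bins.steps) == 1
        assert bins.steps["bin_left_mm"].iloc[0] == 0.0
        assert bins.steps["n_steps"].iloc[0] == 59

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_of_total_distance(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(scale=3, size=(80, 2)), axis=0)
        p = build_path(xy)
        bins = bin_distances(p, bin_width_mm=2.5)
        assert bins.total_mm == pytest.approx(total_distance(p), rel=1e-12)

    def test_fine_bins_aggregate_exactly_to_coarse(self):
        rng = np.random.default_rng(42)
        xy = np.cumsum(rng.normal(scale=4, size=(100, 2)), axis=0)
        p = build_path(xy)
        fine = bin_distances(p, bin_width_mm=5.0).steps
        coarse = bin_distances(p, bin_width_mm=10.0).steps
        agg = (fine.assign(k=(fine["bin_left_mm"] // 10).astype(int))
               .groupby("k")[["n_steps", "distance_mm"]].sum())
        for k, row in coarse.set_index((coarse["bin_left_mm"] // 10).astype(int)).iterrows():
            assert agg.loc[k, "n_steps"] == row["n_steps"]
            assert agg.loc[k, "distance_mm"] == pytest.approx(row["distance_mm"],
                                                              rel=1e-12)

    def test_non_positive_width_rejected(self):
        with pytest.raises(ValueError):
            bin_distances(constant_motion_path(), bin_width_mm=0.0)


class TestOccupancy:
    def test_whole_frame_region_is_one(self):
        p = constant_motion_path()
        assert region_occupancy(p, RegionSpec(0, 0, 320, 240)) == 1.0

    def test_exact_half_split(self):
        # 30 of 60 frames inside x <= 100
        xy = np.column_stack([np.concatenate([np.full(30, 50.0), np.full(30, 200.0)]),
                              np.full(60, 50.0)])
        p = build_path(xy)
        assert region_occupancy(p, RegionSpec(0, 0, 100, 240, "centre")) == 0.5

    def test_boundary_counts_as_inside(self):
        p = build_path([[10.0, 5.0]])
        assert region_occupancy(p, RegionSpec(0, 0, 10, 10)) == 1.0

    def test_single_found_frame_inside_is_one(self):
        xy = [[math.nan, math.nan], [5.0, 5.0], [math.nan, math.nan]]
        assert region_occupancy(build_path(xy), RegionSpec(0, 0, 10, 10)) == 1.0

    def test_no_detections_is_undefined_not_zero(self):
        p = build_path([[math.nan, math.nan]] * 4)
        with pytest.raises(NoDetectionsError):
            region_occupancy(p, RegionSpec(0, 0, 10, 10))

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_under_region_inclusion(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 200, size=(50, 2))
        p = build_path(xy)
        x, y = rng.uniform(0, 80, 2)
        w, h = rng.uniform(20, 60, 2)
        grow = rng.uniform(5, 40, 4)  # pad left/top/right/bottom
        inner = RegionSpec(x, y, w, h, "inner")
        outer = RegionSpec(x - grow[0], y - grow[1],
                           w + grow[0] + grow[2], h + grow[1] + grow[3], "outer")
        assert region_occupancy(p, inner) <= region_occupancy(p, outer)


class TestSegmentCV:
    def test_uniform_motion_has_zero_cv(self):
        p = constant_motion_path(n=360, fps=30.0)  # 12 s
        table = segment_cv(p, [1.0, 2.0, 3.0])
        assert (table["cv_percent"] == 0.0).all()

    def test_alternating_activity_matches_closed_form(self):
        """1 min active / 1 min stationary, 6 min at 1 fps: the six segment
        totals are {d,0,d,0,d,0} and CV must equal their closed form."""
        fps, seg = 1.0, 60
        blocks = []
        pos = 0.0
        for minute in range(6):
            if minute % 2 == 0:
                x = pos + 2.0 * np.arange(seg)
                pos = x[-1] + 2.0
            else:
                x = np.full(seg, pos - 2.0)
            blocks.append(x)
        xy = np.column_stack([np.concatenate(blocks), np.zeros(6 * seg)])
        p = build_path(xy, fps=fps)
        table = segment_cv(p, [60.0])
        totals = np.array([2.0 * (seg - 1), 0, 2.0 * (seg - 1), 0,
                           2.0 * (seg - 1), 0])
        expected = totals.std(ddof=1) / totals.mean() * 100
        assert table["cv_percent"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_cv_decreases_with_duration_on_random_walks(self):
        """Monte-Carlo: longer segments average out rate fluctuations, so the
        mean CV over 50 random walks is non-increasing in duration."""
        durations = [1.0, 2.0, 4.0]
        cvs = np.zeros((50, len(durations)))
        for i in range(50):
            rng = np.random.default_rng(1000 + i)
            steps = rng.exponential(scale=2.0, size=(240, 1)) * \
                rng.choice([-1, 1], size=(240, 1))
            xy = np.column_stack([np.cumsum(steps), np.zeros(240)])
            cvs[i] = segment_cv(build_path(xy, fps=30.0),
                                durations)["cv_percent"].to_numpy()
        mean_cv = cvs.mean(axis=0)
        assert mean_cv[0] >= mean_cv[1] >= mean_cv[2]

    def test_too_long_duration_skipped_with_warning(self):
        p = constant_motion_path(n=60, fps=30.0)  # 2 s of video
        with pytest.warns(UserWarning, match="skipped"):
            table = segment_cv(p, [1.5])
        assert table.empty


class TestNormalise:
    def test_first_found_point_maps_to_origin(self):
        xy = [[math.nan, math.nan], [7.0, 9.0], [10.0, 13.0]]
        norm = normalise_path(build_path(xy))
        _, pts = norm.found_positions()
        assert pts[0].tolist() == [0.0, 0.0]

    def test_distance_preserved_and_idempotent(self):
        rng = np.random.default_rng(5)
        p = build_path(np.cumsum(rng.normal(size=(30, 2)), axis=0) + 100)
        norm = normalise_path(p)
        assert total_distance(norm) == pytest.approx(total_distance(p), rel=1e-12)
        again = normalise_path(norm)
        assert again.found_positions()[1] == pytest.approx(norm.found_positions()[1])

    def test_no_detections_rejected(self):
        with pytest.raises(NoDetectionsError):
            normalise_path(build_path([[math.nan, math.nan]]))


def larva_path(length, width, fps=30.0, scale=None):
    n = len(length)
    xy = np.tile([100.0, 100.0], (n, 1))
    return build_path(xy, fps=fps, rect_l=length, rect_w=width,
                      scale=scale or calibrate_scale(1, 1))


def brute_force_pairs(smoothed):
    """Oracle: scan for alternating local max -> local min pairs."""
    ext = []
    for i in range(1, len(smoothed) - 1):
        if smoothed[i] >= smoothed[i - 1] and smoothed[i] > smoothed[i + 1]:
            ext.append((i, "p"))
        elif smoothed[i] <= smoothed[i - 1] and smoothed[i] < smoothed[i + 1]:
            ext.append((i, "t"))
    count = 0
    open_peak = None
    for _, kind in sorted(ext):
        if kind == "p":
            open_peak = True
        elif open_peak:
            count += 1
            open_peak = None
    return count


class TestStrides:
    def sinusoid(self, n=200, base=40.0, amp=6.0, period=20.0):
        t = np.arange(n)
        return base + amp * np.sin(2 * np.pi * t / period)

    def test_sinusoid_count_matches_brute_force_and_amplitude(self):
        length = self.sinusoid()
        prof = stride_analysis(larva_path(length, length / 4))
        assert prof.n_strides == brute_force_pairs(prof.smoothed_length_px)
        assert prof.mean_amplitude_mm == pytest.approx(12.0, rel=0.10)
        assert not prof.turn_frames

    @pytest.mark.parametrize("period", [12, 20, 40])
    def test_count_matches_oracle_across_periods(self, period):
        length = self.sinusoid(n=240, period=period)
        prof = stride_analysis(larva_path(length, length / 4), smooth_window=5)
        assert period >= 2 * prof.smooth_window
        assert prof.n_strides == brute_force_pairs(prof.smoothed_length_px)

    def test_constant_length_has_no_strides(self):
        prof = stride_analysis(larva_path(np.full(100, 40.0), np.full(100, 10.0)))
        assert prof.n_strides == 0
        assert math.isnan(prof.mean_amplitude_mm)

    @pytest.mark.parametrize("amp", [3.0, 6.0, 12.0])
    def test_amplitude_recovery_under_noise(self, amp):
        """Peak-to-trough recovery within 10% of 2×amp under ±0.5 px
        uniform measurement noise."""
        rng = np.random.default_rng(int(amp * 100))
        length = self.sinusoid(n=400, amp=amp, period=40) + \
            rng.uniform(-0.5, 0.5, size=400)
        prof = stride_analysis(larva_path(length, length / 4),
                               min_prominence_px=amp / 2)
        assert prof.n_strides > 0
        assert prof.mean_amplitude_mm == pytest.approx(2 * amp, rel=0.10)

    def test_turn_frames_flagged_and_excluded(self):
        """A mid-video curl (aspect 4 -> 1.5 for 15 frames) is flagged as a
        turn and hosts no stride event."""
        length = self.sinusoid()
        width = length / 4
        turn = slice(100, 115)
        length[turn] *= 0.6
        width[turn] = length[turn] / 1.5
        prof = stride_analysis(larva_path(length, width))
        flagged = set(prof.turn_frames)
        assert set(range(100, 115)) <= flagged
        for ev in prof.stride_events:
            assert set(range(ev.peak_frame, ev.trough_frame + 1)).isdisjoint(
                range(100, 115))

    def test_amplitude_converted_to_mm(self):
        length = self.sinusoid()
        prof = stride_analysis(larva_path(length, length / 4,
                                          scale=calibrate_scale(2, 1)))
        assert prof.mean_amplitude_mm == pytest.approx(6.0, rel=0.10)

    def test_even_smoothing_window_rejected(self):
        with pytest.raises(ValueError):
            stride_analysis(larva_path(np.full(20, 30.0), np.full(20, 10.0)),
                            smooth_window=4)

    def test_aspect_ratio_at_least_one(self):
        length = self.sinusoid()
        prof = stride_analysis(larva_path(length, length / 4))
        assert (prof.aspect_ratio >= 1).all()
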