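"""Zonal dwell, track length, speed, revisits, stops and the search score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvasearch import (
    ArenaConfig,
    category_of,
    compute_phase_metrics,
    count_revisits,
    count_stops,
    dwell_times,
    minute_bins,
    search_score,
    speed_series,
    track_length,
    zone_of,
    zone_times,
)
from conftest import make_repaired


class TestCategories:
    @pytest.mark.parametrize(
        "r,cat,zone",
        [(5.0, 1, 0), (8.0, 2, 1), (27.0, 6, 3), (0.0, 0, 0), (23.999, 5, 2), (24.0, 6, 3)],
    )
    def test_half_open_binning(self, r, cat, zone):
        assert category_of(r) == cat
        assert zone_of(r) == zone


class TestDwell:
    def test_constant_radius(self):
        t = make_repaired(np.full(600, 10.0))  # 300 s at 2 fps
        d = dwell_times(t, (0.0, 300.0))
        assert d[2] == 300.0 and d.sum() == 300.0

    def test_split_between_two_radii(self):
        r = np.where(np.arange(600) % 2 == 0, 5.0, 25.0)
        d = dwell_times(make_repaired(r), (0.0, 300.0))
        assert d[1] == 150.0 and d[6] == 150.0

    def test_conservation_over_categories(self):
        rng = np.random.default_rng(1)
        t = make_repaired(rng.uniform(0, 30, 600))
        assert dwell_times(t, (0.0, 300.0)).sum() == pytest.approx(300.0)

    def test_zone_times_sum_categories(self):
        d = np.arange(7.0)
        z = zone_times(d)
        np.testing.assert_array_equal(z, [1.0, 5.0, 9.0, 6.0])
        assert z.sum() == d.sum()


class TestTrackLength:
    def test_stationary_is_zero(self):
        total, per_cat = track_length(make_repaired(np.full(100, 10.0)), (0.0, 50.0))
        assert total == 0.0 and per_cat.sum() == 0.0

    def test_straight_crawl(self):
        x = np.arange(100) * 0.5
        total, _ = track_length(make_repaired(x), (0.0, 50.0))
        assert total == pytest.approx(49.5)

    def test_circle_length_approaches_circumference(self):
        n = 2000
        ang = np.linspace(0, 2 * np.pi, n + 1)
        t = make_repaired(10 * np.cos(ang), 10 * np.sin(ang))
        total, per_cat = track_length(t, (0.0, 1e9))
        assert total == pytest.approx(2 * np.pi * 10, rel=1e-5)
        assert per_cat[2] == pytest.approx(total)  # all steps start at r = 10

    def test_per_category_lengths_sum_to_total(self):
        rng = np.random.default_rng(2)
        t = make_repaired(rng.uniform(-20, 20, 500), rng.uniform(-20, 20, 500))
        total, per_cat = track_length(t, (0.0, 250.0))
        assert per_cat.sum() == pytest.approx(total, abs=1e-9)

    def test_edge_assigned_steps_excluded(self):
        t = make_repaired(np.arange(10, dtype=float))
        t.provenance[4] = "edge_assigned"
        t.x_mm[4] = np.nan
        t.y_mm[4] = np.nan
        total, _ = track_length(t, (0.0, 5.0))
        assert total == pytest.approx(7.0)  # 9 steps minus the two touching frame 4


class TestSpeed:
    def test_step_to_speed_conversion(self):
        t = make_repaired([0.0, 0.5, 1.0])
        s = speed_series(t, (0.0, 2.0))
        np.testing.assert_allclose(s.instantaneous_mm_s, [1.0, 1.0])
        assert s.median_mm_s == 1.0

    def test_constant_speed_average_equals_instantaneous(self):
        t = make_repaired(np.arange(50) * 0.3)
        s = speed_series(t, (0.0, 25.0))
        np.testing.assert_allclose(s.smoothed_mm_s, s.instantaneous_mm_s[0], atol=1e-12)

    def test_alternating_steps_average_to_half(self):
        # steps alternate 0 and 0.5 mm -> speeds alternate 0 and 1 mm/s
        x = np.repeat(np.arange(30) * 0.5, 2)
        s = speed_series(make_repaired(x), (0.0, 30.0), avg_frames=10)
        np.testing.assert_allclose(s.smoothed_mm_s, 0.5, atol=1e-12)
        # independent oracle: direct window means
        direct = [np.mean(s.instantaneous_mm_s[i : i + 10]) for i in range(s.instantaneous_mm_s.size - 9)]
        np.testing.assert_allclose(s.smoothed_mm_s, direct, atol=1e-12)


class TestRevisits:
    def test_hand_traced_crossings(self):
        t = make_repaired([25.0, 12.0, 7.0, 9.0, 7.0, 30.0])
        assert count_revisits(t, (0.0, 3.0), 8.0) == 2

    def test_never_entering_zone(self):
        t = make_repaired(np.linspace(10, 30, 50))
        assert count_revisits(t, (0.0, 25.0), 8.0) == 0

    def test_starting_inside_does_not_count(self):
        t = make_repaired(np.full(50, 5.0))
        assert count_revisits(t, (0.0, 25.0), 8.0) == 0

    def test_boundary_landing_counts_as_entry(self):
        t = make_repaired([10.0, 8.0, 10.0])
        assert count_revisits(t, (0.0, 1.5), 8.0) == 1

    def test_entries_match_exits_on_closed_loops(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            r = np.concatenate([[20.0], rng.uniform(2, 28, 200), [20.0]])
            t = make_repaired(r)
            inside = r <= 8.0
            entries = np.count_nonzero(~inside[:-1] & inside[1:])
            exits = np.count_nonzero(inside[:-1] & ~inside[1:])
            assert count_revisits(t, (0.0, 1e9), 8.0) == entries == exits


def track_from_steps(steps):
    """1-D track whose consecutive displacements are exactly `steps`."""
    return make_repaired(np.concatenate([[0.0], np.cumsum(steps)]) + 50.0)


class TestStops:
    def test_single_short_stop(self):
        steps = [0.2, 0.2, 0.01, 0.01, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2]
        n, ivls = count_stops(track_from_steps(steps), (0.0, 1e9))
        assert n == 1 and ivls == [(2, 3)]

    def test_stops_separated_by_four_moving_frames_merge(self):
        steps = [0.01, 0.2, 0.2, 0.2, 0.2, 0.01, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2]
        n, ivls = count_stops(track_from_steps(steps), (0.0, 1e9))
        assert n == 1 and ivls == [(0, 5)]

    def test_stops_separated_by_five_moving_frames_merge(self):
        steps = [0.01] + [0.2] * 5 + [0.01] + [0.2] * 6
        n, _ = count_stops(track_from_steps(steps), (0.0, 1e9))
        assert n == 1

    def test_stops_separated_by_six_moving_frames_stay_separate(self):
        steps = [0.01] + [0.2] * 6 + [0.01] + [0.2] * 6
        n, _ = count_stops(track_from_steps(steps), (0.0, 1e9))
        assert n == 2

    def test_all_moving_means_no_stop(self):
        n, ivls = count_stops(track_from_steps([0.2] * 20), (0.0, 1e9))
        assert n == 0 and ivls == []

    def test_open_stop_at_window_end_counts(self):
        steps = [0.2] * 5 + [0.01, 0.01]
        n, _ = count_stops(track_from_steps(steps), (0.0, 1e9))
        assert n == 1


class TestMinuteBins:
    def test_constant_radius_five_bins(self):
        t = make_repaired(np.full(600, 10.0))
        bins = minute_bins(t, (0.0, 300.0))
        assert len(bins) == 5
        assert all(b["mean_r_mm"] == pytest.approx(10.0) for b in bins)
        assert all(b["duration_s"] == 60.0 for b in bins)

    def test_linear_ramp_first_minute_mean(self):
        r = np.linspace(0, 30, 120, endpoint=False)  # 0..30 over the first minute
        bins = minute_bins(make_repaired(r), (0.0, 60.0))
        assert bins[0]["mean_r_mm"] == pytest.approx(15.0, abs=0.2)

    def test_trailing_partial_bin(self):
        t = make_repaired(np.full(250, 10.0))  # 125 s
        bins = minute_bins(t, (0.0, 125.0))
        assert len(bins) == 3
        assert bins[-1]["duration_s"] == pytest.approx(5.0)


class TestSearchScore:
    @pytest.mark.parametrize(
        "t_search,t_edge,total,expected",
        [(300.0, 0.0, 300.0, 1.0), (105.0, 195.0, 300.0, -0.3), (120.0, 120.0, 300.0, 0.0)],
    )
    def test_examples(self, t_search, t_edge, total, expected):
        z = [total - t_search - t_edge, t_search, 0.0, t_edge]
        assert search_score(z, total) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4))
    def test_antisymmetric_under_zone_swap(self, z):
        total = sum(z) or 1.0
        swapped = [z[0], z[3], z[2], z[1]]
        assert search_score(z, total) == pytest.approx(-search_score(swapped, total))

    def test_rejects_zero_total(self):
        with pytest.raises(ValueError):
            search_score([0, 0, 0, 0], 0.0)


class TestComputePhaseMetrics:
    def test_full_metric_bundle_consistency(self, arena):
        rng = np.random.default_rng(9)
        ang = np.cumsum(rng.normal(0, 0.2, 600))
        r = np.clip(12 + rng.normal(0, 3, 600), 0, 29.9)
        t = make_repaired(r * np.cos(ang), r * np.sin(ang))
        pm = compute_phase_metrics(t, (0.0, 300.0), "search", arena)
        assert pm.time_per_category_s.sum() == pytest.approx(300.0)
        np.testing.assert_allclose(pm.time_per_zone_s, zone_times(pm.time_per_category_s))
        assert pm.length_per_category_mm.sum() == pytest.approx(pm.total_length_mm)
        assert -1.0 <= pm.search_score <= 1.0
        assert pm.time_in_center_zone_s == pm.time_per_zone_s[0]
        assert len(pm.r_per_minute_mm) == 5
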