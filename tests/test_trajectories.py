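"""Daily-track segmentation and movement-metric correctness."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolfmove.trajectories import (
    DailyTrack,
    daily_distance,
    filter_complete,
    net_displacement,
    segment_days,
    straightness,
    summarize_metrics,
    track_metrics,
)
from wolfmove.validation import oracle_track_metrics


def make_track(xs, ys):
    n = len(xs)
    return DailyTrack(
        individual_id="w",
        track_date=pd.Timestamp("2010-03-01").date(),
        timestamps=pd.DatetimeIndex(pd.date_range("2010-03-01 16:00", periods=n, freq="2h")),
        x=np.asarray(xs, dtype=float),
        y=np.asarray(ys, dtype=float),
        slots=np.arange(n),
    )


def fixes_frame(times, xs, ys, ind="w1"):
    return pd.DataFrame(
        {"individual_id": ind, "timestamp": pd.to_datetime(times), "x_km": xs, "y_km": ys}
    )


class TestSegmentation:
    def test_full_day_yields_one_complete_track(self):
        times = pd.date_range("2010-03-01 16:00", periods=12, freq="2h")
        tracks = segment_days(fixes_frame(times, range(12), [0.0] * 12))
        assert len(tracks) == 1
        assert tracks[0].n_observed == 12
        assert tracks[0].completeness == 1.0
        assert tracks[0].track_date == pd.Timestamp("2010-03-01").date()

    def test_fix_in_afternoon_gap_belongs_to_no_track(self):
        tracks = segment_days(fixes_frame(["2010-03-01 15:00"], [0.0], [0.0]))
        assert tracks == []

    def test_fix_beyond_slot_tolerance_is_dropped(self):
        # 16:40 is 40 min from the 16:00 slot, outside the +/-30 min window
        tracks = segment_days(fixes_frame(["2010-03-01 16:40"], [0.0], [0.0]))
        assert tracks == []

    def test_eleven_of_twelve_slots_retained_by_filter(self):
        times = pd.date_range("2010-03-01 16:00", periods=12, freq="2h")[:-1]
        tracks = segment_days(fixes_frame(times, range(11), [0.0] * 11))
        assert tracks[0].n_observed == 11
        assert tracks[0].completeness == pytest.approx(11 / 12)
        kept, rep = filter_complete(tracks)
        assert len(kept) == 1 and rep["n_dropped"] == 0

    @pytest.mark.parametrize("n_obs,survives", [(12, True), (11, True), (10, False), (2, False)])
    def test_completeness_filter_threshold(self, n_obs, survives):
        times = pd.date_range("2010-03-01 16:00", periods=12, freq="2h")[:n_obs]
        tracks = segment_days(fixes_frame(times, range(n_obs), [0.0] * n_obs))
        kept, _ = filter_complete(tracks)
        assert bool(kept) is survives

    def test_duplicate_timestamp_is_an_error(self):
        t = ["2010-03-01 16:00", "2010-03-01 16:00"]
        with pytest.raises(ValueError, match="duplicate"):
            segment_days(fixes_frame(t, [0.0, 1.0], [0.0, 0.0]))

    def test_midnight_crossing_assigns_to_previous_day(self):
        tracks = segment_days(fixes_frame(["2010-03-02 02:00"], [0.0], [0.0]))
        assert tracks[0].track_date == pd.Timestamp("2010-03-01").date()
        assert tracks[0].slots[0] == 5


class TestMetrics:
    def test_collinear_unit_steps(self):
        t = make_track([0, 1, 2], [0, 0, 0])
        assert daily_distance(t) == pytest.approx(2.0)
        assert straightness(t) == pytest.approx(1.0)

    def test_stationary_track_distance_zero_straightness_undefined(self):
        t = make_track([0, 0], [0, 0])
        assert daily_distance(t) == 0.0
        assert math.isnan(straightness(t))

    def test_circle_chord_lengths(self):
        # 12 fixes on a unit circle at 30-degree spacing: 11 chords of 2 sin(15 deg)
        ang = np.deg2rad(np.arange(12) * 30.0)
        t = make_track(np.cos(ang), np.sin(ang))
        assert daily_distance(t) == pytest.approx(11 * 2 * math.sin(math.radians(15)), abs=1e-12)

    def test_net_displacement_345_triangle(self):
        t = make_track([0, 1, 3], [0, 2, 4])
        assert net_displacement(t) == pytest.approx(5.0)

    def test_closed_loop_net_zero(self):
        t = make_track([0, 1, 0], [0, 1, 0])
        assert net_displacement(t) == 0.0
        assert straightness(t) == 0.0

    def test_right_angle_straightness(self):
        t = make_track([0, 1, 1], [0, 0, 1])
        assert straightness(t) == pytest.approx(math.sqrt(2) / 2, abs=1e-12)

    def test_single_fix_metrics_undefined(self):
        t = make_track([0.0], [0.0])
        assert math.isnan(daily_distance(t)) and math.isnan(net_displacement(t))

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            xs, ys = rng.uniform(0, 20, n), rng.uniform(0, 20, n)
            t = make_track(xs, ys)
            odd, ond, ost = oracle_track_metrics(xs, ys)
            assert daily_distance(t) == pytest.approx(odd, abs=1e-9)
            assert net_displacement(t) == pytest.approx(ond, abs=1e-9)
            assert net_displacement(t) <= daily_distance(t) + 1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        pts=st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
            ),
            min_size=2,
            max_size=12,
        ),
        angle=st.floats(0, 2 * math.pi),
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
    )
    def test_metrics_invariant_under_rigid_motion(self, pts, angle, dx, dy):
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        c, s = math.cos(angle), math.sin(angle)
        xr = c * xs - s * ys + dx
        yr = s * xs + c * ys + dy
        t0, t1 = make_track(xs, ys), make_track(xr, yr)
        assert daily_distance(t1) == pytest.approx(daily_distance(t0), abs=1e-7)
        assert net_displacement(t1) == pytest.approx(net_displacement(t0), abs=1e-7)


class TestSummaries:
    def test_constant_metric_degenerate_summary(self):
        m = pd.DataFrame(
            {
                "daily_distance_km": [3.0] * 5,
                "net_displacement_km": [1.0] * 5,
                "straightness": [0.5] * 5,
            }
        )
        s = summarize_metrics(m)
        assert s.loc["daily_distance_km", "mean"] == 3.0
        assert s.loc["daily_distance_km", "sd"] == 0.0
        assert s.loc["daily_distance_km", "iqr"] == 0.0

    def test_quartiles_linear_interpolation(self):
        m = pd.DataFrame(
            {
                "daily_distance_km": [1.0, 2.0, 3.0, 4.0],
                "net_displacement_km": [1.0, 1.0, 1.0, 2.0],
                "straightness": [0.1, 0.2, 0.3, 0.4],
            }
        )
        s = summarize_metrics(m)
        assert s.loc["daily_distance_km", "mean"] == pytest.approx(2.5)
        assert s.loc["daily_distance_km", "q1"] == pytest.approx(1.75)
        assert s.loc["daily_distance_km", "q3"] == pytest.approx(3.25)
        assert s.loc["daily_distance_km", "iqr"] == pytest.approx(1.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_metrics(pd.DataFrame(columns=["daily_distance_km"]))

    def test_straightness_summaries_bounded(self, sim_tracks):
        from wolfmove.trajectories import segment_days

        tracks = segment_days(sim_tracks.fixes)
        m = track_metrics(tracks)
        s = summarize_metrics(m)
        assert 0.0 <= s.loc["straightness", "min"]
        assert s.loc["straightness", "max"] <= 1.0

    def test_triangle_inequality_on_simulator_output(self, sim_tracks):
        tracks = segment_days(sim_tracks.fixes)
        m = track_metrics(tracks)
        valid = m.dropna(subset=["daily_distance_km", "net_displacement_km"])
        assert (valid["net_displacement_km"] <= valid["daily_distance_km"] + 1e-9).all()
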