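import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from shoalkit import (
    OptomotorTrack,
    VirtualFishConfig,
    acuity_scores,
    default_schedule,
    fish_angular_speed,
    relative_orientation,
    score_segments,
    simulate_optomotor_fish,
)
from shoalkit.io_model import ValidationError
from shoalkit.optomotor import STIMULUS_SPEEDS, StimulusSchedule, StimulusSegment


def circular_track(speed_deg_s: float, direction: int, duration_s: float = 10.0,
                   radius: float = 180.0, fps: float = 25.0) -> OptomotorTrack:
    """Closed-form circular motion, clockwise positive."""
    t = np.arange(int(duration_s * fps)) / fps
    ang = np.radians(direction * speed_deg_s * t)
    return OptomotorTrack(
        radius * np.column_stack([np.sin(ang), np.cos(ang)]), fps=fps
    )


class TestRelativeOrientation:
    @pytest.mark.parametrize(
        "delta, expected",
        [(90.0, 90.0), (0.0, 0.0), (170.0, 10.0), (-90.0, -90.0), (180.0, 0.0)],
    )
    def test_arcsin_fold_table(self, delta, expected):
        assert relative_orientation(delta, 0.0) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(-720, 720, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_odd_bounded_and_periodic(self, delta):
        v = relative_orientation(delta, 0.0)
        assert -90.0 - 1e-9 <= v <= 90.0 + 1e-9
        assert relative_orientation(-delta, 0.0) == pytest.approx(-v, abs=1e-9)
        assert relative_orientation(delta + 360.0, 0.0) == pytest.approx(v, abs=1e-9)
        assert relative_orientation(delta, -360.0) == pytest.approx(v, abs=1e-9)


class TestAngularSpeed:
    @pytest.mark.parametrize("speed", STIMULUS_SPEEDS)
    @pytest.mark.parametrize("direction", [1, -1])
    def test_recovers_circular_motion(self, speed, direction):
        w = fish_angular_speed(circular_track(speed, direction))[1:]
        np.testing.assert_allclose(w, direction * speed, rtol=1e-6)

    def test_stationary_fish_has_zero_angular_speed(self):
        track = OptomotorTrack(np.tile([100.0, 50.0], (50, 1)))
        assert np.nanmax(np.abs(fish_angular_speed(track)[1:])) == 0.0

    def test_near_center_frames_are_missing(self):
        pos = np.tile([5.0, 0.0], (20, 1))  # inside the 10 mm exclusion radius
        assert np.isnan(fish_angular_speed(OptomotorTrack(pos))).all()


class TestScoreSegments:
    def test_perfect_follower_every_segment(self):
        schedule = default_schedule()
        track = simulate_optomotor_fish(VirtualFishConfig(gain=1.0), schedule)
        s = score_segments(track, schedule)
        assert (s.per_segment["proportion_following"] == 1.0).all()
        assert s.per_segment["speed_deviation"].abs().max() < 1e-9
        assert s.pooled["proportion_following"] == 1.0
        assert abs(s.pooled["speed_deviation"]) < 1e-9

    def test_half_gain_fish_lags_by_half_the_stimulus_speed(self):
        schedule = default_schedule()
        track = simulate_optomotor_fish(VirtualFishConfig(gain=0.5), schedule)
        s = score_segments(track, schedule)
        row = s.per_stimulus.query("speed_deg_s == 36")
        np.testing.assert_allclose(row["speed_deviation"], -18.0, atol=1e-9)

    def test_zero_gain_fish_deviation_equals_minus_stimulus(self):
        schedule = default_schedule()
        track = simulate_optomotor_fish(VirtualFishConfig(gain=0.0), schedule)
        s = score_segments(track, schedule)
        np.testing.assert_allclose(
            s.per_stimulus["speed_deviation"],
            -s.per_stimulus["speed_deg_s"],
            atol=1e-9,
        )

    def test_contrarian_fish_scores_zero(self):
        # constant CCW circling: every CW segment scores 0 following
        schedule = default_schedule()
        track = circular_track(20.0, -1, duration_s=schedule.total_s + 1)
        s = score_segments(track, schedule)
        cw = s.per_segment[s.per_segment["direction"] == "CW"]
        ccw = s.per_segment[s.per_segment["direction"] == "CCW"]
        assert (cw["proportion_following"] == 0.0).all()
        assert (ccw["proportion_following"] == 1.0).all()

    def test_pooled_is_duration_weighted_mean(self):
        schedule = default_schedule()
        track = simulate_optomotor_fish(
            VirtualFishConfig(gain=0.8, heading_noise=10.0, seed=4), schedule
        )
        s = score_segments(track, schedule)
        w = s.per_segment["duration_s"] / s.per_segment["duration_s"].sum()
        assert s.pooled["speed_deviation"] == pytest.approx(
            float((w * s.per_segment["speed_deviation"]).sum()), abs=1e-12
        )
        assert s.pooled["proportion_following"] == pytest.approx(
            float((w * s.per_segment["proportion_following"]).sum()), abs=1e-12
        )

    def test_following_monotone_in_gain(self):
        schedule = default_schedule()
        gains = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        props = []
        for g in gains:
            track = simulate_optomotor_fish(
                VirtualFishConfig(gain=g, heading_noise=15.0, seed=11), schedule
            )
            props.append(score_segments(track, schedule).pooled["proportion_following"])
        assert spearmanr(gains, props).statistic >= 0.9

    def test_short_track_lists_missing_segments(self):
        schedule = default_schedule()
        track = circular_track(20.0, 1, duration_s=400.0)
        with pytest.raises(ValidationError, match="missing segments"):
            score_segments(track, schedule)


class TestScheduleAndAcuity:
    def test_standard_schedule_structure(self):
        schedule = default_schedule()
        assert len(schedule.segments) == 40
        assert schedule.scored_s == pytest.approx(920.0)
        combos = {(s.speed_deg_s, s.direction) for s in schedule.segments}
        assert len(combos) == 8
        # segments are disjoint and separated by the 3 s transitions
        ordered = sorted(schedule.segments, key=lambda s: s.t_start_s)
        gaps = [b.t_start_s - a.t_end_s for a, b in zip(ordered, ordered[1:])]
        assert all(g == pytest.approx(3.0) for g in gaps)

    def test_schedule_yaml_roundtrip(self, tmp_path):
        schedule = default_schedule()
        schedule.to_yaml(tmp_path / "sched.yaml")
        back = StimulusSchedule.from_yaml(tmp_path / "sched.yaml")
        assert back.segments == schedule.segments
        assert back.acclimation_s == schedule.acclimation_s

    def test_nonstandard_schedule_warns(self):
        with pytest.warns(UserWarning, match="non-standard"):
            StimulusSchedule([StimulusSegment(25.0, 1, 300.0)])

    @pytest.mark.parametrize(
        "intervals, expected",
        [([(0.0, 30.0)], 0.5), ([], 0.0), ([(0.0, 10.0), (20.0, 50.0)], 40.0 / 60.0)],
    )
    def test_acuity_proportions(self, intervals, expected):
        out = acuity_scores({"band_1": intervals}, static_intervals=[(0.0, 15.0)])
        assert out.loc[0, "proportion_following"] == pytest.approx(expected)
        assert out.loc[0, "static_activity_proportion"] == pytest.approx(0.25)

    def test_acuity_interval_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            out = acuity_scores({"b": [(50.0, 70.0)]})
        assert out.loc[0, "proportion_following"] == pytest.approx(10.0 / 60.0)
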