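import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shoalkit import (
    AnalysisConfig,
    frame_polarization,
    nearest_neighbour_distances,
    smooth_velocities,
    summarize_trial,
)
from shoalkit.io_model import ValidationError
from shoalkit.kinematics_metrics import compute_frame_metrics

from conftest import boundary_completeness_trajectory, scripted_trajectory


def _single_fish_traj(x, y):
    """One-fish trajectory wrapper for testing the smoother on a series."""
    pos = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=-1)[:, None, :]
    from shoalkit import ArenaGeometry, TrajectoryDataset

    return TrajectoryDataset(
        trial_id="one", treatment="open_field", line="control", replicate="1",
        positions=pos, arena=ArenaGeometry(),
    )


class TestSavitzkyGolayVelocities:
    def test_exact_on_cubic_polynomial(self):
        t = np.arange(60.0)
        x = 1e-4 * t**3 - 0.01 * t**2 + 0.5 * t - 100.0
        y = -2e-5 * t**3 + 0.02 * t**2 - 0.3 * t + 50.0
        vel = smooth_velocities(_single_fish_traj(x, y), window=11, order=3)
        dx = 3e-4 * t**2 - 0.02 * t + 0.5
        dy = -6e-5 * t**2 + 0.04 * t - 0.3
        interior = slice(5, 55)
        np.testing.assert_allclose(vel[interior, 0, 0], dx[interior], atol=1e-9)
        np.testing.assert_allclose(vel[interior, 0, 1], dy[interior], atol=1e-9)
        assert np.isnan(vel[:5]).all() and np.isnan(vel[55:]).all()

    def test_constant_positions_give_zero_velocity(self):
        vel = smooth_velocities(_single_fish_traj(np.full(40, 7.0), np.full(40, -3.0)))
        assert np.nanmax(np.abs(vel)) == pytest.approx(0.0, abs=1e-12)

    def test_no_interpolation_across_gaps(self):
        x = np.linspace(-50, 50, 80)
        traj = _single_fish_traj(x, np.zeros_like(x))
        traj.positions[40, 0] = np.nan
        vel = smooth_velocities(traj, window=11)
        # the 5 frames flanking the hole on each side lose filter support
        assert np.isnan(vel[35:46, 0, 0]).all()
        assert np.isfinite(vel[34, 0, 0]) and np.isfinite(vel[46, 0, 0])

    def test_run_shorter_than_window_yields_no_velocity(self):
        x = np.linspace(0, 5, 9)  # 9 < window 11
        vel = smooth_velocities(_single_fish_traj(x, x))
        assert np.isnan(vel).all()

    def test_smoothing_beats_raw_differences_on_noisy_linear_motion(self):
        rng = np.random.default_rng(42)
        t = np.arange(300.0)
        true_v = 1.5
        x = true_v * t - 225.0 + rng.normal(0, 1.0, t.size)
        y = rng.normal(0, 1.0, t.size)
        traj = _single_fish_traj(x, y)
        vel = smooth_velocities(traj, window=11)
        smoothed_speed = np.linalg.norm(vel[5:-5, 0], axis=-1)
        raw = np.linalg.norm(np.diff(traj.positions[:, 0], axis=0), axis=-1)[4:-5]
        rmse_smooth = np.sqrt(np.mean((smoothed_speed - true_v) ** 2))
        rmse_raw = np.sqrt(np.mean((raw - true_v) ** 2))
        assert rmse_smooth < rmse_raw

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            smooth_velocities(_single_fish_traj(np.arange(30.0), np.arange(30.0)), window=10)


def _unit_vectors(deg):
    ang = np.radians(np.asarray(deg, float))
    return np.column_stack([np.cos(ang), np.sin(ang)])


class TestFramePolarization:
    @pytest.mark.parametrize(
        "angles, expected",
        [
            ([30.0] * 8, 1.0),                         # perfect alignment
            ([0, 0, 0, 180, 180, 180], 0.0),           # full cancellation
            ([0, 0, 90, 90, 180, 180], 1.0 / 3.0),     # hand unit-vector sum
        ],
    )
    def test_known_configurations(self, angles, expected):
        assert frame_polarization(_unit_vectors(angles)) == pytest.approx(expected, abs=1e-12)

    def test_below_min_headings_is_missing(self):
        assert np.isnan(frame_polarization(_unit_vectors([0, 10, 20, 30, 40])))

    @given(
        st.lists(st.floats(0, 360, allow_nan=False), min_size=6, max_size=8),
        st.floats(-360, 360, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_rotation_and_permutation_invariance(self, angles, rotation):
        rng = np.random.default_rng(0)
        base = frame_polarization(_unit_vectors(angles))
        rotated = frame_polarization(_unit_vectors(np.asarray(angles) + rotation))
        permuted = frame_polarization(_unit_vectors(rng.permutation(angles)))
        assert 0.0 <= base <= 1.0
        assert rotated == pytest.approx(base, abs=1e-9)
        assert permuted == pytest.approx(base, abs=1e-9)

    def test_matches_brute_force_vector_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            angles = rng.uniform(0, 360, rng.integers(6, 9))
            vecs = _unit_vectors(angles)
            brute = np.hypot(*np.sum(vecs, axis=0)) / len(angles)
            assert frame_polarization(vecs) == pytest.approx(brute, abs=1e-12)


class TestNearestNeighbourDistances:
    def test_collinear_hand_oracle(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        np.testing.assert_allclose(nearest_neighbour_distances(pos), [1.0, 1.0, 2.0])

    def test_two_fish_symmetric(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0]])
        np.testing.assert_allclose(nearest_neighbour_distances(pos), [5.0, 5.0])

    def test_fewer_than_two_tracked_all_missing(self):
        pos = np.array([[0.0, 0.0], [np.nan, np.nan]])
        assert np.isnan(nearest_neighbour_distances(pos)).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_and_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        pos = rng.uniform(-200, 200, (n, 2))
        got = nearest_neighbour_distances(pos)
        brute = np.array(
            [min(np.hypot(*(pos[i] - pos[j])) for j in range(n) if j != i) for i in range(n)]
        )
        np.testing.assert_allclose(got, brute, atol=1e-9)
        # rigid motion: rotate by a random angle and translate
        a = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        moved = pos @ rot.T + rng.uniform(-50, 50, 2)
        np.testing.assert_allclose(nearest_neighbour_distances(moved), got, atol=1e-9)


class TestTrialSummaries:
    def test_aligned_constant_speed_school(self, config):
        traj = scripted_trajectory(n_frames=300, speed=0.5)
        s = summarize_trial(traj, config)
        assert s.retained and s.completeness > 0.9
        assert s.median_polarization == pytest.approx(1.0, abs=1e-12)
        assert s.median_speed == pytest.approx(0.5, abs=1e-9)
        assert s.median_nnd == pytest.approx(6.0, abs=1e-9)  # fixed 6 mm lattice spacing

    @pytest.mark.parametrize(
        "fraction, retained", [(0.60, False), (0.70, True), (0.80, True)]
    )
    def test_completeness_boundary_is_inclusive(self, config, fraction, retained):
        traj = boundary_completeness_trajectory(fraction, config)
        s = summarize_trial(traj, config)
        assert s.completeness == pytest.approx(fraction, abs=1e-12)
        assert s.retained is retained
        if not retained:
            assert np.isnan(s.median_polarization)
            assert np.isnan(s.median_speed)
            assert np.isnan(s.median_nnd)

    def test_five_tracked_fish_contribute_no_polarization(self, config):
        traj = scripted_trajectory(n_frames=100)
        positions = traj.positions.copy()
        positions[:, 5:] = np.nan  # only 5 fish ever tracked
        traj2 = traj.__class__(
            trial_id="five", treatment="open_field", line="control",
            replicate="1", positions=positions, arena=traj.arena,
        )
        metrics = compute_frame_metrics(traj2, config)
        assert (metrics["n_tracked"] <= 5).all()
        assert metrics["polarization"].isna().all()

    def test_deleting_rows_never_increases_completeness(self, config):
        rng = np.random.default_rng(11)
        traj = scripted_trajectory(n_frames=200)
        base = summarize_trial(traj, config).completeness
        positions = traj.positions.copy()
        drop = rng.random(positions.shape[:2]) < 0.1
        positions[drop] = np.nan
        traj2 = traj.__class__(
            trial_id="holes", treatment="open_field", line="control",
            replicate="1", positions=positions, arena=traj.arena,
        )
        assert summarize_trial(traj2, config).completeness <= base
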