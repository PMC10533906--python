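import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shoalkit import (
    AnalysisConfig,
    connected_group_frames,
    density_map,
    polarization_heatmap,
    polarization_speed_map,
    zone_polarization,
)
from shoalkit.io_model import ValidationError
from shoalkit.spatial_maps import _cell_index, _grid_edges

from conftest import scripted_trajectory


class TestConnectivityFilter:
    def test_chain_of_six_with_90mm_gaps_is_connected(self):
        pos = np.column_stack([np.arange(6) * 90.0, np.zeros(6)])[None]
        assert connected_group_frames(pos, link_dist=100.0, min_size=6)[0]

    def test_two_distant_clusters_of_four_fail(self):
        cluster = np.array([[0, 0], [5, 0], [0, 5], [5, 5]], dtype=float)
        pos = np.vstack([cluster, cluster + [300.0, 0.0]])[None]
        assert not connected_group_frames(pos, link_dist=100.0, min_size=6)[0]

    def test_coincident_fish_connected(self):
        pos = np.zeros((1, 8, 2))
        assert connected_group_frames(pos, link_dist=100.0, min_size=6)[0]

    def test_untracked_fish_do_not_count(self):
        pos = np.zeros((1, 8, 2))
        pos[0, :3] = np.nan
        assert not connected_group_frames(pos, link_dist=100.0, min_size=6)[0]
        assert connected_group_frames(pos, link_dist=100.0, min_size=5)[0]

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_networkx_components(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        pos = rng.uniform(-250, 250, (n, 2))
        link = float(rng.uniform(20, 200))
        min_size = int(rng.integers(2, n + 1))
        got = connected_group_frames(pos[None], link_dist=link, min_size=min_size)[0]
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(pos[i] - pos[j])) <= link:
                    g.add_edge(i, j)
        oracle = max(len(c) for c in nx.connected_components(g)) >= min_size
        assert got == oracle


def _pinned_group(mean_pol: float, trial_id: str):
    """A school whose centroid stays in cell [0,20)x[0,20) with per-frame
    polarization exactly ``mean_pol`` (half the fish head +alpha, half
    -alpha with cos(alpha) = mean_pol)."""
    alpha = np.degrees(np.arccos(mean_pol))
    angles = [alpha, -alpha] * 4
    return scripted_trajectory(
        n_frames=60, speed=0.2, heading_angles_deg=angles,
        start_centroid=(4.0, 10.0), spread=5.0, trial_id=trial_id,
    )


class TestPolarizationHeatmap:
    def test_eight_groups_in_one_cell_mean_and_support(self, config):
        pols = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        trials = [_pinned_group(p, f"g{i}") for i, p in enumerate(pols)]
        grid = polarization_heatmap(trials, config)
        xi = _cell_index(np.array([10.0]), grid.x_edges)[0]
        yi = _cell_index(np.array([10.0]), grid.y_edges)[0]
        assert grid.support[xi, yi] == 8
        assert not grid.mask[xi, yi]
        assert grid.values[xi, yi] == pytest.approx(0.45, abs=1e-9)
        # every unsuppressed cell has at least 8 supporting groups
        assert (grid.support[~grid.mask] >= config.min_groups_per_cell).all()

    def test_seven_groups_are_masked(self, config):
        trials = [_pinned_group(0.5, f"g{i}") for i in range(7)]
        grid = polarization_heatmap(trials, config)
        assert grid.mask.all()

    def test_single_group_all_cells_masked(self, config):
        grid = polarization_heatmap([_pinned_group(1.0, "solo")], config)
        assert grid.mask.all()

    def test_empty_input_gives_empty_map(self, config):
        grid = polarization_heatmap([], config)
        assert grid.values.size == 0

    def test_mixed_treatments_rejected(self, config):
        a = scripted_trajectory(trial_id="a", treatment="open_field")
        b = scripted_trajectory(trial_id="b", treatment="novel_object", stimulus=True)
        with pytest.raises(ValidationError, match="mix"):
            polarization_heatmap([a, b], config)

    def test_cell_edges_are_half_open_left_inclusive(self, config):
        edges = _grid_edges(scripted_trajectory().arena, config.grid_cell_size)
        i_zero = _cell_index(np.array([0.0]), edges)[0]
        assert edges[i_zero] == 0.0  # x = 0 belongs to [0, 20)
        i_edge = _cell_index(np.array([20.0]), edges)[0]
        assert edges[i_edge] == 20.0  # x = 20 belongs to [20, 40)
        i_below = _cell_index(np.array([19.999]), edges)[0]
        assert edges[i_below] == 0.0


class TestDensityMap:
    def test_all_observations_in_one_cell(self, config):
        traj = scripted_trajectory(n_frames=30, speed=0.2, start_centroid=(10.0, 10.0), spread=0.5)
        grid = density_map(traj, config)
        assert grid.values.max() == pytest.approx(1.0)
        assert grid.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_even_split_across_four_cells(self, config):
        pos = np.array(
            [[[5.0, 5.0], [-5.0, 5.0], [5.0, -5.0], [-5.0, -5.0]]], dtype=float
        ).repeat(20, axis=0)
        traj = scripted_trajectory(n_fish=4)
        traj = traj.__class__(
            trial_id="quad", treatment="open_field", line="control",
            replicate="1", positions=pos, arena=traj.arena,
        )
        grid = density_map(traj, config)
        assert sorted(grid.values[grid.values > 0]) == pytest.approx([0.25] * 4)

    def test_random_trial_sums_to_one(self, config):
        from shoalkit import SchoolSimConfig, simulate_school

        traj = simulate_school(SchoolSimConfig(duration_s=5.0, seed=9, track_loss_rate=0.1))
        grid = density_map(traj, config)
        assert grid.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert (grid.values >= 0).all()


class TestZonePolarization:
    def _fixed_centroid_trial(self, centroid):
        return scripted_trajectory(
            n_frames=60, speed=0.2, heading_angles_deg=[60, -60] * 4,
            start_centroid=centroid, spread=5.0, stimulus=True,
            treatment="predator_model",
        )

    def test_head_side_counts_in_near_and_head_not_tail(self, config):
        traj = self._fixed_centroid_trial((0.0, 150.0))
        assert zone_polarization(traj, "near_stimulus", config) == pytest.approx(0.5, abs=1e-9)
        assert zone_polarization(traj, "head", config) == pytest.approx(0.5, abs=1e-9)
        assert np.isnan(zone_polarization(traj, "tail", config))

    def test_tail_side_with_constant_polarization(self, config):
        traj = self._fixed_centroid_trial((0.0, -150.0))
        assert zone_polarization(traj, "tail", config) == pytest.approx(0.5, abs=1e-9)
        assert np.isnan(zone_polarization(traj, "head", config))

    def test_far_tail_position_outside_near_zone(self, config):
        traj = self._fixed_centroid_trial((0.0, -240.0))
        assert np.isnan(zone_polarization(traj, "near_stimulus", config))
        assert zone_polarization(traj, "tail", config) == pytest.approx(0.5, abs=1e-9)

    def test_requires_stimulus(self, config):
        traj = scripted_trajectory()
        with pytest.raises(ValidationError, match="stimulus"):
            zone_polarization(traj, "head", config)

    def test_generated_head_tail_ordering_recovered(self, config):
        """Lower alignment when the centroid sits at the model head than at
        the tail must come back as head-median < tail-median."""
        head = self._fixed_centroid_trial((0.0, 150.0))   # pol 0.5
        tail = scripted_trajectory(
            n_frames=60, speed=0.2, heading_angles_deg=[25.8, -25.8] * 4,
            start_centroid=(0.0, -150.0), spread=5.0, stimulus=True,
            treatment="predator_model",
        )  # pol = cos(25.8 deg) = 0.9
        pos = np.concatenate([head.positions, tail.positions])
        traj = head.__class__(
            trial_id="zones", treatment="predator_model", line="control",
            replicate="1", positions=pos, arena=head.arena,
        )
        h = zone_polarization(traj, "head", config)
        t = zone_polarization(traj, "tail", config)
        assert h < t
        assert h == pytest.approx(0.5, abs=0.05) and t == pytest.approx(0.9, abs=0.05)


class TestPolarizationSpeedMap:
    def test_single_state_occupies_one_bin(self, config):
        traj = scripted_trajectory(n_frames=80, speed=0.5)
        m = polarization_speed_map([traj], config)
        assert m.density.sum() == pytest.approx(1.0)
        assert m.density.max() == pytest.approx(1.0)

    def test_slow_school_has_low_speed_fraction_near_one(self, config):
        traj = scripted_trajectory(n_frames=80, speed=0.3)
        m = polarization_speed_map([traj], config)
        assert m.low_speed_fraction == pytest.approx(1.0)
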