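"""Shared fixtures and scripted-trajectory builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from shoalkit import AnalysisConfig, ArenaGeometry, TrajectoryDataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def scripted_trajectory(
    n_frames: int = 200,
    n_fish: int = 8,
    speed: float = 0.5,
    heading_angles_deg=None,
    start_centroid=(-100.0, 0.0),
    spread: float = 6.0,
    treatment: str = "open_field",
    stimulus: bool = False,
    trial_id: str = "scripted",
) -> TrajectoryDataset:
    """Deterministic straight-line trajectory with known per-fish headings.

    Fish ``i`` starts ``spread`` mm apart along y around ``start_centroid``
    and moves at constant ``speed`` mm/frame along its heading (default:
    all due +x), so smoothed velocities, polarization and NND have closed
    forms.
    """
    if heading_angles_deg is None:
        heading_angles_deg = np.zeros(n_fish)
    ang = np.radians(np.asarray(heading_angles_deg, dtype=float))
    dirs = np.column_stack([np.cos(ang), np.sin(ang)])
    offsets = np.column_stack(
        [np.zeros(n_fish), (np.arange(n_fish) - (n_fish - 1) / 2) * spread]
    )
    start = np.asarray(start_centroid) + offsets
    t = np.arange(n_frames)[:, None, None]
    positions = start[None] + t * speed * dirs[None]
    return TrajectoryDataset(
        trial_id=trial_id,
        treatment=treatment,
        line="control",
        replicate="1",
        positions=positions,
        arena=ArenaGeometry(stimulus_present=stimulus),
    )


def boundary_completeness_trajectory(fraction: float, config: AnalysisConfig):
    """A 1000-frame, 8-fish trial whose completeness is exactly ``fraction``.

    Five fish are tracked throughout, a sixth only for the first
    ``1000 * fraction + 2 * half_window`` frames and two never, so exactly
    ``fraction`` of frames have >= 6 fish with a defined smoothed velocity.
    """
    n_frames = 1000
    half = config.smoothing_window // 2
    k = int(round(n_frames * fraction)) + 2 * half
    traj = scripted_trajectory(n_frames=n_frames, speed=0.2, start_centroid=(-150.0, 0.0))
    positions = traj.positions.copy()
    positions[k:, 5] = np.nan
    positions[:, 6:] = np.nan
    return TrajectoryDataset(
        trial_id=f"boundary-{fraction}",
        treatment="open_field",
        line="control",
        replicate="1",
        positions=positions,
        arena=traj.arena,
    )
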