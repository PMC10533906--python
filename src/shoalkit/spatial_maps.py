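"""Spatial structure of collective motion over the circular arena.

Grid maps use 20 x 20 mm half-open cells ([x0, x0+20) x [y0, y0+20))
anchored at the arena center.  Centroid heatmaps are restricted to frames
in which at least six fish form a connected group at a 100 mm connection
distance, average within each group first and then across groups per cell,
and suppress cells supported by fewer than eight distinct groups.  Density
maps are per-trial occupancy distributions over individual fish positions.
Stimulus-zone statistics follow the convention that the predator-model
head lies at positive y and the tail at negative y; a centroid exactly on
y = 0 is assigned to the tail (a deterministic tie-break on a measure-zero
set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import AnalysisConfig, ArenaGeometry, TrajectoryDataset, ValidationError
from .kinematics_metrics import compute_frame_metrics, smooth_velocities

__all__ = [
    "GridMap",
    "PolarizationSpeedMap",
    "connected_group_frames",
    "polarization_heatmap",
    "density_map",
    "zone_polarization",
    "polarization_speed_map",
]


@dataclass
class GridMap:
    """Regular 2-D binning of a scalar over the arena.

    ``values[i, j]`` covers the half-open cell
    ``[x_edges[i], x_edges[i+1]) x [y_edges[j], y_edges[j+1])``;
    ``support`` counts contributing groups (mean maps) or observations
    (density maps); ``mask`` is True for suppressed cells.
    """

    cell_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    support: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros_like(self.values, dtype=bool)

    @property
    def n_cells(self) -> tuple[int, int]:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        out = self.values.astype(float).copy()
        out[self.mask] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        xi, yi = np.meshgrid(
            np.arange(self.values.shape[0]), np.arange(self.values.shape[1]), indexing="ij"
        )
        return pd.DataFrame(
            {
                "cell_x": self.x_edges[xi.ravel()],
                "cell_y": self.y_edges[yi.ravel()],
                "value": self.values.ravel(),
                "support": self.support.ravel(),
                "masked": self.mask.ravel(),
            }
        )


def _grid_edges(arena: ArenaGeometry, cell: float) -> np.ndarray:
    n = int(np.ceil(arena.radius * (1.0 + 0.02) / cell))
    return np.arange(-n, n + 1) * cell


def _cell_index(coords: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open binning (left/bottom edge inclusive) onto ``edges``."""
    idx = np.floor((coords - edges[0]) / (edges[1] - edges[0])).astype(int)
    return np.clip(idx, 0, len(edges) - 2)


def connected_group_frames(
    traj_or_positions: TrajectoryDataset | np.ndarray,
    link_dist: float | None = None,
    min_size: int | None = None,
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """Per-frame flag: does a connected group of >= ``min_size`` fish exist?

    Two fish are connected when their distance is at most ``link_dist``
    (100 mm by default); the flag is True when the resulting graph on the
    tracked fish of that frame has a connected component of at least
    ``min_size`` (6) members.  Reachability is computed for all frames at
    once by repeated boolean squaring of the adjacency matrix.

    Accepts a dataset (uses positions of velocity-tracked fish) or a raw
    ``(n_frames, n_fish, 2)`` position array with NaN for missing.
    """
    config = config or AnalysisConfig()
    link_dist = link_dist if link_dist is not None else config.connectivity_distance
    min_size = min_size if min_size is not None else config.min_tracked

    if isinstance(traj_or_positions, TrajectoryDataset):
        vel = smooth_velocities(traj_or_positions, config=config)
        tracked = ~np.isnan(vel[..., 0])
        pos = np.where(tracked[..., None], traj_or_positions.positions, np.nan)
    else:
        pos = np.asarray(traj_or_positions, dtype=float)
        if pos.ndim == 2:
            pos = pos[None]
    valid = ~np.isnan(pos[..., 0])  # (F, n)

    diff = pos[:, :, None, :] - pos[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)  # (F, n, n), NaN with missing
    with np.errstate(invalid="ignore"):
        adj = dist <= link_dist
    adj &= valid[:, :, None] & valid[:, None, :]
    n = pos.shape[1]
    reach = adj | (np.eye(n, dtype=bool) & valid[:, :, None] & valid[:, None, :])
    for _ in range(max(1, int(np.ceil(np.log2(max(n, 2)))))):
        reach = np.matmul(reach.astype(np.uint8), reach.astype(np.uint8)) > 0
    comp_size = reach.sum(axis=2)  # component size per fish (0 for untracked)
    return (comp_size >= min_size).any(axis=1)


def polarization_heatmap(
    trials: list[TrajectoryDataset], config: AnalysisConfig | None = None
) -> GridMap:
    """Mean group polarization by centroid grid cell across trials.

    Frames must pass both the six-of-eight tracking rule and the
    connected-group filter.  Each trial (group) contributes its own mean
    per cell; the cell value is the mean of those group means, and cells
    with fewer than eight supporting groups are masked.
    """
    config = config or AnalysisConfig()
    if not trials:
        empty = np.zeros((0, 0))
        return GridMap(config.grid_cell_size, np.zeros(1), np.zeros(1), empty, empty)
    treatments = {t.treatment for t in trials}
    if len(treatments) > 1:
        raise ValidationError(f"trials mix treatments {sorted(treatments)}")
    arena = trials[0].arena
    edges = _grid_edges(arena, config.grid_cell_size)
    shape = (len(edges) - 1, len(edges) - 1)
    total = np.zeros(shape)
    support = np.zeros(shape, dtype=int)
    for traj in trials:
        metrics = compute_frame_metrics(traj, config)
        ok = (
            metrics["passing"].to_numpy()
            & connected_group_frames(traj, config=config)
            & ~np.isnan(metrics["polarization"].to_numpy())
        )
        if not ok.any():
            continue
        xi = _cell_index(metrics.loc[ok, "centroid_x"].to_numpy(), edges)
        yi = _cell_index(metrics.loc[ok, "centroid_y"].to_numpy(), edges)
        pol = metrics.loc[ok, "polarization"].to_numpy()
        sums = np.zeros(shape)
        counts = np.zeros(shape, dtype=int)
        np.add.at(sums, (xi, yi), pol)
        np.add.at(counts, (xi, yi), 1)
        seen = counts > 0
        total[seen] += sums[seen] / counts[seen]
        support += seen
    with np.errstate(invalid="ignore"):
        values = np.where(support > 0, total / np.maximum(support, 1), np.nan)
    mask = support < config.min_groups_per_cell
    return GridMap(config.grid_cell_size, edges, edges, values, support, mask)


def density_map(traj: TrajectoryDataset, config: AnalysisConfig | None = None) -> GridMap:
    """Occupancy distribution of individual fish positions for one trial.

    The value of each cell is the fraction of all (non-missing) position
    observations falling in it, so values are nonnegative and sum to 1.
    """
    config = config or AnalysisConfig()
    edges = _grid_edges(traj.arena, config.grid_cell_size)
    pos = traj.positions.reshape(-1, 2)
    pos = pos[~np.isnan(pos[:, 0])]
    if len(pos) == 0:
        raise ValidationError("no position observations to bin")
    xi = _cell_index(pos[:, 0], edges)
    yi = _cell_index(pos[:, 1], edges)
    counts = np.zeros((len(edges) - 1, len(edges) - 1), dtype=int)
    np.add.at(counts, (xi, yi), 1)
    return GridMap(config.grid_cell_size, edges, edges, counts / len(pos), counts)


def zone_polarization(
    traj: TrajectoryDataset,
    zone: str,
    config: AnalysisConfig | None = None,
) -> float:
    """Median per-frame polarization while the group centroid is in a zone.

    Zones: ``near_stimulus`` (centroid closer than 200 mm to the arena
    center, where the stimulus is fixed), ``head`` (centroid y > 0) and
    ``tail`` (centroid y <= 0).  Frames must pass the six-of-eight rule;
    returns NaN when no frame qualifies.
    """
    config = config or AnalysisConfig()
    if not traj.arena.stimulus_present:
        raise ValidationError("zone statistics need a stimulus in the arena")
    metrics = compute_frame_metrics(traj, config)
    cx = metrics["centroid_x"].to_numpy()
    cy = metrics["centroid_y"].to_numpy()
    if zone == "near_stimulus":
        in_zone = np.hypot(cx, cy) < config.zone_radius
    elif zone == "head":
        in_zone = cy > 0
    elif zone == "tail":
        in_zone = cy <= 0
    else:
        raise ValidationError(f"unknown zone {zone!r}")
    ok = metrics["passing"].to_numpy() & in_zone & ~np.isnan(metrics["polarization"])
    if not ok.any():
        return float("nan")
    return float(np.median(metrics.loc[ok, "polarization"]))


@dataclass
class PolarizationSpeedMap:
    """Joint distribution of per-frame group speed and polarization."""

    density: np.ndarray  # (n_speed_bins, n_pol_bins), sums to 1
    speed_edges: np.ndarray
    polarization_edges: np.ndarray
    low_speed_fraction: float  # fraction of frames with group speed < 2 mm/frame
    n_frames: int


def polarization_speed_map(
    trials: list[TrajectoryDataset],
    config: AnalysisConfig | None = None,
    speed_edges: np.ndarray | None = None,
    polarization_edges: np.ndarray | None = None,
    low_speed_threshold: float = 2.0,
) -> PolarizationSpeedMap:
    """Normalised 2-D histogram of (group speed, polarization) over frames.

    Pools frames passing the six-of-eight rule across trials and also
    reports the fraction of frames with group speed below 2 mm/frame, the
    diagnostic separating freezing-dominated from free-swimming conditions.
    """
    config = config or AnalysisConfig()
    if speed_edges is None:
        speed_edges = np.linspace(0.0, 10.0, 26)
    if polarization_edges is None:
        polarization_edges = np.linspace(0.0, 1.0, 21)
    speeds, pols = [], []
    for traj in trials:
        m = compute_frame_metrics(traj, config)
        ok = m["passing"].to_numpy() & ~np.isnan(m["polarization"].to_numpy())
        speeds.append(m.loc[ok, "group_speed"].to_numpy())
        pols.append(m.loc[ok, "polarization"].to_numpy())
    speed = np.concatenate(speeds) if speeds else np.empty(0)
    pol = np.concatenate(pols) if pols else np.empty(0)
    hist, se, pe = np.histogram2d(
        np.clip(speed, speed_edges[0], np.nextafter(speed_edges[-1], -np.inf)),
        pol,
        bins=[speed_edges, polarization_edges],
    )
    total = hist.sum()
    density = hist / total if total > 0 else hist
    frac = float((speed < low_speed_threshold).mean()) if len(speed) else float("nan")
    return PolarizationSpeedMap(density, se, pe, frac, int(len(speed)))
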