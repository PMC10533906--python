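"""Per-frame and per-trial collective-motion statistics.

Velocities are first differences of the x and y position series smoothed
with a third-order Savitzky-Golay filter; a fish counts as *tracked* in a
frame when its smoothed velocity is defined there.  Headings are the
directions of smoothed velocities, undefined below a small speed threshold
(direction is meaningless for a resting fish, and freezing bouts are a core
behavioural response here).  Group polarization is the standard directional
order parameter — the norm of the mean unit heading vector — computed only
in frames where at least six of the eight group members contribute a
heading.  Per-trial medians are taken over qualifying frames, and a trial
is retained only when at least 70% of its frames pass the six-of-eight
tracking rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.spatial.distance import cdist

from .io_model import AnalysisConfig, TrajectoryDataset, ValidationError

__all__ = [
    "TrialSummary",
    "smooth_velocities",
    "headings_from_velocities",
    "frame_polarization",
    "nearest_neighbour_distances",
    "compute_frame_metrics",
    "summarize_trial",
]


@dataclass
class TrialSummary:
    """Per-trial collective-motion medians with quality-control flags."""

    trial_id: str
    treatment: str
    line: str
    replicate: str
    presentation_order: int
    median_polarization: float
    median_speed: float  # mm/frame
    median_nnd: float  # mm
    completeness: float
    retained: bool
    window_s: float


def _contiguous_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a 1-D boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def smooth_velocities(
    traj: TrajectoryDataset,
    window: int | None = None,
    order: int = 3,
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """Savitzky-Golay-smoothed per-frame, per-fish velocity in mm/frame.

    The derivative filter is applied independently to the x and y series of
    each contiguous non-missing run of each fish.  Velocity is reported only
    where the window is fully supported (run interiors); it is never
    interpolated across gaps, so runs shorter than the window yield no
    velocity at all.  Returns an ``(n_frames, n_fish, 2)`` array with NaN
    where undefined.
    """
    config = config or AnalysisConfig()
    window = int(window or config.smoothing_window)
    if window % 2 == 0 or window <= order:
        raise ValidationError("smoothing window must be odd and exceed the order")
    half = window // 2
    pos = traj.positions
    vel = np.full_like(pos, np.nan)
    for j in range(traj.n_fish):
        valid = ~np.isnan(pos[:, j, 0])
        for start, stop in _contiguous_runs(valid):
            if stop - start < window:
                continue
            seg = savgol_filter(
                pos[start:stop, j, :], window, order, deriv=1, delta=1.0, axis=0
            )
            vel[start + half : stop - half, j, :] = seg[half : stop - start - half]
    return vel


def headings_from_velocities(
    velocities: np.ndarray, speed_threshold: float = 0.1
) -> np.ndarray:
    """Unit heading vectors; NaN where velocity is missing or speed < threshold."""
    speed = np.linalg.norm(velocities, axis=-1)
    with np.errstate(invalid="ignore"):
        ok = speed >= speed_threshold
    unit = np.full_like(velocities, np.nan)
    unit[ok] = velocities[ok] / speed[ok, None]
    return unit


def frame_polarization(headings: np.ndarray, min_headings: int = 6) -> float:
    """Directional order parameter of one frame: ‖mean unit heading vector‖.

    ``headings`` is an ``(n, 2)`` array of unit vectors, NaN rows ignored.
    Returns NaN when fewer than ``min_headings`` fish contribute (the
    six-of-eight rule), else a value in [0, 1]: 1 for perfect alignment,
    0 for complete cancellation.
    """
    headings = np.asarray(headings, dtype=float)
    valid = ~np.isnan(headings[:, 0])
    if valid.sum() < min_headings:
        return float("nan")
    mean_vec = headings[valid].mean(axis=0)
    return float(min(np.linalg.norm(mean_vec), 1.0))


def nearest_neighbour_distances(positions: np.ndarray) -> np.ndarray:
    """Per-fish distance (mm) to the closest other tracked fish in one frame.

    ``positions`` is ``(n, 2)`` with NaN rows for untracked fish; those and
    frames with fewer than two tracked fish yield NaN.
    """
    positions = np.asarray(positions, dtype=float)
    valid = ~np.isnan(positions[:, 0])
    out = np.full(positions.shape[0], np.nan)
    if valid.sum() < 2:
        return out
    pts = positions[valid]
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    out[valid] = d.min(axis=1)
    return out


def compute_frame_metrics(
    traj: TrajectoryDataset, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-frame metrics table.

    Columns: ``frame, n_tracked`` (fish with a defined smoothed velocity),
    ``n_headings``, ``polarization`` (NaN unless >= ``min_tracked`` headings),
    ``group_speed`` (mean speed over tracked fish, mm/frame),
    ``centroid_x/centroid_y`` (mean position of tracked fish) and
    ``passing`` (the six-of-eight rule on tracked fish).
    """
    config = config or AnalysisConfig()
    vel = smooth_velocities(traj, config=config)
    speed = np.linalg.norm(vel, axis=-1)  # (frames, fish)
    tracked = ~np.isnan(speed)
    headings = headings_from_velocities(vel, config.heading_speed_threshold)
    has_heading = ~np.isnan(headings[..., 0])

    n_tracked = tracked.sum(axis=1)
    n_headings = has_heading.sum(axis=1)
    mean_vec = np.full((traj.n_frames, 2), np.nan)
    some = n_headings > 0
    if some.any():
        mean_vec[some] = np.nanmean(
            np.where(has_heading[..., None], headings, np.nan)[some], axis=1
        )
    polarization = np.minimum(np.linalg.norm(mean_vec, axis=1), 1.0)
    polarization[n_headings < config.min_tracked] = np.nan

    group_speed = np.full(traj.n_frames, np.nan)
    any_tracked = n_tracked > 0
    group_speed[any_tracked] = np.nanmean(
        np.where(tracked, speed, np.nan)[any_tracked], axis=1
    )

    centroid = np.full((traj.n_frames, 2), np.nan)
    pos_tracked = np.where(tracked[..., None], traj.positions, np.nan)
    centroid[any_tracked] = np.nanmean(pos_tracked[any_tracked], axis=1)

    return pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "n_tracked": n_tracked,
            "n_headings": n_headings,
            "polarization": polarization,
            "group_speed": group_speed,
            "centroid_x": centroid[:, 0],
            "centroid_y": centroid[:, 1],
            "passing": n_tracked >= config.min_tracked,
        }
    )


def summarize_trial(
    traj: TrajectoryDataset,
    config: AnalysisConfig | None = None,
    window_s: float | None = None,
) -> TrialSummary:
    """Per-trial medians of polarization, speed and nearest-neighbour distance.

    ``window_s`` restricts the analysis to the first so-many seconds; when
    omitted, open-field trials use the configured 6 min comparison window
    and stimulus trials their full duration.  All medians are computed over
    frames passing the six-of-eight tracking rule; speed and NND are
    per-fish medians first, then the median across fish.  The trial is
    retained only when the fraction of passing frames reaches the 70%
    completeness threshold (boundary inclusive); otherwise all medians are
    reported missing.
    """
    config = config or AnalysisConfig()
    if window_s is None:
        window_s = config.oft_window_s if traj.treatment == "open_field" else traj.duration_s
    n = min(traj.n_frames, int(round(window_s * traj.fps)))

    metrics = compute_frame_metrics(traj, config).iloc[:n]
    nan = float("nan")
    if n == 0:
        return TrialSummary(
            traj.trial_id, traj.treatment, traj.line, traj.replicate,
            traj.presentation_order, nan, nan, nan, 0.0, False, float(window_s),
        )

    passing = metrics["passing"].to_numpy()
    completeness = float(passing.mean())
    retained = completeness >= config.completeness_threshold

    median_pol = median_speed = median_nnd = nan
    if retained:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            median_pol = float(np.nanmedian(metrics["polarization"].to_numpy()))
            vel = smooth_velocities(traj, config=config)[:n][passing]
            speed = np.linalg.norm(vel, axis=-1)
            per_fish_speed = np.nanmedian(speed, axis=0)
            median_speed = float(np.nanmedian(per_fish_speed))
            pos = traj.positions[:n][passing]
            tracked = ~np.isnan(speed)
            pos = np.where(tracked[..., None], pos, np.nan)
            nnd = np.stack([nearest_neighbour_distances(frame) for frame in pos])
            per_fish_nnd = np.nanmedian(nnd, axis=0)
            median_nnd = float(np.nanmedian(per_fish_nnd))

    return TrialSummary(
        trial_id=traj.trial_id,
        treatment=traj.treatment,
        line=traj.line,
        replicate=traj.replicate,
        presentation_order=traj.presentation_order,
        median_polarization=median_pol,
        median_speed=median_speed,
        median_nnd=median_nnd,
        completeness=completeness,
        retained=retained,
        window_s=float(window_s),
    )
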