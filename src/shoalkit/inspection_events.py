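"""Predator-inspection event aggregation.

Inspections are scored manually (one randomly chosen focal fish per trial)
as start/end times within the first 3 min after the predator model enters
the arena.  This module turns those event tables into the three response
variables — number of inspections, total time inspecting and mean
inspection duration — and links events back to trajectory-derived frame
metrics.  Events are half-open ``[start, end)`` so contiguous events never
double-count time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AnalysisConfig, InspectionEventTable, TrajectoryDataset
from .kinematics_metrics import compute_frame_metrics

__all__ = ["InspectionSummary", "summarize_inspections", "inspection_covariates"]


@dataclass
class InspectionSummary:
    """Counts and durations of predator inspections within the scoring window."""

    trial_id: str
    n_inspections: int
    total_time_s: float
    mean_duration_s: float  # NaN when no inspections occurred
    window_s: float


def summarize_inspections(events: InspectionEventTable) -> InspectionSummary:
    """Aggregate one trial's events into count, total time and mean duration.

    Events extending past the scoring window are truncated at the window
    boundary (with a warning); events entirely outside it are dropped.
    """
    window = events.scoring_window_s
    durations = []
    for start, end in events.events:
        if start >= window:
            warnings.warn(
                f"event ({start}, {end}) starts outside the {window} s window; dropped",
                stacklevel=2,
            )
            continue
        if end > window:
            warnings.warn(
                f"event ({start}, {end}) truncated at the {window} s window",
                stacklevel=2,
            )
            end = window
        durations.append(end - start)
    n = len(durations)
    total = float(sum(durations))
    mean = total / n if n else float("nan")
    return InspectionSummary(events.trial_id, n, total, mean, window)


def inspection_covariates(
    traj: TrajectoryDataset,
    events: InspectionEventTable,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-event medians of group state during the event.

    For each event, the median centroid distance to the stimulus (arena
    center) and median group polarization over frames in ``[start, end)``
    that pass the six-of-eight rule.  Events outside the trajectory's time
    span yield missing records with a warning.  Trajectory and events must
    share the moment of stimulus introduction as time zero.
    """
    config = config or AnalysisConfig()
    metrics = compute_frame_metrics(traj, config)
    dist = np.hypot(metrics["centroid_x"].to_numpy(), metrics["centroid_y"].to_numpy())
    pol = metrics["polarization"].to_numpy()
    passing = metrics["passing"].to_numpy()
    records = []
    for start, end in events.events:
        i0 = int(np.ceil(start * traj.fps))
        i1 = int(np.ceil(end * traj.fps))
        if i0 >= traj.n_frames:
            warnings.warn(
                f"event ({start}, {end}) lies outside the trajectory time span",
                stacklevel=2,
            )
            records.append(
                {"start_s": start, "end_s": end,
                 "median_distance": np.nan, "median_polarization": np.nan}
            )
            continue
        sel = np.zeros(traj.n_frames, dtype=bool)
        sel[i0 : min(i1, traj.n_frames)] = True
        sel &= passing
        d = dist[sel]
        p = pol[sel]
        records.append(
            {
                "start_s": start,
                "end_s": end,
                "median_distance": float(np.nanmedian(d)) if len(d) and not np.all(np.isnan(d)) else np.nan,
                "median_polarization": float(np.nanmedian(p)) if len(p) and not np.all(np.isnan(p)) else np.nan,
            }
        )
    out = pd.DataFrame(
        records, columns=["start_s", "end_s", "median_distance", "median_polarization"]
    )
    out.insert(0, "trial_id", events.trial_id)
    return out
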