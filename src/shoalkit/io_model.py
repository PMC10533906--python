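"""Domain types, readers/writers, configuration and validation.

Coordinate convention used throughout the package: the origin is the arena
center, units are millimetres, and when a stimulus (novel object or predator
model) is present its long axis lies on the y axis with the predator-model
head toward positive y and the tail toward negative y.  Missing detections
are explicit missing values (NaN), never sentinel coordinates, because the
downstream quality-control rules (six-of-eight tracked fish per frame, 70%
track completeness per trial) are defined over missingness.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TREATMENTS",
    "LINES",
    "BRAIN_REGIONS",
    "ArenaGeometry",
    "AnalysisConfig",
    "TrajectoryDataset",
    "InspectionEventTable",
    "BrainVolumeTable",
    "read_trajectories",
    "write_trajectories",
    "read_inspection_events",
    "write_inspection_events",
    "read_brain_volumes",
    "write_summary_table",
    "read_summary_table",
]

TREATMENTS = ("open_field", "novel_object", "predator_model")
LINES = ("polarization", "control")

#: The 11-region parcellation of the guppy brain used for volumetry.
BRAIN_REGIONS = (
    "olfactory_bulbs",
    "ventral_telencephalon",
    "dorsal_telencephalon",
    "thalamus",
    "hypothalamus",
    "nucleus_glomerulus",
    "torus_semicircularis",
    "optic_tectum_cup",
    "central_optic_tectum",
    "cerebellum",
    "medulla_oblongata",
)


class ValidationError(ValueError):
    """An input table or dataset violates a structural invariant."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular arena geometry in mm, origin at the arena center.

    The default 275 mm radius is the 55 cm test arena.  When
    ``stimulus_present`` the stimulus sits at the center with the
    predator-model head toward positive y and the tail toward negative y.
    """

    radius: float = 275.0
    center: tuple[float, float] = (0.0, 0.0)
    stimulus_present: bool = False

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError("arena radius must be positive")

    def contains(self, xy: np.ndarray, tolerance_frac: float = 0.02) -> np.ndarray:
        """Boolean mask of points within ``radius * (1 + tolerance_frac)``.

        NaN positions are reported as contained (missing is not "outside").
        """
        xy = np.asarray(xy, dtype=float)
        d = np.hypot(xy[..., 0] - self.center[0], xy[..., 1] - self.center[1])
        limit = self.radius * (1.0 + tolerance_frac)
        return ~(d > limit)


@dataclass
class AnalysisConfig:
    """Tunable analysis constants.

    Defaults are the study protocol: 11-frame (0.44 s at 25 Hz) third-order
    Savitzky-Golay smoothing, per-frame statistics only when at least 6 of
    the 8 fish are tracked, trials kept only at >= 70% complete frames,
    100 mm connection distance for the connected-group filter, 20 mm square
    grid cells with an 8-group minimum per cell, a 200 mm near-stimulus
    zone, a 6 min open-field comparison window and a 3 min predator
    inspection scoring window.
    """

    smoothing_window: int = 11
    smoothing_order: int = 3
    heading_speed_threshold: float = 0.1  # mm/frame; below this heading is undefined
    completeness_threshold: float = 0.70
    min_tracked: int = 6
    connectivity_distance: float = 100.0  # mm
    grid_cell_size: float = 20.0  # mm
    min_groups_per_cell: int = 8
    zone_radius: float = 200.0  # mm
    oft_window_s: float = 360.0
    inspection_window_s: float = 180.0
    arena_tolerance_frac: float = 0.02
    min_orbit_radius: float = 10.0  # mm; polar angle unstable nearer the center
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.smoothing_window % 2 == 0 or self.smoothing_window <= self.smoothing_order:
            raise ValidationError(
                "smoothing window must be odd and exceed the polynomial order"
            )
        positive = (
            "heading_speed_threshold",
            "min_tracked",
            "connectivity_distance",
            "grid_cell_size",
            "min_groups_per_cell",
            "zone_radius",
            "oft_window_s",
            "inspection_window_s",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 < self.completeness_threshold <= 1.0):
            raise ValidationError("completeness threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class TrajectoryDataset:
    """One trial's multi-fish positional time series.

    ``positions`` has shape ``(n_frames, n_fish, 2)`` in mm with NaN rows
    for missing detections.  Frames are an implicit gap-free 0..n_frames-1
    index at constant ``fps``.
    """

    trial_id: str
    treatment: str
    line: str
    replicate: str
    positions: np.ndarray
    fps: float = 25.0
    presentation_order: int = 1
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    body_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValidationError("positions must have shape (n_frames, n_fish, 2)")
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def validate(self, tolerance_frac: float = 0.02) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if self.line not in LINES:
            raise ValidationError(f"unknown line {self.line!r}")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        # half-missing coordinates (x without y) are malformed, not missing
        nan = np.isnan(self.positions)
        if np.any(nan[..., 0] != nan[..., 1]):
            raise ValidationError("positions must be missing in both coordinates or neither")
        inside = self.arena.contains(self.positions, tolerance_frac)
        if not np.all(inside | nan[..., 0]):
            raise ValidationError("positions outside the arena beyond tolerance")

    def missing_fraction(self) -> float:
        return float(np.isnan(self.positions[..., 0]).mean())


@dataclass
class InspectionEventTable:
    """Manually scored predator-inspection events for one trial.

    Events are ``(start_s, end_s)`` in seconds relative to predator-model
    introduction, half-open ``[start, end)``; the scoring window is the
    first 3 min after introduction.
    """

    trial_id: str
    events: list[tuple[float, float]]
    scoring_window_s: float = 180.0

    def __post_init__(self) -> None:
        self.events = [(float(a), float(b)) for a, b in self.events]
        self.validate()

    def validate(self) -> None:
        for start, end in self.events:
            if start < 0:
                raise ValidationError(f"event start {start} < 0")
            if end <= start:
                raise ValidationError(f"event ({start}, {end}) has non-positive duration")
        ordered = sorted(self.events)
        for (s0, e0), (s1, _e1) in zip(ordered, ordered[1:]):
            if s1 < e0:
                raise ValidationError(f"events ({s0}, {e0}) and starting {s1} overlap")


@dataclass
class BrainVolumeTable:
    """Per-fish whole-brain and 11-region volumes with body size and line labels.

    Wraps a DataFrame with columns ``fish_id, line, replicate,
    standard_length, whole_brain`` plus one column per region in
    :data:`BRAIN_REGIONS`.  Region volumes are a parcellation subset of the
    whole brain, so their sum may not exceed ``whole_brain``.
    """

    data: pd.DataFrame

    REQUIRED = ("fish_id", "line", "replicate", "standard_length", "whole_brain")

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data).reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in (*self.REQUIRED, *BRAIN_REGIONS) if c not in self.data.columns]
        if missing:
            raise ValidationError(f"brain volume table lacks columns: {missing}")
        vols = self.data[list(("whole_brain",) + BRAIN_REGIONS + ("standard_length",))]
        if not (vols.to_numpy(dtype=float) > 0).all():
            raise ValidationError("all volumes and body sizes must be positive")
        region_sum = self.data[list(BRAIN_REGIONS)].sum(axis=1)
        if (region_sum > self.data["whole_brain"] * (1 + 1e-9)).any():
            raise ValidationError("region volumes exceed whole-brain volume")
        bad_lines = set(self.data["line"]) - set(LINES)
        if bad_lines:
            raise ValidationError(f"unknown lines {bad_lines}")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Trajectory IO (idTracker-style long CSV + YAML sidecar metadata)
# ---------------------------------------------------------------------------

def _metadata_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".yaml")


def read_trajectories(
    path: str | Path,
    config: AnalysisConfig | None = None,
    metadata_path: str | Path | None = None,
) -> TrajectoryDataset:
    """Read a long-format trajectory CSV (columns frame, fish, x, y).

    Tracking software emits bare coordinate tables, so trial metadata
    (treatment, line, replicate, fps, arena geometry, pixel calibration)
    travels in a YAML sidecar, by default ``<stem>.yaml`` next to the CSV.
    Coordinates are converted to mm relative to the arena center using the
    sidecar's ``pixels_per_mm`` and ``center`` entries.  Missing (frame,
    fish) rows become missing positions; positions outside the arena beyond
    a 2%-of-radius tolerance are warned about and marked missing.
    """
    config = config or AnalysisConfig()
    path = Path(path)
    meta_path = Path(metadata_path) if metadata_path else _metadata_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)

    table = pd.read_csv(path)
    required = {"frame", "fish", "x", "y"}
    if not required.issubset(table.columns):
        raise ValidationError(f"trajectory table must have columns {sorted(required)}")
    if table.duplicated(["frame", "fish"]).any():
        raise ValidationError("duplicate (frame, fish) rows")
    if not table["frame"].is_monotonic_increasing:
        raise ValidationError("frames out of order")

    n_fish = int(meta.get("n_fish", 8))
    fps = float(meta.get("fps", 25.0))
    ppm = float(meta.get("pixels_per_mm", 1.0))
    center = tuple(meta.get("center", (0.0, 0.0)))
    arena = ArenaGeometry(
        radius=float(meta.get("arena_radius_mm", 275.0)),
        stimulus_present=bool(meta.get("stimulus_present", False)),
    )

    frames = np.arange(int(table["frame"].min()), int(table["frame"].max()) + 1)
    frame_index = {f: i for i, f in enumerate(frames)}
    positions = np.full((len(frames), n_fish, 2), np.nan)
    fish_ids = sorted(table["fish"].unique())
    if len(fish_ids) > n_fish:
        raise ValidationError(f"more fish ids than n_fish={n_fish}")
    fish_index = {fid: j for j, fid in enumerate(fish_ids)}
    rows = table[["frame", "fish", "x", "y"]].to_numpy()
    for f, fid, x, y in rows:
        i = frame_index[int(f)]
        j = fish_index[fid]
        positions[i, j, 0] = (x - center[0]) / ppm
        positions[i, j, 1] = (y - center[1]) / ppm

    inside = arena.contains(positions, config.arena_tolerance_frac)
    outside = ~inside & ~np.isnan(positions[..., 0])
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} detections outside the arena beyond tolerance; "
            "marked missing",
            stacklevel=2,
        )
        positions[outside] = np.nan

    return TrajectoryDataset(
        trial_id=str(meta.get("trial_id", path.stem)),
        treatment=meta["treatment"],
        line=meta["line"],
        replicate=str(meta.get("replicate", "1")),
        presentation_order=int(meta.get("presentation_order", 1)),
        fps=fps,
        positions=positions,
        arena=arena,
    )


def write_trajectories(traj: TrajectoryDataset, path: str | Path) -> None:
    """Write a dataset back to CSV + YAML sidecar (mm units, unit calibration).

    Missing detections are written as absent rows, so read ∘ write is the
    identity including missingness.
    """
    path = Path(path)
    frames, fish = np.nonzero(~np.isnan(traj.positions[..., 0]))
    table = pd.DataFrame(
        {
            "frame": frames,
            "fish": fish,
            "x": traj.positions[frames, fish, 0],
            "y": traj.positions[frames, fish, 1],
        }
    )
    table.to_csv(path, index=False)
    meta = {
        "trial_id": traj.trial_id,
        "treatment": traj.treatment,
        "line": traj.line,
        "replicate": traj.replicate,
        "presentation_order": traj.presentation_order,
        "fps": traj.fps,
        "n_fish": traj.n_fish,
        "pixels_per_mm": 1.0,
        "center": [0.0, 0.0],
        "arena_radius_mm": traj.arena.radius,
        "stimulus_present": traj.arena.stimulus_present,
    }
    with open(_metadata_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Event and volume tables
# ---------------------------------------------------------------------------

def read_inspection_events(
    path: str | Path, scoring_window_s: float = 180.0
) -> list[InspectionEventTable]:
    """Read a BORIS-export-like CSV (trial_id, start_s, end_s), one table per trial."""
    table = pd.read_csv(path)
    required = {"trial_id", "start_s", "end_s"}
    if not required.issubset(table.columns):
        raise ValidationError(f"event table must have columns {sorted(required)}")
    out = []
    for trial_id, group in table.groupby("trial_id", sort=True):
        events = list(zip(group["start_s"].astype(float), group["end_s"].astype(float)))
        out.append(InspectionEventTable(str(trial_id), events, scoring_window_s))
    return out


def write_inspection_events(tables: Iterable[InspectionEventTable], path: str | Path) -> None:
    rows = [
        {"trial_id": t.trial_id, "start_s": s, "end_s": e}
        for t in tables
        for s, e in t.events
    ]
    pd.DataFrame(rows, columns=["trial_id", "start_s", "end_s"]).to_csv(path, index=False)


def read_brain_volumes(path: str | Path) -> BrainVolumeTable:
    return BrainVolumeTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Generic summary tables
# ---------------------------------------------------------------------------

def _as_record(row) -> dict:
    if dataclasses.is_dataclass(row) and not isinstance(row, type):
        return dataclasses.asdict(row)
    return dict(row)


def write_summary_table(rows: Sequence, path: str | Path) -> pd.DataFrame:
    """Write one row per trial as CSV with stable (field-declaration) column order.

    Accepts dataclass instances or mappings; an empty collection yields a
    header-only file when the schema is known (a DataFrame input) or an
    empty file otherwise.  Returns the frame that was written.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        records = [_as_record(r) for r in rows]
        frame = pd.DataFrame.from_records(records)
    frame.to_csv(path, index=False)
    return frame


def read_summary_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
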