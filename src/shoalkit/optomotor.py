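"""Optomotor (drum-arena) visual-performance analytics.

A single fish swims in a 50 cm arena while vertical black-and-white bands
rotate around it at one of four angular speeds (14.4, 25, 36, 45 deg/s) in
either direction.  Positions are transformed to polar coordinates about
the arena center; the fish's *relative orientation* is
``arcsin(sin(theta - vartheta))`` where ``theta`` is its heading and
``vartheta`` the angle of the arena radius through its position.  All
angles here use a compass-style convention — measured clockwise from the
positive y axis — so that clockwise circulation gives positive relative
orientation and positive angular speed, matching the reporting convention
for these assays.

Angular speed is the *signed* per-frame rotation of the position vector
(sign from the cross-product orientation, magnitude from the dot product),
in deg/s; the unsigned dot-product angle alone cannot distinguish the two
stimulus directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import AnalysisConfig, ValidationError

__all__ = [
    "STIMULUS_SPEEDS",
    "StimulusSegment",
    "StimulusSchedule",
    "OptomotorTrack",
    "OptomotorSummary",
    "default_schedule",
    "relative_orientation",
    "position_angles",
    "fish_orientation",
    "fish_angular_speed",
    "score_segments",
    "acuity_scores",
]

#: Drum rotation speeds used in the temporal-resolution assay, deg/s.
STIMULUS_SPEEDS = (14.4, 25.0, 36.0, 45.0)

CW, CCW = 1, -1  # direction signs: clockwise positive


@dataclass(frozen=True)
class StimulusSegment:
    speed_deg_s: float
    direction: int  # +1 clockwise, -1 counter-clockwise
    t_start_s: float
    duration_s: float = 23.0

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + self.duration_s

    @property
    def signed_speed(self) -> float:
        return self.direction * self.speed_deg_s


@dataclass
class StimulusSchedule:
    """Piecewise stimulus program for one temporal-resolution test.

    After a 300 s acclimation, the 8 combinations of 4 speeds x 2
    directions are each presented 5 times for 23 s (920 s of scored
    stimulus overall), with 3 s smooth speed transitions between
    presentations that are excluded from scoring.
    """

    segments: list[StimulusSegment]
    acclimation_s: float = 300.0
    transition_s: float = 3.0

    def __post_init__(self) -> None:
        combos = {(s.speed_deg_s, s.direction) for s in self.segments}
        if len(self.segments) != 40 or len(combos) != 8:
            warnings.warn(
                "non-standard schedule: expected 8 speed x direction combinations "
                "x 5 repetitions",
                stacklevel=2,
            )

    @property
    def total_s(self) -> float:
        return max(s.t_end_s for s in self.segments)

    @property
    def scored_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    @classmethod
    def from_yaml(cls, path) -> "StimulusSchedule":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        segments = [
            StimulusSegment(
                float(s["speed_deg_s"]), int(s["direction"]),
                float(s["t_start_s"]), float(s.get("duration_s", 23.0)),
            )
            for s in data["segments"]
        ]
        return cls(
            segments,
            acclimation_s=float(data.get("acclimation_s", 300.0)),
            transition_s=float(data.get("transition_s", 3.0)),
        )

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            "acclimation_s": self.acclimation_s,
            "transition_s": self.transition_s,
            "segments": [
                {
                    "speed_deg_s": s.speed_deg_s,
                    "direction": s.direction,
                    "t_start_s": s.t_start_s,
                    "duration_s": s.duration_s,
                }
                for s in self.segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_schedule(
    acclimation_s: float = 300.0,
    duration_s: float = 23.0,
    transition_s: float = 3.0,
    repetitions: int = 5,
) -> StimulusSchedule:
    """The standard 40-segment program, in a fixed pseudo-random order.

    Presentation order was randomised once a priori and held constant for
    every fish; here a fixed-seed shuffle plays that role, so every caller
    sees the same order.
    """
    combos = [(v, d) for v in STIMULUS_SPEEDS for d in (CW, CCW)]
    order = np.repeat(np.arange(len(combos)), repetitions)
    np.random.default_rng(20211108).shuffle(order)
    segments = []
    t = acclimation_s
    for k in order:
        t += transition_s
        speed, direction = combos[k]
        segments.append(StimulusSegment(speed, direction, t, duration_s))
        t += duration_s
    return StimulusSchedule(segments, acclimation_s, transition_s)


@dataclass
class OptomotorTrack:
    """Single-fish positions (mm, origin at arena center) at constant fps."""

    positions: np.ndarray  # (n_frames, 2)
    fps: float = 25.0
    arena_radius: float = 250.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("track positions must have shape (n_frames, 2)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def _compass_deg(xy: np.ndarray) -> np.ndarray:
    """Angle measured clockwise from +y, in degrees (compass convention)."""
    return np.degrees(np.arctan2(xy[..., 0], xy[..., 1]))


def position_angles(track: OptomotorTrack, min_radius: float = 10.0) -> np.ndarray:
    """Per-frame polar angle of the fish position (compass deg); NaN near center."""
    r = np.linalg.norm(track.positions, axis=1)
    angles = _compass_deg(track.positions)
    with np.errstate(invalid="ignore"):
        angles[~(r > min_radius)] = np.nan
    return angles


def fish_orientation(track: OptomotorTrack, min_step: float = 1e-9) -> np.ndarray:
    """Per-frame heading (compass deg) from inter-frame displacement.

    The orientation at frame i is the direction of the step from frame i-1
    to frame i; frame 0 and frames without displacement are NaN.
    """
    disp = np.diff(track.positions, axis=0)
    theta = np.full(track.n_frames, np.nan)
    step = np.linalg.norm(disp, axis=1)
    ok = step > min_step
    theta[1:][ok] = _compass_deg(disp[ok])
    return theta


def relative_orientation(theta_deg, vartheta_deg):
    """``arcsin(sin(theta - vartheta))`` in degrees, folded into [-90, 90].

    Positive values mean the fish is circling clockwise around the arena,
    negative counter-clockwise; 0 is purely radial motion.  Both inputs are
    compass angles; adding full turns to either leaves the result
    unchanged.
    """
    delta = np.radians(np.asarray(theta_deg, dtype=float) - np.asarray(vartheta_deg, dtype=float))
    return np.degrees(np.arcsin(np.sin(delta)))


def track_relative_orientation(
    track: OptomotorTrack, min_radius: float = 10.0
) -> np.ndarray:
    """Per-frame relative orientation of a track (deg in [-90, 90])."""
    return relative_orientation(fish_orientation(track), position_angles(track, min_radius))


def fish_angular_speed(track: OptomotorTrack, min_radius: float = 10.0) -> np.ndarray:
    """Signed per-frame angular speed of the position vector, deg/s.

    Positive for clockwise rotation.  The magnitude comes from the angle
    between consecutive position vectors (their normalised dot product) and
    the sign from the orientation of their cross product.  Frames whose
    position radius is at or below ``min_radius`` (10 mm) have an
    ill-defined polar angle and yield NaN, as does frame 0.
    """
    p0 = track.positions[:-1]
    p1 = track.positions[1:]
    dot = np.einsum("ij,ij->i", p0, p1)
    cross = p0[:, 0] * p1[:, 1] - p0[:, 1] * p1[:, 0]  # positive = CCW in math axes
    ccw_step = np.arctan2(cross, dot)
    out = np.full(track.n_frames, np.nan)
    out[1:] = -np.degrees(ccw_step) * track.fps  # clockwise positive
    r = np.linalg.norm(track.positions, axis=1)
    bad = ~(r > min_radius)
    out[1:][bad[1:] | bad[:-1]] = np.nan
    return out


@dataclass
class OptomotorSummary:
    """Segment, per-stimulus and pooled direction-following statistics.

    ``per_segment`` has one row per scheduled presentation;
    ``per_stimulus`` aggregates the repetitions of each (speed, direction)
    combination by duration-weighted mean; ``pooled`` is the
    duration-weighted mean over all scored segments.
    """

    per_segment: pd.DataFrame
    per_stimulus: pd.DataFrame
    pooled: dict = field(default_factory=dict)


def score_segments(
    track: OptomotorTrack,
    schedule: StimulusSchedule,
    config: AnalysisConfig | None = None,
    method: str = "orientation",
    following_threshold_deg: float = 0.0,
) -> OptomotorSummary:
    """Score direction-following and speed-matching per stimulus segment.

    For every scored frame of a segment (acclimation and 3 s transitions
    excluded) the fish is *following* when the sign of its relative
    orientation (``method="orientation"``, the default) or of its signed
    angular speed (``method="displacement"``) matches the stimulus
    direction, beyond ``following_threshold_deg``.  Per segment:

    - ``proportion_following``: following frames / scored frames;
    - ``mean_speed``: mean signed angular speed along the stimulus
      direction (deg/s, NaN-frames excluded);
    - ``speed_deviation``: that mean minus the stimulus speed (negative =
      fish slower than the drum).
    """
    config = config or AnalysisConfig()
    min_r = config.min_orbit_radius
    if track.duration_s < schedule.total_s:
        missing = [
            f"{s.speed_deg_s} deg/s {'CW' if s.direction == CW else 'CCW'} @ {s.t_start_s:.0f}s"
            for s in schedule.segments
            if s.t_end_s > track.duration_s
        ]
        raise ValidationError(
            f"track ({track.duration_s:.1f} s) shorter than schedule "
            f"({schedule.total_s:.1f} s); missing segments: {missing}"
        )
    rel = track_relative_orientation(track, min_r)
    omega = fish_angular_speed(track, min_r)

    rows = []
    for seg in schedule.segments:
        # frame i carries the step (i-1, i): score frames whose step lies
        # fully inside the segment so boundary steps never leak transition
        i0 = int(np.ceil(seg.t_start_s * track.fps - 1e-9)) + 1
        i1 = min(int(np.floor(seg.t_end_s * track.fps + 1e-9)) + 1, track.n_frames)
        sl = slice(i0, i1)
        signal = rel[sl] if method == "orientation" else omega[sl]
        if method not in ("orientation", "displacement"):
            raise ValidationError(f"unknown scoring method {method!r}")
        with np.errstate(invalid="ignore"):
            following = (signal * seg.direction) > following_threshold_deg
        n_frames = i1 - i0
        prop = float(following.sum() / n_frames) if n_frames else float("nan")
        w = omega[sl]
        w = w[~np.isnan(w)]
        mean_speed = float(np.mean(w * seg.direction)) if len(w) else 0.0
        rows.append(
            {
                "speed_deg_s": seg.speed_deg_s,
                "direction": "CW" if seg.direction == CW else "CCW",
                "t_start_s": seg.t_start_s,
                "duration_s": seg.duration_s,
                "n_frames": n_frames,
                "proportion_following": prop,
                "mean_speed": mean_speed,
                "speed_deviation": mean_speed - seg.speed_deg_s,
            }
        )
    per_segment = pd.DataFrame(rows)

    def _pool(g: pd.DataFrame) -> pd.Series:
        w = g["duration_s"].to_numpy()
        w = w / w.sum()
        return pd.Series(
            {
                "proportion_following": float(
                    np.clip(np.dot(w, g["proportion_following"]), 0.0, 1.0)
                ),
                "mean_speed": float(np.dot(w, g["mean_speed"])),
                "speed_deviation": float(np.dot(w, g["speed_deviation"])),
                "n_segments": len(g),
            }
        )

    per_stimulus = (
        per_segment.groupby(["speed_deg_s", "direction"], sort=True)
        .apply(_pool, include_groups=False)
        .reset_index()
    )
    pooled = dict(_pool(per_segment))
    pooled.pop("n_segments")
    return OptomotorSummary(per_segment, per_stimulus, pooled)


def acuity_scores(
    intervals_by_stimulus: dict,
    static_intervals: list[tuple[float, float]] | None = None,
    presentation_s: float = 60.0,
) -> pd.DataFrame:
    """Visual-acuity scores from manually scored following intervals.

    Each rotating-grating stimulus is shown for 60 s; the score is the
    proportion of that minute the fish spent circling with the stimulus.
    Intervals exceeding the presentation window are truncated with a
    warning.  The activity proportion during the static-control
    presentation is carried alongside (as a covariate, never subtracted).
    """
    def _total(intervals) -> float:
        total = 0.0
        for start, end in intervals:
            if end <= start:
                raise ValidationError(f"interval ({start}, {end}) has non-positive length")
            if end > presentation_s:
                warnings.warn(
                    f"interval ({start}, {end}) truncated at {presentation_s} s",
                    stacklevel=3,
                )
                end = presentation_s
            if start >= presentation_s:
                continue
            total += end - start
        return total

    static_prop = _total(static_intervals) / presentation_s if static_intervals is not None else float("nan")
    rows = [
        {
            "stimulus": key,
            "proportion_following": _total(intervals) / presentation_s,
            "static_activity_proportion": static_prop,
        }
        for key, intervals in intervals_by_stimulus.items()
    ]
    return pd.DataFrame(rows)
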