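"""Synthetic-data generators with the statistical structure the analyses assume.

Four generators:

- :func:`simulate_school` — a zonal (repulsion / alignment / attraction)
  agent-based model of 8 guppies in the 55 cm arena at 25 Hz, with
  treatment-dependent slowing, freezing bouts and stimulus avoidance, and
  selection-line offsets in alignment tendency and preferred speed.  The
  zonal family is used because it lets speed, cohesion and alignment be
  manipulated independently — the three response variables downstream.
- :func:`simulate_optomotor_fish` — a virtual fish orbiting the drum arena
  whose angular speed is ``gain x stimulus speed`` (lagged, noised).
- :func:`simulate_brain_volumes` — log-normal region volumes with
  replicate-line structure and configurable multiplicative region effects.
- :func:`simulate_trial_summaries` / :func:`simulate_inspection_counts` —
  summary-level cohorts (line + replicate + noise) for calibrating the
  statistical layer.

Every generator is deterministic given its seed.  No generator is
calibrated to reproduce real-data effect magnitudes; defaults are chosen
to be biologically plausible for female guppies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import (
    BRAIN_REGIONS,
    AnalysisConfig,
    ArenaGeometry,
    BrainVolumeTable,
    TrajectoryDataset,
    ValidationError,
)
from .optomotor import CW, OptomotorTrack, StimulusSchedule

__all__ = [
    "SchoolSimConfig",
    "VirtualFishConfig",
    "TREATMENT_RESPONSES",
    "simulate_school",
    "simulate_line_cohort",
    "inject_track_loss",
    "simulate_optomotor_fish",
    "simulate_brain_volumes",
    "simulate_trial_summaries",
    "simulate_inspection_counts",
]


@dataclass
class StimulusResponse:
    """How a school reacts to an object in the arena center."""

    slowdown_factor: float = 1.0  # multiplies preferred speed near the stimulus
    freeze_prob_per_s: float = 0.0
    freeze_mean_s: float = 2.0  # exponential bout length
    avoidance_radius: float = 0.0  # mm
    avoidance_strength: float = 0.0
    head_zone_extra: float = 0.0  # extra avoidance weight for y > 0 (model head)

    def __post_init__(self) -> None:
        if not (0.0 < self.slowdown_factor <= 1.0):
            raise ValidationError("slowdown factor must lie in (0, 1]")
        if not (0.0 <= self.freeze_prob_per_s <= 1.0):
            raise ValidationError("freeze probability must lie in [0, 1]")


#: Stimulus responses by treatment: none in the open field, moderate for the
#: novel object, strong (more slowing, freezing and head-zone avoidance) for
#: the predator model.
TREATMENT_RESPONSES = {
    "open_field": StimulusResponse(),
    "novel_object": StimulusResponse(
        slowdown_factor=0.45, freeze_prob_per_s=0.03, freeze_mean_s=1.5,
        avoidance_radius=150.0, avoidance_strength=0.8, head_zone_extra=0.0,
    ),
    "predator_model": StimulusResponse(
        slowdown_factor=0.3, freeze_prob_per_s=0.08, freeze_mean_s=2.5,
        avoidance_radius=200.0, avoidance_strength=1.2, head_zone_extra=0.8,
    ),
}


@dataclass
class SchoolSimConfig:
    """Parameters of the zonal schooling simulator.

    Speeds are mm/frame at 25 Hz (3.0 mm/frame = 75 mm/s, about three body
    lengths per second for an actively cruising 25 mm female guppy).  Line
    offsets are added for the polarization-selected line only.
    """

    n_fish: int = 8
    fps: float = 25.0
    duration_s: float = 360.0
    arena_radius: float = 275.0
    preferred_speed: float = 3.0
    line_speed_offset: float = 0.25
    alignment_weight: float = 0.8
    line_alignment_offset: float = 0.4
    attraction_weight: float = 0.6
    repulsion_radius: float = 25.0
    repulsion_weight: float = 2.0
    persistence_weight: float = 1.5
    heading_noise: float = 0.9  # circular std, radians per frame
    alignment_radius: float = 150.0
    attraction_radius: float = 400.0
    speed_relax: float = 0.25  # per-frame relaxation toward target speed
    track_loss_rate: float = 0.0
    track_loss_mean_gap_frames: float = 25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("alignment_weight", "attraction_weight", "repulsion_weight",
                     "persistence_weight", "heading_noise"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not (0.0 <= self.track_loss_rate <= 1.0):
            raise ValidationError("track loss rate must lie in [0, 1]")
        if self.preferred_speed <= 0:
            raise ValidationError("preferred speed must be positive")


@dataclass
class VirtualFishConfig:
    """Virtual optomotor fish: follows the drum at ``gain`` x stimulus speed."""

    gain: float = 1.0
    lag_s: float = 0.0
    heading_noise: float = 0.0  # deg/s std of angular speed noise
    orbit_radius: float = 180.0  # mm
    fps: float = 25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gain <= 1.0):
            raise ValidationError("gain must lie in [0, 1]")
        if self.lag_s < 0:
            raise ValidationError("lag must be nonnegative")


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.divide(v, norm, out=np.zeros_like(v), where=norm > 0)


def _simulate_positions(
    config: SchoolSimConfig,
    response: StimulusResponse,
    align_w: np.ndarray,
    speed_pref: np.ndarray,
    rng: np.random.Generator,
    initial_positions: np.ndarray | None = None,
) -> np.ndarray:
    """Core Euler stepper, vectorised over a batch of independent trials.

    ``align_w`` and ``speed_pref`` are per-trial arrays of length B; the
    return is ``(n_frames, B, n_fish, 2)``.  Kept private: callers use
    :func:`simulate_school` (B=1) or :func:`simulate_line_cohort`.
    """
    B = len(align_w)
    n = config.n_fish
    n_frames = int(round(config.duration_s * config.fps))
    radius = config.arena_radius
    align_w = align_w[:, None, None]
    speed_pref = np.broadcast_to(speed_pref[:, None], (B, n))

    if initial_positions is not None:
        pos = np.asarray(initial_positions, dtype=float).reshape(B, n, 2).copy()
        if np.any(np.linalg.norm(pos, axis=-1) > radius):
            raise ValidationError("fish initialized outside the arena")
    else:
        r = radius * 0.4 * np.sqrt(rng.random((B, n)))
        phi = rng.uniform(0, 2 * np.pi, (B, n))
        pos = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)
    angles = rng.uniform(0, 2 * np.pi, (B, n))
    heading = np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    speed = speed_pref.copy()
    frozen_until = np.full((B, n), -1)

    p_freeze = response.freeze_prob_per_s / config.fps
    out = np.empty((n_frames, B, n, 2))
    eye = np.eye(n, dtype=bool)

    for t in range(n_frames):
        out[t] = pos
        diff = pos[:, None, :, :] - pos[:, :, None, :]  # diff[b, i, j] = p_j - p_i
        dist = np.linalg.norm(diff, axis=-1)
        dist[:, eye] = np.inf

        rep_mask = dist < config.repulsion_radius
        rep = -(_unit(diff) * rep_mask[..., None]).sum(axis=2)

        ali_mask = dist < config.alignment_radius
        ali = _unit((heading[:, None, :, :] * ali_mask[..., None]).sum(axis=2))

        att_mask = dist < config.attraction_radius
        counts = att_mask.sum(axis=2)[..., None]
        centroid_others = np.divide(
            (pos[:, None, :, :] * att_mask[..., None]).sum(axis=2),
            counts,
            out=pos.copy(),
            where=counts > 0,
        )
        att = _unit(centroid_others - pos)

        steer = (
            config.persistence_weight * heading
            + align_w * ali
            + config.attraction_weight * att
            + config.repulsion_weight * rep
        )

        r_now = np.linalg.norm(pos, axis=-1)
        near_stim = np.zeros((B, n), dtype=bool)
        if response.avoidance_radius > 0:
            near_stim = r_now < response.avoidance_radius
            away = _unit(pos)
            strength = response.avoidance_strength + response.head_zone_extra * (
                pos[..., 1] > 0
            )
            steer += (near_stim * strength)[..., None] * away

        # inward bias near the wall keeps density maps free of edge pile-up
        near_wall = r_now > radius - 20.0
        steer -= near_wall[..., None] * _unit(pos)

        direction = _unit(steer)
        fallback = np.linalg.norm(direction, axis=-1) == 0
        direction[fallback] = heading[fallback]
        noise = rng.normal(0.0, config.heading_noise, (B, n))
        cos_n, sin_n = np.cos(noise), np.sin(noise)
        heading = np.stack(
            [
                cos_n * direction[..., 0] - sin_n * direction[..., 1],
                sin_n * direction[..., 0] + cos_n * direction[..., 1],
            ],
            axis=-1,
        )

        target = np.where(near_stim, speed_pref * response.slowdown_factor, speed_pref)
        speed = speed + config.speed_relax * (target - speed)

        if p_freeze > 0:
            start = (rng.random((B, n)) < p_freeze) & (frozen_until < t)
            if start.any():
                lengths = rng.exponential(
                    response.freeze_mean_s * config.fps, int(start.sum())
                )
                frozen_until[start] = t + np.maximum(lengths.astype(int), 1)
        frozen = frozen_until >= t
        eff_speed = np.where(frozen, 0.0, speed)

        new_pos = pos + heading * eff_speed[..., None]
        outside = np.linalg.norm(new_pos, axis=-1) > radius - 2.0
        if outside.any():
            # reflect heading about the wall tangent, then bias inward
            normal = _unit(pos[outside])
            h = heading[outside]
            h = h - 2 * (h * normal).sum(axis=-1, keepdims=True) * normal
            heading[outside] = _unit(h - 0.3 * normal)
            new_pos[outside] = pos[outside] + heading[outside] * eff_speed[outside, None]
            still_out = np.linalg.norm(new_pos, axis=-1) > radius - 2.0
            if still_out.any():
                bad = tuple(np.array(np.nonzero(outside))[:, still_out])
                new_pos[bad] = _unit(new_pos[bad]) * (radius - 2.0)
        pos = new_pos
    return out


def _line_params(config: SchoolSimConfig, line: str) -> tuple[float, float]:
    align_w = config.alignment_weight
    speed_pref = config.preferred_speed
    if line == "polarization":
        align_w += config.line_alignment_offset
        speed_pref += config.line_speed_offset
    return align_w, speed_pref


def simulate_school(
    config: SchoolSimConfig,
    treatment: str = "open_field",
    line: str = "control",
    replicate: str = "1",
    trial_id: str | None = None,
    presentation_order: int = 1,
    response: StimulusResponse | None = None,
    initial_positions: np.ndarray | None = None,
) -> TrajectoryDataset:
    """Simulate one trial of 8 fish schooling in the circular arena.

    Per frame (Euler step, one frame at 25 Hz) each fish steers by a
    weighted sum of repulsion from neighbours within the repulsion radius,
    alignment to the mean neighbour heading, attraction to the neighbour
    centroid and its own heading persistence, plus wrapped-normal heading
    noise.  Speed relaxes toward the preferred speed, multiplied by the
    treatment's slowdown factor within the stimulus avoidance radius;
    freezing bouts (exponential length) clamp speed to zero.  Walls reflect
    the heading with a small inward bias.  Deterministic given the seed.
    """
    if treatment not in TREATMENT_RESPONSES:
        raise ValidationError(f"unknown treatment {treatment!r}")
    response = response or TREATMENT_RESPONSES[treatment]
    rng = np.random.default_rng(config.seed)
    align_w, speed_pref = _line_params(config, line)
    out = _simulate_positions(
        config,
        response,
        np.array([align_w]),
        np.array([speed_pref]),
        rng,
        None if initial_positions is None else np.asarray(initial_positions)[None],
    )

    traj = TrajectoryDataset(
        trial_id=trial_id or f"sim-{treatment}-{line}-{replicate}-{config.seed}",
        treatment=treatment,
        line=line,
        replicate=str(replicate),
        presentation_order=presentation_order,
        fps=config.fps,
        positions=out[:, 0],
        arena=ArenaGeometry(
            radius=config.arena_radius, stimulus_present=treatment != "open_field"
        ),
    )
    if config.track_loss_rate > 0:
        loss_seed = None if config.seed is None else config.seed + 1
        traj = inject_track_loss(
            traj, config.track_loss_rate, config.track_loss_mean_gap_frames, loss_seed
        )
    return traj


def simulate_line_cohort(
    config: SchoolSimConfig,
    treatment: str = "open_field",
    trials_per_line: int = 14,
    n_replicates: int = 3,
    seed: int | None = None,
) -> list[TrajectoryDataset]:
    """Simulate a full two-regime cohort in one vectorised batch.

    ``n_replicates`` replicate lines per regime, ``trials_per_line`` trials
    each; polarization-line trials carry the configured alignment and
    speed offsets.  All trials step in a single batched call, so a cohort
    costs little more than a handful of individual trials.
    """
    if treatment not in TREATMENT_RESPONSES:
        raise ValidationError(f"unknown treatment {treatment!r}")
    response = TREATMENT_RESPONSES[treatment]
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    meta = [
        (line, str(rep + 1), k)
        for line in ("polarization", "control")
        for rep in range(n_replicates)
        for k in range(trials_per_line)
    ]
    params = np.array([_line_params(config, line) for line, _, _ in meta])
    out = _simulate_positions(config, response, params[:, 0], params[:, 1], rng)
    arena = ArenaGeometry(
        radius=config.arena_radius, stimulus_present=treatment != "open_field"
    )
    return [
        TrajectoryDataset(
            trial_id=f"sim-{treatment}-{line}-{rep}-{k:03d}",
            treatment=treatment,
            line=line,
            replicate=rep,
            presentation_order=1,
            fps=config.fps,
            positions=out[:, b],
            arena=arena,
        )
        for b, (line, rep, k) in enumerate(meta)
    ]


def inject_track_loss(
    traj: TrajectoryDataset,
    loss_rate: float,
    mean_gap_frames: float = 25.0,
    seed: int | None = None,
) -> TrajectoryDataset:
    """Delete contiguous per-fish track gaps, emulating tracker identity loss.

    Missingness follows a two-state Markov chain per fish with stationary
    missing fraction ``loss_rate`` and mean gap length ``mean_gap_frames``,
    so expected completeness is ``1 - loss_rate`` up to Monte-Carlo noise.
    ``loss_rate`` 0 returns an identical dataset.
    """
    if not (0.0 <= loss_rate <= 1.0):
        raise ValidationError("loss rate must lie in [0, 1]")
    positions = traj.positions.copy()
    if loss_rate > 0:
        if loss_rate < 1.0:
            rng = np.random.default_rng(seed)
            p_exit = 1.0 / mean_gap_frames
            p_enter = loss_rate * p_exit / (1.0 - loss_rate)
            for j in range(traj.n_fish):
                missing = rng.random() < loss_rate
                for t in range(traj.n_frames):
                    if missing:
                        positions[t, j] = np.nan
                        missing = rng.random() >= p_exit
                    else:
                        missing = rng.random() < p_enter
        else:
            positions[:] = np.nan
    return TrajectoryDataset(
        trial_id=traj.trial_id,
        treatment=traj.treatment,
        line=traj.line,
        replicate=traj.replicate,
        presentation_order=traj.presentation_order,
        fps=traj.fps,
        positions=positions,
        arena=traj.arena,
    )


def simulate_optomotor_fish(
    config: VirtualFishConfig, schedule: StimulusSchedule
) -> OptomotorTrack:
    """Virtual fish orbiting the drum arena at ``gain`` x stimulus speed.

    The fish circles at a fixed radius; its signed angular speed tracks the
    (lagged) stimulus speed scaled by the gain, with optional white noise.
    During acclimation and the 3 s transitions the stimulus program is
    piecewise constant at the adjacent segment's speed (those frames are
    excluded from scoring anyway).  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    fps = config.fps
    n_frames = int(round(schedule.total_s * fps)) + 1
    times = np.arange(n_frames) / fps - config.lag_s

    stim = np.zeros(n_frames)
    for seg in schedule.segments:
        sel = (times >= seg.t_start_s) & (times < seg.t_end_s)
        stim[sel] = seg.signed_speed
    omega = config.gain * stim  # deg/s, clockwise positive
    if config.heading_noise > 0:
        omega = omega + rng.normal(0.0, config.heading_noise, n_frames)

    # clockwise-positive compass angle of the position vector
    angle = np.concatenate([[0.0], np.cumsum(omega[:-1]) / fps])
    rad = np.radians(angle)
    x = config.orbit_radius * np.sin(rad)
    y = config.orbit_radius * np.cos(rad)
    return OptomotorTrack(np.column_stack([x, y]), fps=fps)


def simulate_brain_volumes(
    n_per_line: int | tuple[int, int] = (13, 15),
    effect_map: dict | None = None,
    replicate_sd: float = 0.03,
    residual_sd: float = 0.08,
    allometric_slope: float = 2.0,
    n_replicates: int = 3,
    seed: int | None = None,
) -> BrainVolumeTable:
    """Log-normal brain-region volumes with replicate-line structure.

    Region volumes (mm^3) are built independently around species-plausible
    shares of an ~8 mm^3 brain, scale allometrically with standard length
    (log-log slope ``allometric_slope``), and carry a shared per-replicate
    intercept (sd ``replicate_sd``) plus per-region residual noise (sd
    ``residual_sd``), all on the log scale.  ``effect_map`` maps region
    name -> multiplicative ratio applied in the polarization line; the
    default applies a 7% larger thalamus, 4% larger optic tectum cup and 8%
    smaller medulla oblongata.  The whole brain is the region sum plus an
    unparcellated remainder, so the parcellation invariant holds by
    construction and applying a ratio to one region leaves its
    rest-of-brain volume untouched.
    """
    if effect_map is None:
        effect_map = {
            "thalamus": 1.07,
            "optic_tectum_cup": 1.04,
            "medulla_oblongata": 1.0 / 1.08,
        }
    for region, ratio in effect_map.items():
        if region not in BRAIN_REGIONS:
            raise ValidationError(f"unknown region {region!r} in effect map")
        if ratio <= 0:
            raise ValidationError("effect ratios must be positive")
    if isinstance(n_per_line, int):
        n_per_line = (n_per_line, n_per_line)
    rng = np.random.default_rng(seed)

    # approximate shares of total brain volume (sum 0.92; remainder 8%)
    shares = {
        "olfactory_bulbs": 0.02,
        "ventral_telencephalon": 0.07,
        "dorsal_telencephalon": 0.13,
        "thalamus": 0.04,
        "hypothalamus": 0.09,
        "nucleus_glomerulus": 0.02,
        "torus_semicircularis": 0.04,
        "optic_tectum_cup": 0.18,
        "central_optic_tectum": 0.12,
        "cerebellum": 0.12,
        "medulla_oblongata": 0.09,
    }
    base_sl = 25.0  # mm standard length
    base_total = 8.0  # mm^3

    rows = []
    for line, n_fish in zip(("polarization", "control"), n_per_line):
        rep_effects = rng.normal(0.0, replicate_sd, n_replicates)
        for i in range(n_fish):
            replicate = i % n_replicates
            sl = rng.normal(base_sl, 1.5)
            sl = max(sl, 15.0)
            log_size = allometric_slope * np.log(sl / base_sl) + rep_effects[replicate]
            row = {
                "fish_id": f"{line[:3]}-{replicate + 1}-{i:03d}",
                "line": line,
                "replicate": str(replicate + 1),
                "standard_length": sl,
            }
            total = 0.0
            for region in BRAIN_REGIONS:
                ratio = effect_map.get(region, 1.0) if line == "polarization" else 1.0
                vol = (
                    shares[region]
                    * base_total
                    * ratio
                    * np.exp(log_size + rng.normal(0.0, residual_sd))
                )
                row[region] = vol
                total += vol
            remainder = 0.08 * base_total * np.exp(log_size)
            row["whole_brain"] = total + remainder
            rows.append(row)
    return BrainVolumeTable(pd.DataFrame(rows))


def simulate_trial_summaries(
    trials_per_line: int = 14,
    n_replicates: int = 3,
    line_effect: float = 0.0,
    baseline: float = 0.55,
    replicate_sd: float = 0.02,
    residual_sd: float = 0.08,
    response: str = "median_polarization",
    seed: int | None = None,
) -> pd.DataFrame:
    """Summary-level two-regime cohort for calibrating the statistical layer.

    Each regime has ``n_replicates`` replicate lines of ``trials_per_line``
    trials; the response is baseline + line effect (polarization regime
    only) + a per-line normal intercept + residual noise.  The defaults
    mimic the study's scale: ~40 trials per regime across 3 lines, small
    between-line and larger within-line variation in median polarization.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for line in ("polarization", "control"):
        shift = line_effect if line == "polarization" else 0.0
        for rep in range(n_replicates):
            intercept = baseline + shift + rng.normal(0.0, replicate_sd)
            values = intercept + rng.normal(0.0, residual_sd, trials_per_line)
            for k, v in enumerate(values):
                rows.append(
                    {
                        "trial_id": f"{line[:3]}-{rep + 1}-{k:03d}",
                        "line": line,
                        "replicate": str(rep + 1),
                        response: float(v),
                    }
                )
    return pd.DataFrame(rows)


def simulate_inspection_counts(
    trials_per_line: int = 27,
    n_replicates: int = 3,
    rate_control: float = 8.0,
    rate_ratio: float = 1.0,
    replicate_sd_log: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Poisson inspection counts with a configurable incidence-rate ratio.

    The polarization regime's rate is ``rate_control x rate_ratio``;
    replicate lines share log-normal rate intercepts of sd
    ``replicate_sd_log``.
    """
    if rate_ratio <= 0 or rate_control <= 0:
        raise ValidationError("rates must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for line in ("polarization", "control"):
        rate = rate_control * (rate_ratio if line == "polarization" else 1.0)
        for rep in range(n_replicates):
            lam = rate * np.exp(rng.normal(0.0, replicate_sd_log))
            counts = rng.poisson(lam, trials_per_line)
            for k, c in enumerate(counts):
                rows.append(
                    {
                        "trial_id": f"{line[:3]}-{rep + 1}-{k:03d}",
                        "line": line,
                        "replicate": str(rep + 1),
                        "n_inspections": int(c),
                    }
                )
    return pd.DataFrame(rows)
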