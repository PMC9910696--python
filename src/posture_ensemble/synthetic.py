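"""Synthetic inpatient-like sessions: posture schedules, matching
accelerations, and data losses.

The generator emulates a hospital ward day: reclining-dominant nights,
upright peaks around mealtimes, and rare short walking bouts, as a
time-inhomogeneous Markov chain on the 24-h epoch grid.  Acceleration
is rendered per epoch so that the trunk angle of each sample matches
the label's configured angle regime, with walking epochs carrying a
sinusoidal norm oscillation at gait cadence.  Everything is
seed-deterministic; no global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sensor_io import (
    MISSING,
    POSTURES,
    RECLINING,
    SITTING,
    WALKING,
    AccelSeries,
    EpochGrid,
    PostureDaySeries,
    write_accel_csv,
    write_posture_csv,
)
from .loss_sim import LossSpec, inject_losses

__all__ = [
    "ScheduleBlock",
    "ScheduleConfig",
    "AccelRenderConfig",
    "default_schedule",
    "simulate_posture_days",
    "render_acceleration",
    "simulate_heart_rate_days",
    "make_session_fixtures",
]


@dataclass(frozen=True)
class ScheduleBlock:
    """One time-of-day block with a stationary posture distribution."""

    start_hour: float
    end_hour: float
    probs: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 <= self.start_hour < self.end_hour <= 24:
            raise ValueError("block hours must satisfy 0 <= start < end <= 24")
        if set(self.probs) - set(POSTURES):
            raise ValueError(f"block probabilities must be over {POSTURES}")
        if not np.isclose(sum(self.probs.values()), 1.0):
            raise ValueError("block probabilities must sum to 1")


@dataclass(frozen=True)
class ScheduleConfig:
    """Time-inhomogeneous Markov posture schedule.

    At each epoch the chain keeps the previous label with probability
    ``persistence``; otherwise it redraws from the current block's
    distribution, so the within-block stationary distribution equals
    the block distribution regardless of persistence.  A fresh draw of
    ``walking`` starts a bout lasting ``walk_bout_length`` epochs (the
    per-block walking probability is therefore the bout *initiation*
    rate).  Blocks must tile 24 h exactly.
    """

    grid: EpochGrid = field(default_factory=EpochGrid)
    blocks: tuple[ScheduleBlock, ...] = ()
    persistence: float = 0.9
    walk_bout_length: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must lie in [0, 1]")
        if self.walk_bout_length < 1:
            raise ValueError("walk_bout_length must be >= 1")
        blocks = tuple(sorted(self.blocks, key=lambda b: b.start_hour))
        object.__setattr__(self, "blocks", blocks)
        if not blocks:
            return
        if blocks[0].start_hour != 0 or blocks[-1].end_hour != 24:
            raise ValueError("blocks must tile 24 h (start at 0, end at 24)")
        for a, b in zip(blocks, blocks[1:]):
            if not np.isclose(a.end_hour, b.start_hour):
                raise ValueError("blocks must tile 24 h without gaps or overlaps")

    def block_index_per_epoch(self) -> np.ndarray:
        hours = (np.arange(self.grid.epochs_per_day) + 0.5) * self.grid.epoch_length / 3600.0
        starts = np.array([b.start_hour for b in self.blocks])
        return np.clip(np.searchsorted(starts, hours, side="right") - 1, 0, len(self.blocks) - 1)


def default_schedule(grid: EpochGrid | None = None, seed: int = 0) -> ScheduleConfig:
    """Ward-like default: reclining-dominant 21:00-06:00, upright peaks
    around the 8:00 / 12:00 / 18:00 meals, walking of order 1 % of
    daytime epochs."""
    # Per-block walking probability is a bout *initiation* rate applied on
    # the (1 - persistence) fraction of fresh-draw epochs; at the defaults
    # (persistence 0.9, 3-epoch bouts) a daytime value of 0.025 realises a
    # walking ratio of roughly half a percent of the day.
    b = ScheduleBlock
    blocks = (
        b(0.0, 6.0, {RECLINING: 0.97, SITTING: 0.03, WALKING: 0.0}),
        b(6.0, 7.5, {RECLINING: 0.60, SITTING: 0.375, WALKING: 0.025}),
        b(7.5, 8.5, {RECLINING: 0.25, SITTING: 0.725, WALKING: 0.025}),
        b(8.5, 11.5, {RECLINING: 0.60, SITTING: 0.375, WALKING: 0.025}),
        b(11.5, 12.5, {RECLINING: 0.25, SITTING: 0.725, WALKING: 0.025}),
        b(12.5, 17.5, {RECLINING: 0.60, SITTING: 0.375, WALKING: 0.025}),
        b(17.5, 18.5, {RECLINING: 0.25, SITTING: 0.725, WALKING: 0.025}),
        b(18.5, 21.0, {RECLINING: 0.70, SITTING: 0.295, WALKING: 0.005}),
        b(21.0, 24.0, {RECLINING: 0.97, SITTING: 0.03, WALKING: 0.0}),
    )
    return ScheduleConfig(grid=grid or EpochGrid(), blocks=blocks, seed=seed)


def simulate_posture_days(
    config: ScheduleConfig | None = None,
    n_days: int = 2,
    rng: np.random.Generator | None = None,
) -> list[PostureDaySeries]:
    """Draw ``n_days`` independent day series from the schedule.

    Day-to-day variation comes from independent draws of the same
    chain; output is deterministic given ``config.seed``.
    """
    config = config or default_schedule()
    if not config.blocks:
        raise ValueError("schedule has no blocks")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = config.grid
    n_epochs = grid.epochs_per_day
    block_idx = config.block_index_per_epoch()
    labels_order = list(POSTURES)
    block_probs = [
        np.array([blk.probs.get(lab, 0.0) for lab in labels_order]) for blk in config.blocks
    ]

    days = []
    for d in range(n_days):
        labels = np.empty(n_epochs, dtype=object)
        prev = None
        bout_remaining = 0
        for t in range(n_epochs):
            if bout_remaining > 0:
                labels[t] = WALKING
                bout_remaining -= 1
                prev = WALKING
                continue
            if prev is not None and rng.random() < config.persistence and prev != WALKING:
                labels[t] = prev
                continue
            p = block_probs[block_idx[t]]
            lab = labels_order[rng.choice(len(labels_order), p=p)]
            if lab == WALKING:
                bout_remaining = config.walk_bout_length - 1
            labels[t] = lab
            prev = lab
        days.append(PostureDaySeries(day_id=f"day{d + 1}", grid=grid, labels=labels))
    return days


@dataclass(frozen=True)
class AccelRenderConfig:
    """Per-posture acceleration regimes used to render raw samples.

    Reclining epochs are rendered at ``reclining_angle`` (supine-side
    epochs at ``supine_angle`` when ``supine_fraction`` > 0), upright
    and walking epochs at ``upright_angle``; per-sample angular jitter
    and per-axis sensor noise are Gaussian.  Walking epochs modulate
    the norm with a sinusoid of amplitude ``gait_amplitude`` at
    ``cadence`` Hz, which the default step detector resolves.
    """

    reclining_angle: float = 10.0
    supine_angle: float = 170.0
    supine_fraction: float = 0.0
    upright_angle: float = 90.0
    jitter_sd: float = 8.0
    noise_sd: float = 0.03
    gait_amplitude: float = 0.3
    cadence: float = 2.0
    sample_rate: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if 35.0 <= self.reclining_angle <= 143.0 or 35.0 <= self.supine_angle <= 143.0:
            raise ValueError("reclining/supine mean angles must lie outside [35, 143] deg")
        if not 35.0 <= self.upright_angle <= 143.0:
            raise ValueError("upright mean angle must lie inside [35, 143] deg")
        if not 0 <= self.supine_fraction <= 1:
            raise ValueError("supine_fraction must lie in [0, 1]")
        if self.sample_rate <= 0 or self.cadence <= 0:
            raise ValueError("sample_rate and cadence must be positive")


def render_acceleration(
    day: PostureDaySeries,
    config: AccelRenderConfig | None = None,
    date: str = "2000-01-01",
    rng: np.random.Generator | None = None,
) -> AccelSeries:
    """Render 25 Hz (by default) tri-axial samples consistent with a day's labels.

    Missing epochs emit no samples, emulating raw data loss.  For a
    label with mean angle theta, samples point along
    ``(0, sin(theta), cos(theta))`` so the recovered trunk angle
    matches the regime; walking epochs additionally oscillate the norm
    at gait cadence.
    """
    config = config or AccelRenderConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = day.grid
    present = np.flatnonzero(day.labels != MISSING)
    if present.size == 0:
        raise ValueError("day has no non-missing epochs to render")
    n_per = int(round(config.sample_rate * grid.epoch_length))
    lab_epochs = day.labels[present]

    # mean angle per epoch; a supine_fraction of reclining epochs render supine-side
    mean_angle = np.where(lab_epochs == RECLINING, config.reclining_angle, config.upright_angle)
    if config.supine_fraction > 0:
        supine = (lab_epochs == RECLINING) & (rng.random(present.size) < config.supine_fraction)
        mean_angle = np.where(supine, config.supine_angle, mean_angle)

    t_sec = (
        np.repeat(present * grid.epoch_length, n_per)
        + np.tile(np.arange(n_per) / config.sample_rate, present.size)
    )
    theta = np.repeat(mean_angle, n_per) + rng.normal(0.0, config.jitter_sd, t_sec.size)
    phase = np.repeat(rng.uniform(0, 2 * np.pi, present.size), n_per)
    amp = np.repeat(np.where(lab_epochs == WALKING, config.gait_amplitude, 0.0), n_per)
    magnitude = 1.0 + amp * np.sin(2 * np.pi * config.cadence * t_sec + phase)

    rad = np.radians(theta)
    noise = rng.normal(0.0, config.noise_sd, (t_sec.size, 3))
    ax = noise[:, 0]
    ay = magnitude * np.sin(rad) + noise[:, 1]
    az = magnitude * np.cos(rad) + noise[:, 2]

    t = pd.Timestamp(date) + pd.to_timedelta(t_sec, unit="s")
    data = pd.DataFrame({"t": t, "ax": ax, "ay": ay, "az": az})
    return AccelSeries(day_id=day.day_id, data=data, nominal_rate=config.sample_rate)


def simulate_heart_rate_days(
    n_days: int,
    grid: EpochGrid | None = None,
    seed: int = 0,
    base: float = 70.0,
    circadian_amplitude: float = 8.0,
    noise_sd: float = 2.0,
) -> list[np.ndarray]:
    """Minimal heart-rate generator (circadian sinusoid + noise) to
    exercise quantitative ensemble averaging; not a physiological model."""
    grid = grid or EpochGrid()
    rng = np.random.default_rng(seed)
    hours = np.arange(grid.epochs_per_day) * grid.epoch_length / 3600.0
    circadian = base - circadian_amplitude * np.cos(2 * np.pi * (hours - 16) / 24)
    return [circadian + rng.normal(0, noise_sd, grid.epochs_per_day) for _ in range(n_days)]


def make_session_fixtures(
    out_dir,
    n_sessions: int = 1,
    days_per_session: int = 2,
    loss: LossSpec | None = None,
    seed: int = 0,
    schedule: ScheduleConfig | None = None,
    render: AccelRenderConfig | None = None,
    write_accel: bool = True,
) -> dict:
    """Write a reproducible on-disk fixture set of synthetic sessions.

    Per session day: a posture CSV and (optionally) a matching
    acceleration CSV; plus one ``manifest.json`` recording ids, paths,
    seeds and the exact injected-loss epochs.  Regeneration with the
    same arguments is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = schedule or default_schedule()
    render = render or AccelRenderConfig()
    root_ss = np.random.SeedSequence(seed)
    manifest = {
        "seed": seed,
        "n_sessions": n_sessions,
        "days_per_session": days_per_session,
        "epoch_length": schedule.grid.epoch_length,
        "loss": None
        if loss is None
        else {"target_rate": loss.target_rate, "block_length": loss.block_length},
        "sessions": [],
    }
    for s, session_ss in enumerate(root_ss.spawn(n_sessions)):
        rng = np.random.default_rng(session_ss)
        sid = f"session_{s:03d}"
        days = simulate_posture_days(schedule, days_per_session, rng=rng)
        entry = {"id": sid, "days": []}
        for d, day in enumerate(days):
            day = replace_day_id(day, f"{sid}_day{d + 1}")
            masked: list[int] = []
            if loss is not None:
                day, mask = inject_losses(day, loss, rng=rng, return_mask=True)
                masked = np.flatnonzero(mask).tolist()
            posture_path = out / f"{day.day_id}_posture.csv"
            write_posture_csv(day, posture_path)
            day_entry = {
                "day_id": day.day_id,
                "posture_csv": posture_path.name,
                "injected_loss_epochs": masked,
            }
            if write_accel:
                date = (pd.Timestamp("2000-01-01") + pd.Timedelta(days=d)).strftime("%Y-%m-%d")
                accel = render_acceleration(day, render, date=date, rng=rng)
                accel_path = out / f"{day.day_id}_accel.csv"
                write_accel_csv(accel, accel_path)
                day_entry["accel_csv"] = accel_path.name
            entry["days"].append(day_entry)
        manifest["sessions"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def replace_day_id(day: PostureDaySeries, day_id: str) -> PostureDaySeries:
    return PostureDaySeries(day_id=day_id, grid=day.grid, labels=day.labels.copy())
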