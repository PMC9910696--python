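"""Containers and file I/O for trunk-worn accelerometer sessions.

A measurement session is one or more calendar days of tri-axial
acceleration recorded by a chest-worn sensor (nominally 25 Hz, units of
g).  Postures derived from it live on a fixed *epoch grid*: the 24-h
clock divided into equal epochs (1 min by default), shared across days
so that the same epoch index always means the same time of day.

Acceleration files are plain CSV with header ``timestamp,ax,ay,az``;
posture files are CSV with header ``epoch_start,label`` where the label
set is closed: ``reclining``, ``sitting_or_standing``, ``walking`` or
``missing``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400

RECLINING = "reclining"
SITTING = "sitting_or_standing"
WALKING = "walking"
MISSING = "missing"

#: The three posture states, in canonical order.
POSTURES = (RECLINING, SITTING, WALKING)
#: All admissible epoch labels (postures plus the missing marker).
LABELS = POSTURES + (MISSING,)

ACCEL_COLUMNS = ("timestamp", "ax", "ay", "az")


class FormatError(ValueError):
    """A file or label sequence violates the declared format."""


class EmptyInputError(ValueError):
    """An operation received no usable data."""


class GridMismatchError(ValueError):
    """Day series expected to share one epoch grid do not."""


@dataclass(frozen=True)
class EpochGrid:
    """Fixed time-of-day grid the posture series live on.

    Parameters
    ----------
    epoch_length : int
        Epoch duration in seconds.  Must divide 86400 so that epochs
        tile the 24-h day exactly; the grid is anchored at local
        midnight and epochs are half-open ``[start, start + length)``.
    """

    epoch_length: int = 60

    def __post_init__(self) -> None:
        if self.epoch_length <= 0 or SECONDS_PER_DAY % self.epoch_length != 0:
            raise ValueError(
                f"epoch_length must be a positive divisor of {SECONDS_PER_DAY}, "
                f"got {self.epoch_length}"
            )

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_length

    @property
    def epoch_minutes(self) -> float:
        """Epoch duration in minutes (the inverse posture sampling rate)."""
        return self.epoch_length / 60.0

    def epoch_index(self, timestamps: pd.Series | pd.DatetimeIndex) -> np.ndarray:
        """Map timestamps to epoch indices by time of day."""
        ts = pd.DatetimeIndex(timestamps)
        seconds = (
            ts.hour.to_numpy() * 3600 + ts.minute.to_numpy() * 60 + ts.second.to_numpy()
        )
        return seconds // self.epoch_length

    def epoch_start_strings(self) -> list[str]:
        """``HH:MM:SS`` start-of-epoch strings for CSV export."""
        starts = np.arange(self.epochs_per_day) * self.epoch_length
        return [f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}" for s in starts]


@dataclass
class AccelSeries:
    """One day of tri-axial acceleration samples.

    ``data`` holds columns ``t`` (datetime64), ``ax``, ``ay``, ``az``
    (in g).  Timestamps are naive local time, strictly increasing, and
    confined to one calendar day; ward recordings are day-segmented and
    cross-midnight files are rejected rather than silently split.
    """

    day_id: str
    data: pd.DataFrame
    nominal_rate: float = 25.0

    def __post_init__(self) -> None:
        required = {"t", "ax", "ay", "az"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"AccelSeries data must have columns {sorted(required)}")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if len(self.data) == 0:
            raise EmptyInputError("AccelSeries must contain at least one sample")
        t = pd.DatetimeIndex(self.data["t"])
        if not t.is_monotonic_increasing or t.has_duplicates:
            raise FormatError("timestamps must be strictly increasing")
        if t.normalize().nunique() != 1:
            raise FormatError("samples must fall within a single calendar day")
        comps = self.data[["ax", "ay", "az"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(comps)):
            raise FormatError("acceleration components must be finite")

    def __len__(self) -> int:
        return len(self.data)

    def norms(self) -> np.ndarray:
        """Per-sample acceleration norm |a(t)| in g."""
        return accel_norm(
            self.data["ax"].to_numpy(),
            self.data["ay"].to_numpy(),
            self.data["az"].to_numpy(),
        )

    def seconds_from_start(self) -> np.ndarray:
        t = pd.DatetimeIndex(self.data["t"]).asi8
        return (t - t[0]) / 1e9


@dataclass
class PostureDaySeries:
    """Per-epoch posture labels for one day on a fixed grid."""

    day_id: str
    grid: EpochGrid
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.grid.epochs_per_day:
            raise ValueError(
                f"expected {self.grid.epochs_per_day} labels, got {len(self.labels)}"
            )
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise FormatError(f"unknown posture labels: {sorted(map(str, bad))}")

    @property
    def missing_mask(self) -> np.ndarray:
        return self.labels == MISSING

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def replace_labels(self, labels: np.ndarray, day_id: str | None = None) -> "PostureDaySeries":
        return PostureDaySeries(day_id or self.day_id, self.grid, labels)


def accel_norm(ax, ay, az):
    """Euclidean norm of the acceleration vector, in g.

    Accepts scalars or arrays; broadcasting follows numpy rules.
    """
    return np.sqrt(np.square(ax) + np.square(ay) + np.square(az))


def read_accel_csv(path, day_id: str | None = None, nominal_rate: float = 25.0) -> AccelSeries:
    """Read an acceleration CSV (``timestamp,ax,ay,az``) into an :class:`AccelSeries`.

    Rows with unparsable timestamps or non-numeric components are
    skipped and counted (logged at WARNING); the result is time-sorted.
    Duplicate timestamps keep the first occurrence.
    """
    df = pd.read_csv(path, dtype=str)
    missing_cols = set(ACCEL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    t = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    comps = {c: pd.to_numeric(df[c], errors="coerce") for c in ("ax", "ay", "az")}
    out = pd.DataFrame({"t": t, **comps})
    ok = out.notna().all(axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: skipped %d malformed row(s)", path, n_bad)
    out = out[ok].sort_values("t", kind="stable")
    out = out.drop_duplicates(subset="t", keep="first").reset_index(drop=True)
    if len(out) == 0:
        raise EmptyInputError(f"{path}: no parsable rows")
    if day_id is None:
        day_id = str(pd.Timestamp(out["t"].iloc[0]).date())
    return AccelSeries(day_id=day_id, data=out, nominal_rate=nominal_rate)


def write_accel_csv(series: AccelSeries, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(series.data["t"]).strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "ax": series.data["ax"].to_numpy(),
            "ay": series.data["ay"].to_numpy(),
            "az": series.data["az"].to_numpy(),
        }
    )
    df.to_csv(path, index=False, float_format="%.5f")


def flag_missing_epochs(
    series: AccelSeries, grid: EpochGrid, min_fraction: float = 0.5
) -> np.ndarray:
    """Boolean mask of epochs with too few samples to classify.

    An epoch is missing iff its observed sample count is below
    ``min_fraction`` of the expected count ``nominal_rate * epoch_length``.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    idx = grid.epoch_index(series.data["t"])
    counts = np.bincount(idx, minlength=grid.epochs_per_day)
    expected = series.nominal_rate * grid.epoch_length
    return counts < min_fraction * expected


def write_posture_csv(series: PostureDaySeries, path) -> None:
    """Write a posture day series as ``epoch_start,label`` CSV."""
    pd.DataFrame(
        {"epoch_start": series.grid.epoch_start_strings(), "label": series.labels}
    ).to_csv(path, index=False)


def read_posture_csv(path, day_id: str | None = None) -> PostureDaySeries:
    """Read a posture CSV back; the grid is inferred from the row count.

    Raises :class:`FormatError` on unknown label tokens (the label set
    is closed) or a row count that does not tile 24 h.
    """
    df = pd.read_csv(path, dtype=str)
    if not {"epoch_start", "label"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns epoch_start,label")
    n = len(df)
    if n == 0:
        raise EmptyInputError(f"{path}: no data rows")
    if SECONDS_PER_DAY % n != 0:
        raise FormatError(f"{path}: {n} epochs do not tile a 24-h day")
    grid = EpochGrid(epoch_length=SECONDS_PER_DAY // n)
    labels = df["label"].to_numpy(dtype=object)
    bad = set(labels) - set(LABELS)
    if bad:
        raise FormatError(f"{path}: unknown posture labels {sorted(map(str, bad))}")
    if day_id is None:
        import os

        day_id = os.path.splitext(os.path.basename(str(path)))[0]
    return PostureDaySeries(day_id=day_id, grid=grid, labels=labels)
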