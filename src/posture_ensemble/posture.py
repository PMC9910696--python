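"""Trunk-angle posture classification.

The chest-worn sensor's declination in the sagittal plane is computed
from the direction of the measured acceleration (gravity at rest):

    theta = (180/pi) * arccos(az / |a|),  signed by ay

Static postures are separated by two angle thresholds: within the
upright band ``[prone_upright, upright_supine]`` (35 deg and 143 deg by
default) the subject is sitting or standing; outside it (prone, supine,
or forward-flexed — including all negative angles) the subject is
reclining.  Walking is an overlay on the upright state: an epoch is
walking when the subject is upright and a rules-based step detector
fires on the acceleration norm.

Thresholds can also be estimated per session from the valleys of the
trunk-angle occurrence histogram, because long recordings of static
postures produce well-separated angle modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .sensor_io import (
    MISSING,
    RECLINING,
    SITTING,
    WALKING,
    AccelSeries,
    EmptyInputError,
    EpochGrid,
    PostureDaySeries,
    flag_missing_epochs,
)

__all__ = [
    "PostureThresholds",
    "WalkingRule",
    "TrunkAngleSeries",
    "AngleHistogram",
    "trunk_angle",
    "trunk_angle_series",
    "detect_walking",
    "classify_sample",
    "classify_samples",
    "classify_day",
    "build_angle_histogram",
    "estimate_thresholds",
]


class ZeroNormError(ValueError):
    """Trunk angle is undefined for a zero acceleration vector."""


@dataclass(frozen=True)
class PostureThresholds:
    """Angle boundaries of the upright band, in degrees."""

    prone_upright: float = 35.0
    upright_supine: float = 143.0

    def __post_init__(self) -> None:
        if not -180 < self.prone_upright < self.upright_supine < 180:
            raise ValueError(
                "thresholds must satisfy -180 < prone_upright < upright_supine < 180"
            )


@dataclass(frozen=True)
class WalkingRule:
    """Rules-based step detector operating on the acceleration norm.

    A walking span is a run of at least ``min_consecutive_steps`` peaks
    of the baseline-detrended norm exceeding ``peak_threshold`` (g),
    with successive inter-peak intervals inside
    ``[min_interval, max_interval]`` seconds — the plausible human
    cadence band.  The baseline is a centered moving average over
    ``baseline_window`` seconds.
    """

    peak_threshold: float = 0.1
    min_interval: float = 0.3
    max_interval: float = 2.0
    min_consecutive_steps: int = 4
    baseline_window: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.min_interval < self.max_interval:
            raise ValueError("require 0 < min_interval < max_interval")
        if self.min_consecutive_steps < 2:
            raise ValueError("min_consecutive_steps must be >= 2")
        if self.peak_threshold <= 0 or self.baseline_window <= 0:
            raise ValueError("peak_threshold and baseline_window must be positive")


@dataclass
class TrunkAngleSeries:
    """Per-sample trunk angles (degrees) for one day; NaN marks invalid samples."""

    day_id: str
    angles: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and (finite.min() < -180 or finite.max() > 180):
            raise ValueError("angles must lie in [-180, 180] degrees")


def trunk_angle(ax, ay, az):
    """Signed sagittal trunk angle in degrees.

    ``theta = (180/pi) arccos(az/|a|)`` with the sign of the ``ay``
    component (negative for ``ay < 0``).  Scalar inputs with zero norm
    raise :class:`ZeroNormError`; in array inputs zero-norm samples
    yield NaN so the caller can mark them invalid.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    norm = np.sqrt(ax**2 + ay**2 + az**2)
    scalar = norm.ndim == 0
    if scalar and norm == 0:
        raise ZeroNormError("trunk angle undefined for zero acceleration vector")
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(az / norm, -1.0, 1.0)))
    theta = np.where(ay >= 0, theta, -theta)
    theta = np.where(norm == 0, np.nan, theta)
    return float(theta) if scalar else theta


def trunk_angle_series(series: AccelSeries) -> TrunkAngleSeries:
    """Trunk angles for every sample of an acceleration day."""
    d = series.data
    return TrunkAngleSeries(
        day_id=series.day_id,
        angles=trunk_angle(d["ax"].to_numpy(), d["ay"].to_numpy(), d["az"].to_numpy()),
    )


def detect_walking(series: AccelSeries, rule: WalkingRule | None = None) -> np.ndarray:
    """Per-sample boolean walking mask from the acceleration norm.

    Peaks of the detrended norm above ``rule.peak_threshold`` are
    grouped greedily into runs of cadence-compatible intervals; runs of
    at least ``min_consecutive_steps`` peaks mark every sample from the
    first to the last peak of the run as walking.
    """
    rule = rule or WalkingRule()
    norm = series.norms()
    n = len(norm)
    window = max(1, int(round(rule.baseline_window * series.nominal_rate)))
    baseline = uniform_filter1d(norm, size=window, mode="nearest")
    detrended = norm - baseline
    peaks, _ = find_peaks(detrended, height=rule.peak_threshold)
    walking = np.zeros(n, dtype=bool)
    if len(peaks) == 0:
        return walking
    t = series.seconds_from_start()
    peak_times = t[peaks]
    run_start = 0
    for k in range(1, len(peaks) + 1):
        end_of_run = k == len(peaks)
        if not end_of_run:
            gap = peak_times[k] - peak_times[k - 1]
            if rule.min_interval <= gap <= rule.max_interval:
                continue
        if k - run_start >= rule.min_consecutive_steps:
            walking[peaks[run_start] : peaks[k - 1] + 1] = True
        run_start = k
    return walking


def classify_sample(theta: float, walking: bool, thresholds: PostureThresholds | None = None) -> str:
    """Posture label for a single sample."""
    thresholds = thresholds or PostureThresholds()
    if not -180 <= theta <= 180:
        raise ValueError("theta must lie in [-180, 180]")
    upright = thresholds.prone_upright <= theta <= thresholds.upright_supine
    if upright:
        return WALKING if walking else SITTING
    return RECLINING


def classify_samples(
    thetas: np.ndarray, walking: np.ndarray, thresholds: PostureThresholds | None = None
) -> np.ndarray:
    """Vectorised :func:`classify_sample`; NaN angles yield the empty label ''."""
    thresholds = thresholds or PostureThresholds()
    thetas = np.asarray(thetas, dtype=float)
    upright = (thetas >= thresholds.prone_upright) & (thetas <= thresholds.upright_supine)
    out = np.where(upright, np.where(walking, WALKING, SITTING), RECLINING)
    out = np.where(np.isnan(thetas), "", out).astype(object)
    return out


def classify_day(
    accel: AccelSeries,
    grid: EpochGrid | None = None,
    thresholds: PostureThresholds | None = None,
    rule: WalkingRule | None = None,
    min_fraction: float = 0.5,
) -> PostureDaySeries:
    """Classify an acceleration day into per-epoch posture labels.

    Sample labels are aggregated per epoch by plurality; ties are broken
    by specificity (walking > sitting_or_standing > reclining).  Epochs
    failing :func:`flag_missing_epochs`, or with no valid samples, are
    labelled missing.
    """
    grid = grid or EpochGrid()
    thresholds = thresholds or PostureThresholds()
    rule = rule or WalkingRule()

    angles = trunk_angle_series(accel).angles
    walking = detect_walking(accel, rule)
    sample_labels = classify_samples(angles, walking, thresholds)

    idx = grid.epoch_index(accel.data["t"])
    n_epochs = grid.epochs_per_day
    # tie priority: most specific activity wins
    priority = (WALKING, SITTING, RECLINING)
    counts = np.zeros((n_epochs, len(priority)), dtype=int)
    valid = sample_labels != ""
    for j, lab in enumerate(priority):
        counts[:, j] = np.bincount(idx[valid & (sample_labels == lab)], minlength=n_epochs)

    labels = np.array(priority, dtype=object)[np.argmax(counts, axis=1)]
    missing = flag_missing_epochs(accel, grid, min_fraction) | (counts.sum(axis=1) == 0)
    labels[missing] = MISSING
    return PostureDaySeries(day_id=accel.day_id, grid=grid, labels=labels)


@dataclass
class AngleHistogram:
    """Occurrence histogram of trunk angles over [-180, 180] degrees."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"bin_center": self.bin_centers, "count": self.counts}).to_csv(
            path, index=False
        )


def build_angle_histogram(series, bin_width: float = 1.0) -> AngleHistogram:
    """Histogram of trunk-angle occurrences pooled over day series.

    ``series`` is a :class:`TrunkAngleSeries`, an array of angles, or a
    list of either.  NaN angles are dropped; at least one finite angle
    is required.
    """
    if not isinstance(series, (list, tuple)):
        series = [series]
    arrays = [s.angles if isinstance(s, TrunkAngleSeries) else np.asarray(s, float) for s in series]
    if not arrays:
        raise EmptyInputError("no angle data")
    angles = np.concatenate([a.ravel() for a in arrays])
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        raise EmptyInputError("no finite angles to histogram")
    n_bins = int(round(360.0 / bin_width))
    if n_bins < 1 or not np.isclose(n_bins * bin_width, 360.0):
        raise ValueError("bin_width must divide 360 degrees")
    counts, edges = np.histogram(angles, bins=n_bins, range=(-180.0, 180.0))
    return AngleHistogram(bin_edges=edges, counts=counts)


def estimate_thresholds(
    hist: AngleHistogram,
    search_low: tuple[float, float] = (15.0, 60.0),
    search_high: tuple[float, float] = (120.0, 165.0),
    smooth_window: int = 5,
) -> PostureThresholds:
    """Estimate posture thresholds from valleys of the angle histogram.

    Each threshold is the center of the minimum-count bin of the
    smoothed histogram within its search range (ties resolved to the
    lowest angle).  A flat histogram within a range yields the range
    midpoint with a warning.  The default search ranges bracket the
    canonical 35 deg / 143 deg boundaries with margin.
    """
    if search_low[0] >= search_low[1] or search_high[0] >= search_high[1]:
        raise ValueError("search ranges must be ordered (low, high)")
    if search_low[1] > search_high[0]:
        raise ValueError("search ranges must be disjoint and ordered")
    if hist.counts.sum() == 0:
        raise EmptyInputError("histogram is empty")

    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(hist.counts.astype(float), kernel, mode="same")
    centers = hist.bin_centers

    def valley(lo: float, hi: float) -> float:
        mask = (centers >= lo) & (centers <= hi)
        if not mask.any():
            raise ValueError(f"search range ({lo}, {hi}) contains no bins")
        sub = smoothed[mask]
        if np.allclose(sub, sub[0]):
            warnings.warn(
                f"flat histogram in search range ({lo}, {hi}); using its midpoint",
                stacklevel=3,
            )
            return 0.5 * (lo + hi)
        return float(centers[mask][np.argmin(sub)])

    return PostureThresholds(
        prone_upright=valley(*search_low), upright_supine=valley(*search_high)
    )
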