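"""Ensemble averaging across measurement days.

The imputation pools the same time of day across the N days of a
measurement session.  For a categorical posture series the
ensemble-averaged *period* of posture i at epoch t is

    P_i(t) = N_i(t) / (f * N(t))

where N_i(t) is the number of valid days showing posture i at t, N(t)
the number of valid (non-missing) days at t, and f the posture sampling
rate (1/epoch).  P_i is reported in minutes, so at the default 1-min
epoch P_i(t) is simply the fraction of valid days in posture i.  An
epoch is unimputable only when every day is missing there — which is
why the residual missing rate after ensembling is the size of the
intersection of the per-day missing sets.

The same averaging applies to quantitative series (heart rate): the
per-epoch mean over valid days, passing a single valid day's value
through unchanged.

Daily totals integrate the period series over the 24-h grid:
T_i = sum_t P_i(t) over epochs with N(t) >= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sensor_io import (
    MISSING,
    POSTURES,
    RECLINING,
    SITTING,
    WALKING,
    EmptyInputError,
    EpochGrid,
    GridMismatchError,
    PostureDaySeries,
)

__all__ = [
    "CategoricalEnsemble",
    "QuantitativeEnsemble",
    "DailyTotals",
    "ensemble_categorical",
    "ensemble_quantitative",
    "total_periods",
    "conventional_select_day",
    "missing_rate",
]

#: Tie-break priority for hard labels: most specific activity wins.
HARD_LABEL_PRIORITY = (WALKING, SITTING, RECLINING)


@dataclass
class CategoricalEnsemble:
    """Ensemble-averaged posture periods on the 24-h epoch grid.

    Attributes
    ----------
    n_valid : (E,) int array
        N(t), valid-day count per epoch.
    counts : (E, 3) int array
        N_i(t) per posture, columns ordered as :data:`POSTURES`.
    periods_min : (E, 3) float array
        P_i(t) in minutes; NaN where N(t) = 0 (unimputable epoch).
    """

    grid: EpochGrid
    n_total: int
    n_valid: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    periods_min: np.ndarray = field(repr=False)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.n_valid == 0

    def hard_labels(self) -> np.ndarray:
        """Single label per epoch: argmax_i N_i(t), ties by priority
        walking > sitting_or_standing > reclining; missing where N(t)=0."""
        order = [POSTURES.index(lab) for lab in HARD_LABEL_PRIORITY]
        winner = np.argmax(self.counts[:, order], axis=1)
        labels = np.array(HARD_LABEL_PRIORITY, dtype=object)[winner]
        labels[self.missing_mask] = MISSING
        return labels

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.periods_min, columns=[f"P_{lab}" for lab in POSTURES]
        )
        df.insert(0, "epoch_start", self.grid.epoch_start_strings())
        df["N_valid_days"] = self.n_valid
        return df

    def to_csv(self, path) -> None:
        """Ensemble CSV; unimputable epochs are written with empty P fields."""
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


@dataclass
class QuantitativeEnsemble:
    """Ensemble-averaged quantitative series (e.g. heart rate)."""

    grid: EpochGrid
    values: np.ndarray = field(repr=False)
    n_valid: np.ndarray = field(repr=False)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.n_valid == 0


@dataclass
class DailyTotals:
    """Total period of each posture over 24 h, in minutes."""

    minutes: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.minutes.values()))

    @property
    def ratios(self) -> dict[str, float]:
        """Period ratios over the total measured period (sum of T_i)."""
        tot = self.total
        if tot == 0:
            return {lab: float("nan") for lab in self.minutes}
        return {lab: v / tot for lab, v in self.minutes.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "posture": list(self.minutes),
                "minutes": list(self.minutes.values()),
                "ratio": list(self.ratios.values()),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def _check_common_grid(days: list[PostureDaySeries]) -> EpochGrid:
    if not days:
        raise EmptyInputError("at least one day series is required")
    grid = days[0].grid
    if any(d.grid != grid for d in days[1:]):
        raise GridMismatchError("all day series must share one epoch grid")
    return grid


def ensemble_categorical(days: list[PostureDaySeries]) -> CategoricalEnsemble:
    """Categorical ensemble average of posture day series.

    Per epoch, counts days per posture among non-missing days and forms
    P_i(t) = N_i(t)/(f N(t)).  Epochs missing on all days remain
    missing in the output (NaN periods).
    """
    grid = _check_common_grid(days)
    labels = np.stack([d.labels for d in days])  # (D, E)
    counts = np.stack([(labels == lab).sum(axis=0) for lab in POSTURES], axis=1)
    n_valid = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        periods = grid.epoch_minutes * counts / n_valid[:, None]
    periods[n_valid == 0] = np.nan
    return CategoricalEnsemble(
        grid=grid,
        n_total=len(days),
        n_valid=n_valid,
        counts=counts,
        periods_min=periods,
    )


def ensemble_quantitative(
    day_values: list[np.ndarray], grid: EpochGrid | None = None
) -> QuantitativeEnsemble:
    """Quantitative ensemble average (per-epoch mean over valid days).

    ``day_values`` are per-epoch arrays with NaN marking missing
    epochs.  Epochs valid on a single day pass that day's value through
    unchanged; epochs missing on all days stay NaN.
    """
    if not day_values:
        raise EmptyInputError("at least one day series is required")
    values = np.stack([np.asarray(v, dtype=float) for v in day_values])
    if grid is not None and values.shape[1] != grid.epochs_per_day:
        raise GridMismatchError("day length does not match the epoch grid")
    grid = grid or EpochGrid(epoch_length=86400 // values.shape[1])
    n_valid = np.sum(np.isfinite(values), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=0)
    return QuantitativeEnsemble(grid=grid, values=mean, n_valid=n_valid)


def total_periods(ens: CategoricalEnsemble) -> DailyTotals:
    """Daily totals T_i = sum_t P_i(t) over imputable epochs, minutes.

    Unimputable (all-days-missing) epochs are excluded, not
    redistributed, so sum_i T_i equals the epoch length times the
    number of imputable epochs.
    """
    totals = np.nansum(ens.periods_min, axis=0)
    return DailyTotals(minutes={lab: float(t) for lab, t in zip(POSTURES, totals)})


def conventional_select_day(days: list[PostureDaySeries]) -> PostureDaySeries:
    """Baseline imputation: keep the day with the fewest missing epochs.

    Ties go to the earliest day in the list.
    """
    if not days:
        raise EmptyInputError("at least one day series is required")
    _check_common_grid(days)
    return days[int(np.argmin([d.n_missing for d in days]))]


def missing_rate(obj) -> float:
    """Missing-data rate as a percentage of the 24-h epoch grid.

    Accepts a :class:`PostureDaySeries` (per-day rate), a
    :class:`CategoricalEnsemble` or :class:`QuantitativeEnsemble`
    (post-imputation rate), or a list of day series — the
    reference-without-imputation rate of a multi-day session, taken as
    the mean of the per-day rates.
    """
    if isinstance(obj, PostureDaySeries):
        return 100.0 * obj.n_missing / obj.grid.epochs_per_day
    if isinstance(obj, (CategoricalEnsemble, QuantitativeEnsemble)):
        return 100.0 * float(obj.missing_mask.sum()) / obj.grid.epochs_per_day
    if isinstance(obj, (list, tuple)):
        if not obj:
            raise EmptyInputError("empty session")
        return float(np.mean([missing_rate(d) for d in obj]))
    raise TypeError(f"missing_rate does not accept {type(obj).__name__}")
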