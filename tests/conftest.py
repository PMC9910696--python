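import numpy as np
import pytest

from posture_ensemble import (
    MISSING,
    RECLINING,
    SITTING,
    WALKING,
    EpochGrid,
    PostureDaySeries,
)

R, S, W, M = RECLINING, SITTING, WALKING, MISSING


@pytest.fixture
def minute_grid():
    """The default 1-min epoch grid (1440 epochs/day)."""
    return EpochGrid(60)


@pytest.fixture
def toy_grid():
    """10-epoch toy grid for hand-checkable cases."""
    return EpochGrid(8640)


def make_day(grid, labels, day_id="day", fill=RECLINING):
    """Build a PostureDaySeries from a partial label list, padding with ``fill``."""
    full = np.array([fill] * grid.epochs_per_day, dtype=object)
    full[: len(labels)] = labels
    return PostureDaySeries(day_id=day_id, grid=grid, labels=full)


@pytest.fixture
def worked_example_days(minute_grid):
    """Five 1-min-epoch days realising the hand-worked ensemble cases:

    epoch 5 — no loss, day labels (R, S, S, W, W), N(t)=5;
    epoch 6 — two days lost, remaining labels (S, S, W), N(t)=3.
    """
    at_5 = [R, S, S, W, W]
    at_6 = [M, M, S, S, W]
    days = []
    for d in range(5):
        labels = np.array([R] * minute_grid.epochs_per_day, dtype=object)
        labels[5] = at_5[d]
        labels[6] = at_6[d]
        days.append(PostureDaySeries(f"day{d + 1}", minute_grid, labels))
    return days


def random_labels(rng, n_epochs, p_missing=0.15):
    """Random label vector over the closed label set."""
    choices = np.array([R, S, W, M], dtype=object)
    probs = [(1 - p_missing) * 0.5, (1 - p_missing) * 0.35, (1 - p_missing) * 0.15, p_missing]
    return rng.choice(choices, size=n_epochs, p=probs)
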