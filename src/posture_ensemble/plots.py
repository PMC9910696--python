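"""24-h activity visualisations.

Two report styles: a population view stacking, per time of day, the
fraction of sessions in each posture (missing excluded, so the stack
sums to at most 1), and a per-individual multi-week view of
ensemble-averaged posture periods with a totals-ratio bar chart.
"""

from __future__ import annotations

import numpy as np

from .sensor_io import POSTURES
from .ensemble import CategoricalEnsemble, total_periods

__all__ = ["plot_population_24h", "plot_individual_weeks", "population_ratios"]

_COLORS = {POSTURES[0]: "#9467bd", POSTURES[1]: "#2ca02c", POSTURES[2]: "#ff7f0e"}


def population_ratios(ensembles: list[CategoricalEnsemble]) -> dict[str, np.ndarray]:
    """Per-epoch population ratio of each posture over the hard-label
    views of the inputs; 1 represents the total number of inputs."""
    if not ensembles:
        raise ValueError("at least one ensemble is required")
    hard = np.stack([e.hard_labels() for e in ensembles])
    return {lab: (hard == lab).mean(axis=0) for lab in POSTURES}


def _hours_axis(grid) -> np.ndarray:
    return (np.arange(grid.epochs_per_day) + 0.5) * grid.epoch_length / 3600.0


def plot_population_24h(ensembles: list[CategoricalEnsemble], path) -> None:
    """Stacked time-of-day posture population ratios, written to ``path``."""
    import matplotlib.pyplot as plt

    ratios = population_ratios(ensembles)
    hours = _hours_axis(ensembles[0].grid)
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.stackplot(
        hours,
        [ratios[lab] for lab in POSTURES],
        labels=list(POSTURES),
        colors=[_COLORS[lab] for lab in POSTURES],
    )
    ax.set_xlim(0, 24)
    ax.set_ylim(0, 1)
    ax.set_xticks(range(0, 25, 3))
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("population ratio")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_individual_weeks(week_ensembles: list[CategoricalEnsemble], path) -> None:
    """Per-week 24-h posture-period panels plus a totals-ratio bar chart."""
    import matplotlib.pyplot as plt

    if not week_ensembles:
        raise ValueError("at least one week is required")
    n = len(week_ensembles)
    fig, axes = plt.subplots(n + 1, 1, figsize=(9, 2.2 * (n + 1)), squeeze=False)
    for w, ens in enumerate(week_ensembles):
        ax = axes[w, 0]
        hours = _hours_axis(ens.grid)
        epoch_min = ens.grid.epoch_minutes
        fractions = [np.nan_to_num(ens.periods_min[:, j] / epoch_min) for j in range(len(POSTURES))]
        ax.stackplot(hours, fractions, colors=[_COLORS[lab] for lab in POSTURES])
        ax.set_xlim(0, 24)
        ax.set_ylim(0, 1)
        ax.set_ylabel(f"week {w + 1}")
    axes[n - 1, 0].set_xlabel("time of day (h)")

    ax = axes[n, 0]
    width = 0.8 / len(POSTURES)
    for j, lab in enumerate(POSTURES):
        vals = [total_periods(e).ratios[lab] for e in week_ensembles]
        ax.bar(
            np.arange(n) + (j - 1) * width, vals, width=width, color=_COLORS[lab], label=lab
        )
    ax.set_xticks(range(n), [f"wk {w + 1}" for w in range(n)])
    ax.set_ylabel("ratio of total period")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
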