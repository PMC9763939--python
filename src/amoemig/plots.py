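"""Best-effort plotting conveniences; the CSV tables are the contract."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import AggregatedCurve

__all__ = ["plot_aggregated_curves", "superplot"]


def plot_aggregated_curves(
    curves: Mapping[str, AggregatedCurve],
    ylabel: str,
    xlabel: str = "time (s)",
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Mean +/- SD band per condition (CR decay or MSD style)."""
    if ax is None:
        _, ax = plt.subplots()
    for cond, agg in curves.items():
        ax.plot(agg.abscissa, agg.mean_of_replicates, label=cond)
        ax.fill_between(
            agg.abscissa,
            agg.mean_of_replicates - agg.sd_of_replicates,
            agg.mean_of_replicates + agg.sd_of_replicates,
            alpha=0.25,
        )
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax


def superplot(
    values: Mapping[str, Mapping[str, Sequence[float]]],
    ylabel: str,
    ax: plt.Axes | None = None,
    rng: np.random.Generator | None = None,
) -> plt.Axes:
    """SuperPlot-style scatter: cells jittered per condition, replicate
    medians overlaid as large circles, mean +/- SD of medians as a bar."""
    if ax is None:
        _, ax = plt.subplots()
    rng = rng or np.random.default_rng(0)
    for i, (cond, reps) in enumerate(values.items()):
        medians = []
        for j, (rep, vals) in enumerate(reps.items()):
            vals = np.asarray(list(vals), dtype=float)
            x = i + rng.uniform(-0.25, 0.25, size=len(vals))
            ax.scatter(x, vals, s=8, alpha=0.4, color=f"C{j}")
            medians.append(np.median(vals))
            ax.scatter([i], [medians[-1]], s=60, color=f"C{j}",
                       edgecolor="black", zorder=3)
        m, s = np.mean(medians), np.std(medians, ddof=1) if len(medians) > 1 else 0.0
        ax.errorbar([i + 0.35], [m], yerr=[s], fmt="_", color="black",
                    capsize=4, zorder=4)
    ax.set_xticks(range(len(values)))
    ax.set_xticklabels(list(values))
    ax.set_ylabel(ylabel)
    return ax
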