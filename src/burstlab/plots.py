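"""Plotting helpers: count histograms and size-binned dosage curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_count_histograms(samples: dict[str, np.ndarray], ax=None, density=True):
    """Overlaid integer-count histograms, one per labelled sample."""
    if ax is None:
        _, ax = plt.subplots()
    kmax = max(int(np.max(s)) for s in samples.values() if len(s))
    bins = np.arange(-0.5, kmax + 1.5)
    for label, sample in samples.items():
        ax.hist(sample, bins=bins, density=density, alpha=0.5, label=label)
    ax.set_xlabel("molecules per cell")
    ax.set_ylabel("frequency" if density else "cells")
    ax.legend()
    return ax


def plot_size_binned(binned: pd.DataFrame, ax=None):
    """Mean +- sem per cell-size bin with the 3-bin moving average."""
    if ax is None:
        _, ax = plt.subplots()
    occupied = binned[binned["n"] > 0]
    ax.errorbar(
        occupied["bin_center"], occupied["mean"], yerr=occupied["sem"],
        fmt="o", color="k", capsize=2,
    )
    ax.plot(occupied["bin_center"], occupied["moving_average"], "-", color="tab:red")
    ax.set_xlabel("cell area (µm$^2$)")
    ax.set_ylabel("mean molecules per cell")
    return ax


def save_figure(ax, path) -> None:
    ax.figure.savefig(path, bbox_inches="tight")
    plt.close(ax.figure)
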