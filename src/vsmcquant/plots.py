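"""Histogram and box-plot figures for pipeline reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_histogram", "plot_box_pair"]


def plot_histogram(samples, title: str, xlabel: str, path, bins: int = 30) -> None:
    samples = np.asarray(samples, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    if samples.size:
        ax.hist(samples, bins=bins, color="tab:blue", edgecolor="black", linewidth=0.4)
    ax.set_title(title)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_box_pair(control, drug, title: str, ylabel: str, path) -> None:
    fig, ax = plt.subplots(figsize=(3.2, 3))
    ax.boxplot(
        [np.asarray(control, float), np.asarray(drug, float)],
        tick_labels=["control", "drug"],
        whis=(10, 90),
        showfliers=False,
    )
    ax.set_title(title)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
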