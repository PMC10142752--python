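"""Figure exports: marker density curves with cutoffs, t-SNE scatters,
correlation heatmaps, and group-comparison bar charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import MARKERS
from .phenotype import ThresholdSet
from .stats import CorrelationMatrix


def _save(fig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_marker_densities(
    cells: pd.DataFrame, thresholds: ThresholdSet | None, path: str | Path
) -> None:
    """Pooled log-intensity density per marker with the fitted cutoff."""
    fig, axes = plt.subplots(1, len(MARKERS), figsize=(4 * len(MARKERS), 3))
    for ax, m in zip(np.atleast_1d(axes), MARKERS):
        x = np.log(cells[m].to_numpy())
        ax.hist(x, bins=80, density=True, color="0.6")
        if thresholds and m in thresholds:
            ax.axvline(np.log(thresholds[m].cutoff), color="crimson", lw=1.5)
        ax.set_title(m)
        ax.set_xlabel("log mean intensity")
    _save(fig, path)


def plot_tsne(cells: pd.DataFrame, colour_by: str, path: str | Path) -> None:
    """t-SNE scatter coloured by cluster, group, or an MOI^high flag."""
    fig, ax = plt.subplots(figsize=(6, 6))
    vals = cells[colour_by]
    if vals.dtype == bool:
        vals = vals.astype(int)
    if vals.dtype == object:
        codes = pd.Categorical(vals).codes
    else:
        codes = vals
    ax.scatter(cells["tsne_x"], cells["tsne_y"], c=codes, s=3, cmap="tab20", lw=0)
    ax.set_title(f"t-SNE coloured by {colour_by}")
    ax.set_xticks([])
    ax.set_yticks([])
    _save(fig, path)


def plot_correlation_heatmap(cm: CorrelationMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(0.6 * len(cm.variables) + 2,) * 2)
    im = ax.imshow(cm.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cm.variables)), cm.variables, rotation=90)
    ax.set_yticks(range(len(cm.variables)), cm.variables)
    fig.colorbar(im, ax=ax, label="Spearman r")
    _save(fig, path)


def plot_group_bars(
    comparisons: pd.DataFrame, region: str, path: str | Path
) -> None:
    """Per-endpoint group medians with raw-p stars for one region."""
    sub = comparisons[comparisons["region"] == region]
    med_cols = [c for c in sub.columns if c.startswith("median_")]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(sub)), 4))
    x = np.arange(len(sub))
    w = 0.35
    for off, c in zip((-w / 2, w / 2), med_cols):
        ax.bar(x + off, sub[c], width=w, label=c.removeprefix("median_"))
    for xi, (_, row) in zip(x, sub.iterrows()):
        if row["stars_raw_p"] != "ns":
            ax.text(xi, max(row[c] for c in med_cols) * 1.02, row["stars_raw_p"],
                    ha="center")
    ax.set_xticks(x, sub["endpoint"], rotation=45, ha="right")
    ax.set_title(region)
    ax.legend()
    _save(fig, path)
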