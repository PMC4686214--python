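"""Rank-order summary plots and the per-replicate heat map.

Plots are written both as vector images and as the underlying point tables,
so every rendered number can be re-derived from a TSV.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .quantify import heat_bin

__all__ = ["rank_plot_data", "heatmap_matrix", "plot_rank_series", "plot_heatmap", "HEAT_COLORS"]

HEAT_COLORS: Dict[str, str] = {
    "bright_green": "#00cc00",
    "dark_green": "#1a6b1a",
    "grey": "#9e9e9e",
    "dark_red": "#8b1a1a",
    "bright_red": "#e60000",
    "white": "#ffffff",
}


def rank_plot_data(merged: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Rank-ordered per-replicate ratios, one series per condition.

    ``merged`` holds one capped, form-merged value per (peptide, condition,
    replicate).  Each test condition becomes a series of its replicate ratios
    sorted ascending; the reference condition's self-ratios form their own
    series (they hover around 1 by construction).  Capped values sit exactly
    at the cap.  Intended for log-scale y rendering.
    """
    frames = []
    for condition, sub in merged.groupby("condition", sort=True):
        vals = np.sort(sub["ratio"].dropna().to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "series": condition,
                    "is_reference": condition == reference,
                    "rank": np.arange(1, vals.size + 1),
                    "ratio": vals,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["series", "is_reference", "rank", "ratio"])
    return pd.concat(frames, ignore_index=True)


def heatmap_matrix(
    merged: pd.DataFrame,
    peptide_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Peptide × (condition, replicate) matrix of merged ratios and heat bins.

    Rows are peptides, columns are replicate sub-columns grouped by condition
    (experiment).  Cells without a value are white (peptide undetected or all
    forms overlap-flagged in that replicate).
    """
    wide = merged.pivot_table(
        index="peptide_id",
        columns=["condition", "replicate"],
        values="ratio",
        aggfunc="mean",
    )
    if peptide_order is not None:
        wide = wide.reindex([p for p in peptide_order if p in wide.index])
    bins = wide.map(heat_bin)
    out = pd.concat({"ratio": wide, "bin": bins}, axis=1)
    return out


def plot_rank_series(rank_data: pd.DataFrame, path, title: str = "") -> None:
    """Scatter of rank-ordered ratios per series, log-scale y."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for series, sub in rank_data.groupby("series", sort=True):
        ref = bool(sub["is_reference"].iloc[0])
        ax.scatter(
            sub["rank"],
            sub["ratio"],
            s=8,
            color="black" if ref else "tab:red",
            label=f"{series}{' (reference)' if ref else ''}",
        )
    ax.set_yscale("log")
    ax.axhline(1.0, lw=0.5, color="grey")
    ax.set_xlabel("rank order of peptide replicates")
    ax.set_ylabel("relative peptide level")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    """Color-coded replicate heat map from :func:`heatmap_matrix` output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    bins = matrix["bin"]
    order = list(HEAT_COLORS)
    cmap = ListedColormap([HEAT_COLORS[b] for b in order])
    codes = bins.apply(lambda col: col.map({b: i for i, b in enumerate(order)})).to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * codes.shape[1]), max(3, 0.14 * codes.shape[0])))
    ax.imshow(codes, aspect="auto", cmap=cmap, vmin=0, vmax=len(order) - 1, interpolation="nearest")
    ax.set_xticks(range(codes.shape[1]))
    ax.set_xticklabels(["/".join(map(str, c)) for c in bins.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(codes.shape[0]))
    ax.set_yticklabels(bins.index, fontsize=5)
    ax.set_xlabel("experiment / replicate")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
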