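"""Minimal figure exports: replicate χ² scatter and R² heat map (SVG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_replicate_chi2(
    screen: pd.DataFrame, path: str | Path, highlight: list[str] | None = None
) -> None:
    """Scatter of per-protein χ² in replicate 2 vs replicate 1."""
    chi_cols = [c for c in screen.columns if c.startswith("chi2_")]
    if len(chi_cols) < 2:
        raise ValueError("need two replicate chi2 columns to plot")
    x, y = screen[chi_cols[0]], screen[chi_cols[1]]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=12, c="0.6", edgecolors="none")
    for name in highlight or []:
        if name in screen.index:
            ax.scatter(x[name], y[name], s=28, c="tab:red")
            ax.annotate(name, (x[name], y[name]), fontsize=8)
    ax.set_xlabel(f"χ² {chi_cols[0][5:]}")
    ax.set_ylabel(f"χ² {chi_cols[1][5:]}")
    ax.set_xscale("symlog", linthresh=0.01)
    ax.set_yscale("symlog", linthresh=0.01)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_r2_heatmap(r2_ordered: pd.DataFrame, path: str | Path) -> None:
    """Heat map of the clustered R² matrix (rows already ordered)."""
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.35 * r2_ordered.shape[1], 1.5 + 0.16 * r2_ordered.shape[0])
    )
    im = ax.imshow(r2_ordered.to_numpy(dtype=float), aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=1.0)
    ax.set_xticks(range(r2_ordered.shape[1]), r2_ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(r2_ordered.shape[0]), r2_ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="R²", shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
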