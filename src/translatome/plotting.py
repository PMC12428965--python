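"""Figure helpers: PCA overview, Jaccard / module-trait heatmaps, UpSet bars,
enrichment heatmaps.  All functions write a PNG and return the path."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_pca(coords: pd.DataFrame, ss: pd.DataFrame, path: str | Path) -> Path:
    """Scatter of PC1/PC2 coloured by fraction, marked by condition."""
    ann = ss.set_index("sample_id")
    fig, ax = plt.subplots(figsize=(6, 5))
    colours = {"total": "tab:orange", "polysome": "tab:green"}
    markers = {"Control": "o", "Hardening": "s", "Stress": "^", "Combo": "D"}
    for sample in coords.index:
        frac = ann.at[sample, "fraction"]
        cond = ann.at[sample, "condition"]
        ax.scatter(
            coords.at[sample, "PC1"],
            coords.at[sample, "PC2"],
            c=colours.get(frac, "grey"),
            marker=markers.get(cond, "x"),
            s=50,
            edgecolor="black",
            linewidth=0.5,
        )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("Sample overview (colour: fraction, marker: condition)")
    return _save(fig, path)


def plot_heatmap(
    matrix: pd.DataFrame,
    path: str | Path,
    title: str = "",
    annotate: pd.DataFrame | None = None,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
) -> Path:
    """Generic annotated heatmap (used for Jaccard and enrichment tables)."""
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.5 * matrix.shape[0])
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    if annotate is not None:
        for i in range(matrix.shape[0]):
            for j in range(matrix.shape[1]):
                ax.text(
                    j, i, str(annotate.iat[i, j]), ha="center", va="center",
                    fontsize=6, color="white",
                )
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    return _save(fig, path)


def plot_module_trait(mt: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Module x trait heatmap of correlations with p-values in brackets."""
    r = mt.pivot(index="module", columns="trait", values="r")
    p = mt.pivot(index="module", columns="trait", values="p_value")
    labels = r.copy().astype(object)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            labels.iat[i, j] = f"{r.iat[i, j]:.2f}\n({p.iat[i, j]:.2g})"
    return plot_heatmap(
        r, path, title=title, annotate=labels, cmap="RdBu_r", vmin=-1, vmax=1
    )


def plot_upset(regions: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Bar chart of exclusive intersection sizes with a membership matrix."""
    set_names = [c for c in regions.columns if c != "size"]
    n = len(regions)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(6, 0.35 * n), 6),
        gridspec_kw={"height_ratios": [3, 1]}, sharex=True,
    )
    ax_bar.bar(range(n), regions["size"], color="tab:blue")
    ax_bar.set_ylabel("exclusive size")
    ax_bar.set_title(title, fontsize=9)
    for j, name in enumerate(set_names):
        member = regions[name].to_numpy(dtype=bool)
        ys = np.full(n, j, dtype=float)
        ax_dot.scatter(
            np.arange(n)[member], ys[member], c="black", s=12, zorder=3
        )
        ax_dot.scatter(
            np.arange(n)[~member], ys[~member], c="lightgrey", s=12, zorder=2
        )
    ax_dot.set_yticks(range(len(set_names)), set_names, fontsize=7)
    ax_dot.set_xticks([])
    ax_dot.invert_yaxis()
    return _save(fig, path)
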