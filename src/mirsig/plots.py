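"""Optional figure rendering: expression heatmap and qPCR boxplots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .array_io import ExpressionMatrix


def expression_heatmap(matrix: ExpressionMatrix, path: Path | str,
                       log: bool = True) -> None:
    """Clustered miRNA x sample heatmap of normalized intensities."""
    vals = matrix.values.astype(float)
    data = np.log10(vals + 1.0) if log else vals.to_numpy()
    data = np.asarray(data)
    if data.shape[0] > 2:
        order = hierarchy.leaves_list(
            hierarchy.linkage(pdist(data), method="average"))
    else:
        order = np.arange(data.shape[0])
    # keep groups contiguous on the x axis
    cols = (matrix.samples_in_group("FM") + matrix.samples_in_group("control"))
    col_pos = [list(vals.columns).index(c) for c in cols]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(cols)), max(4, 0.02 * data.shape[0])))
    im = ax.imshow(data[np.ix_(order, col_pos)], aspect="auto",
                   cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(cols, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{data.shape[0]} miRNAs")
    fig.colorbar(im, ax=ax,
                 label="log10(signal + 1)" if log else "signal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qpcr_boxplots(rel_expr: pd.DataFrame, groups: Mapping[str, str],
                  path: Path | str, log: bool = False) -> None:
    """Per-miRNA boxplots of relative expression (2^-dCt), FM vs control."""
    df = rel_expr.copy()
    df["group"] = df["sample_id"].map(dict(groups))
    mirnas = sorted(df["mirna_id"].unique())
    ncol = min(4, len(mirnas))
    nrow = int(np.ceil(len(mirnas) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow),
                             squeeze=False)
    for k, mirna in enumerate(mirnas):
        ax = axes[k // ncol][k % ncol]
        sub = df[df["mirna_id"] == mirna]
        data = [sub.loc[sub["group"] == g, "rel_expr"].to_numpy()
                for g in ("control", "FM")]
        ax.boxplot(data, tick_labels=["control", "FM"])
        if log:
            ax.set_yscale("log")
        ax.set_title(mirna, fontsize=8)
    for k in range(len(mirnas), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
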