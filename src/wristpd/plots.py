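"""Matplotlib renderings of the analysis outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def correlation_heatmap(matrix: pd.DataFrame, path: str | Path,
                        title: str = "|r| between features and MDS-UPDRS items") -> None:
    """Absolute-correlation heat map, features on rows, exercises on columns."""
    fig, ax = plt.subplots(figsize=(1.2 * len(matrix.columns) + 3,
                                    0.35 * len(matrix) + 2))
    data = matrix.to_numpy(dtype=float)
    im = ax.imshow(np.abs(data), cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), [f"ex{c}" for c in matrix.columns])
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if np.isfinite(data[i, j]):
                ax.text(j, i, f"{abs(data[i, j]):.2f}", ha="center", va="center",
                        color="w", fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="|r|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embedding_scatter(coords: pd.DataFrame, path: str | Path,
                      title: str = "t-SNE of windowed features") -> None:
    """2-D embedding brushed by clinical score (0-4)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    score = coords["score"].to_numpy(dtype=float)
    sc = ax.scatter(coords["dim1"], coords["dim2"], c=score, cmap="plasma",
                    vmin=0, vmax=4, s=12, alpha=0.8)
    fig.colorbar(sc, ax=ax, label="MDS-UPDRS score")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
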