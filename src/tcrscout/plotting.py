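"""Scatter panels over the UMAP embedding (marker overlays, clusters)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .embedding import DEFAULT_MARKERS, EmbeddingResult


def plot_embedding_panels(
    result: EmbeddingResult,
    norm: np.ndarray,
    gene_ids: list[str],
    path: str | Path,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
) -> None:
    """One panel per marker plus a cluster panel, saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    panels = [m for m in markers if m in gene_index] + ["cluster"]
    ncols = 3
    nrows = -(-len(panels) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.5 * nrows), squeeze=False)
    x, y = result.umap_coords[:, 0], result.umap_coords[:, 1]
    for ax, panel in zip(axes.flat, panels):
        if panel == "cluster":
            sc = ax.scatter(x, y, c=result.cluster_labels, s=6, cmap="tab10")
        else:
            sc = ax.scatter(x, y, c=norm[:, gene_index[panel]], s=6, cmap="viridis")
            fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_title(panel)
        ax.set_xticks([])
        ax.set_yticks([])
    for ax in axes.flat[len(panels):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
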