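"""Static heatmap of the clustered matrix (protein rows ordered by protein
cluster, sample columns by class)."""

from __future__ import annotations

import numpy as np

from .matrix import IntensityMatrix


def plot_heatmap(
    m: IntensityMatrix,
    classes: np.ndarray,
    protein_clusters: np.ndarray | None = None,
    path=None,
):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = m.to_array()
    z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
    col_order = np.argsort(classes, kind="stable")
    row_order = (np.argsort(protein_clusters, kind="stable")
                 if protein_clusters is not None else np.arange(arr.shape[0]))
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(z[np.ix_(row_order, col_order)], aspect="auto",
                   cmap="RdBu_r", vmin=-3, vmax=3, interpolation="nearest")
    ax.set_xlabel("samples (ordered by class)")
    ax.set_ylabel("proteins (ordered by protein cluster)")
    fig.colorbar(im, ax=ax, label="row z-score")
    # class boundaries
    sorted_classes = np.asarray(classes)[col_order]
    for b in np.where(np.diff(sorted_classes) != 0)[0]:
        ax.axvline(b + 0.5, color="black", lw=0.8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
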