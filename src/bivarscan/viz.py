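"""Diagnostic graphics for the bivariate screen.

Three plot families, each emitted as a vector/raster figure *plus* a TSV
sidecar holding the exact plotted numbers, so figures are testable:

* the RGB-encoded pair-accuracy image: an n × n pixel grid over displayed
  genes where each off-diagonal pixel's (red, green, blue) channels are the
  pair's CV scores in the three cohorts — a white pixel means perfect
  accuracy in all three, a dark one a pair that separates nowhere; the
  diagonal (a gene with itself) is masked;
* the aggregate-vs-selectivity scatter of gene pairs (transferable pairs
  sit low on the selectivity axis, cohort-specific ones high);
* 2-D embeddings of one cohort's samples coloured by class (PCA is
  deterministic and tested; UMAP/t-SNE are optional conveniences).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bivariate import PairScoreTensor
from .data_io import ExpressionDataset

DIAGONAL_SENTINEL = -1.0


def rgb_pair_image(
    tensor: PairScoreTensor,
    display_genes: Sequence[str],
    channel_order: tuple[str, str, str] | None = None,
) -> np.ndarray:
    """RGB image of pair CV scores for the displayed genes.

    Returns an (n, n, 3) float array: pixel (i, j) carries the CV score of
    pair (gene_i, gene_j) in the cohorts mapped to (red, green, blue) by
    ``channel_order`` (default: tensor cohort order).  The image is
    symmetric by construction and the diagonal carries the sentinel −1.
    """
    if len(tensor.dataset_names) != 3:
        raise ValueError(
            f"RGB encoding needs exactly 3 cohorts, got {len(tensor.dataset_names)}"
        )
    order = list(channel_order) if channel_order else list(tensor.dataset_names)
    if sorted(order) != sorted(tensor.dataset_names):
        raise ValueError(f"channel_order must permute {tensor.dataset_names}")
    chan = [tensor.dataset_names.index(name) for name in order]
    genes = list(display_genes)
    missing = [g for g in genes if g not in tensor.genes]
    if missing:
        raise KeyError(f"display genes not in tensor: {missing}")

    pair_idx = {p: i for i, p in enumerate(tensor.pairs)}
    n = len(genes)
    img = np.full((n, n, 3), DIAGONAL_SENTINEL)
    for i in range(n):
        for j in range(i + 1, n):
            scores = tensor.scores[pair_idx[tuple(sorted((genes[i], genes[j])))]]
            img[i, j] = img[j, i] = scores[chan]
    return img


def plot_rgb_pair_image(
    tensor: PairScoreTensor,
    display_genes: Sequence[str],
    path: str | Path,
    channel_order: tuple[str, str, str] | None = None,
) -> Path:
    """Render the RGB pair image to ``path`` with a TSV sidecar of channels."""
    img = rgb_pair_image(tensor, display_genes, channel_order)
    genes = list(display_genes)
    shown = np.where(img == DIAGONAL_SENTINEL, 0.0, img)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(shown, interpolation="nearest")
    ax.set_xticks(range(len(genes)), genes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    order = list(channel_order) if channel_order else list(tensor.dataset_names)
    ax.set_title(
        "pair CV accuracy — R: %s, G: %s, B: %s" % tuple(order), fontsize=9
    )
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    rows = []
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            rows.append(
                {"gene_row": gi, "gene_col": gj,
                 "red": img[i, j, 0], "green": img[i, j, 1], "blue": img[i, j, 2]}
            )
    pd.DataFrame(rows).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    return path


def aggregate_selectivity_scatter(
    records: pd.DataFrame,
    path: str | Path,
    annotate_top: int = 10,
) -> Path:
    """Scatter of pair aggregate (x) vs selectivity σ (y), top pairs labelled.

    ``records`` is the table from
    :func:`bivarscan.bivariate.pair_statistics` (columns ``gene_a``,
    ``gene_b``, ``aggregate``, ``selectivity``).  The plotted coordinates
    are written unchanged to a TSV sidecar.
    """
    if records.empty:
        raise ValueError("no pair records to plot")
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(records["aggregate"], records["selectivity"], s=8, alpha=0.6)
    top = records.nlargest(min(annotate_top, len(records)), "aggregate")
    for _, row in top.iterrows():
        ax.annotate(
            f"{row['gene_a']}–{row['gene_b']}",
            (row["aggregate"], row["selectivity"]),
            fontsize=6,
        )
    ax.set_xlabel("aggregated pair score (Σ CV across cohorts)")
    ax.set_ylabel("selectivity σ = max(S²) − min(S²)")
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    records[["gene_a", "gene_b", "aggregate", "selectivity"]].to_csv(
        path.with_suffix(".tsv"), sep="\t", index=False
    )
    return path


def embedding_coordinates(
    dataset: ExpressionDataset,
    genes: Sequence[str] | None = None,
    method: str = "pca",
    seed: int = 0,
) -> pd.DataFrame:
    """2-D sample embedding of one cohort (rows: samples; cols: dim1, dim2, label).

    ``pca`` is deterministic; ``umap`` and ``tsne`` are stochastic
    (seed-controlled) and available only if their libraries are installed.
    """
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples to embed")
    X = dataset.values(list(genes) if genes is not None else None)
    X = X - X.mean(axis=0)
    if method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (dataset.n_samples - 1) / 3)
        coords = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity
        ).fit_transform(X)
    elif method == "umap":
        try:
            from umap import UMAP
        except ImportError as exc:  # pragma: no cover - env-dependent
            raise RuntimeError(
                "umap-learn is not installed; use method='pca' or 'tsne'"
            ) from exc
        coords = UMAP(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(
        {
            "dim1": coords[:, 0],
            "dim2": coords[:, 1],
            "label": dataset.labels.to_numpy(),
        },
        index=dataset.matrix.columns,
    )


def embedding_plot(
    dataset: ExpressionDataset,
    path: str | Path,
    genes: Sequence[str] | None = None,
    method: str = "pca",
    seed: int = 0,
) -> Path:
    """Render a class-coloured 2-D embedding with a TSV sidecar."""
    coords = embedding_coordinates(dataset, genes=genes, method=method, seed=seed)
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, color, name in ((0, "tab:blue", "control"), (1, "tab:red", "case")):
        sub = coords[coords["label"] == label]
        ax.scatter(sub["dim1"], sub["dim2"], s=18, c=color, label=name, alpha=0.8)
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(f"{dataset.name}: {method} embedding", fontsize=10)
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    coords.to_csv(path.with_suffix(".tsv"), sep="\t")
    return path
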