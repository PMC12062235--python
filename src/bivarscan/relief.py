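"""Relief-F gene scoring: the pipeline's filter feature-selection stage.

Relief-F weights each gene by how well it separates nearest neighbours of
opposite classes relative to neighbours of the same class.  Unlike a t-test
it is sensitive to local and distributional structure, which is why it can
retain genes whose class-conditional distributions differ without a mean
shift — exactly the genes a univariate differential-expression screen
discards.

This implementation is the deterministic full pass: every sample serves as
the target once (no random subsampling), neighbours are found by Manhattan
distance on range-scaled features, and distance ties are broken by sample
index, so the weights are a pure function of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset


@dataclass
class ReliefResult:
    """Per-gene Relief-F weights plus the induced deterministic ordering."""

    weights: pd.Series  # indexed by gene symbol
    k: int
    gene_order: list[str]  # descending weight, lexicographic tie-break

    def table(self) -> pd.DataFrame:
        """Weights as a ranked table (gene, weight, rank)."""
        out = self.weights.loc[self.gene_order].reset_index()
        out.columns = ["gene", "weight"]
        out["rank"] = np.arange(1, len(out) + 1)
        return out


def relief_f_scores(dataset: ExpressionDataset, k: int = 3) -> ReliefResult:
    """Deterministic full-pass Relief-F weights for every gene in a cohort.

    For each target sample, the k nearest hits (same class) and k nearest
    misses (other class) are found by Manhattan distance on features scaled
    to [0, 1] by their observed range.  The weight of feature f accumulates
    miss diffs minus hit diffs; the miss term is weighted by the miss
    class's prior over the complement of the target's class prior (the
    standard multi-class form, which reduces to weight 1 in the two-class
    case), and the total is normalised by n_samples × k.

    Constant genes get a weight of exactly 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = dataset.values()  # samples × genes
    y = dataset.labels.to_numpy()
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k + 1:
            raise ValueError(
                f"{dataset.name}: class {cls} has {cnt} samples; "
                f"Relief-F with k={k} needs at least {k + 1} per class"
            )
    priors = {cls: cnt / n for cls, cnt in zip(classes, counts)}

    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    scale = np.where(rng > 0, rng, 1.0)
    Z = (X - lo) / scale  # range-scaled; constant genes become all-zero diffs

    # full pairwise Manhattan distance (cohorts are small; O(n^2 p) is cheap)
    D = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    hit_acc = np.zeros(p)
    miss_acc = np.zeros(p)
    for i in range(n):
        order = np.argsort(D[i], kind="stable")  # ties → lowest sample index
        same = order[y[order] == y[i]][:k]
        hit_acc += np.abs(Z[i] - Z[same]).sum(axis=0)
        for cls in classes:
            if cls == y[i]:
                continue
            other = order[y[order] == cls][:k]
            w = priors[cls] / (1.0 - priors[y[i]])
            miss_acc += w * np.abs(Z[i] - Z[other]).sum(axis=0)

    weights = (miss_acc - hit_acc) / (n * k)
    series = pd.Series(weights, index=dataset.matrix.index, name="relief_weight")
    order = sorted(series.index, key=lambda g: (-series[g], g))
    return ReliefResult(weights=series, k=k, gene_order=order)


def select_top(result: ReliefResult, n: int = 500) -> list[str]:
    """First ``n`` genes of the Relief ordering (ties already lexicographic)."""
    if n > len(result.gene_order):
        raise ValueError(
            f"requested top {n} genes but only {len(result.gene_order)} scored"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    return result.gene_order[:n]
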