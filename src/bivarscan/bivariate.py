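"""Exhaustive gene-pair scoring with cross-validated linear SVMs.

Every unordered pair from a selected gene list is scored in every cohort by
stratified k-fold cross-validation of a linear support-vector classifier
(default C=100, 5 folds).  Features are standardized inside each training
fold and the fitted scaling applied to the held-out fold, so no information
leaks across the split.  The per-(pair, cohort) accuracies form a score
tensor from which the pipeline derives:

* the per-gene aggregated score ("CV_sum"): the sum of all passing cell
  scores (cell score > threshold) over every pair containing the gene and
  every cohort — the quantity that ranks genes;
* per-pair statistics: the cross-cohort aggregate ΣS_i and the selectivity
  σ = max(S_i²) − min(S_i²), which flags cohort-dependent pairs (σ near 0
  marks pairs that transfer across cohorts);
* transfer summaries: how pairs passing in a source cohort perform in the
  others, with a Welch two-sample t-test on the score vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .data_io import ExpressionDataset, StudyCollection

DEFAULT_C = 100.0
DEFAULT_FOLDS = 5
DEFAULT_THRESHOLD = 0.70


def enumerate_pairs(genes: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs in canonical lexicographic order.

    n genes yield n(n−1)/2 pairs; each pair is a tuple (a, b) with a < b.
    """
    uniq = sorted(set(genes))
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct genes to form pairs")
    return list(itertools.combinations(uniq, 2))


def stratified_splits(
    y: np.ndarray, n_splits: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified CV splits whose fold composition is label-arrangement
    invariant.

    Each class's member indices (taken in increasing order) are shuffled
    with the seed and dealt into folds, so the per-fold class-count pattern
    depends only on the class sizes — never on where in the sample order
    the classes sit.  This matters for the permutation null: the observed
    run (often block-sorted labels) and the shuffled-label runs must get
    statistically identical fold layouts, otherwise the null is biased.
    """
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_splits)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, n_splits)):
            folds[f].extend(chunk.tolist())
    all_idx = np.arange(len(y))
    out = []
    for f in range(n_splits):
        test = np.array(sorted(folds[f]), dtype=int)
        train = np.setdiff1d(all_idx, test)
        out.append((train, test))
    return out


class _FoldData:
    """Per-cohort CV layout with per-(fold, gene) standardized columns.

    Standardization statistics come from the training rows of each fold
    only; the whole standardized column (train + test rows) is cached so
    that scoring a pair is just a column gather plus one SVC fit per fold.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        genes: Sequence[str],
        folds: int,
        seed: int,
    ) -> None:
        y = dataset.labels.to_numpy()
        counts = np.bincount(y, minlength=2)
        if counts.min() < folds:
            raise ValueError(
                f"{dataset.name}: smallest class has {counts.min()} samples, "
                f"fewer than {folds} CV folds"
            )
        X = dataset.values(genes)  # samples × genes
        self.y = y
        self.splits = stratified_splits(y, folds, seed)
        self.Z: list[np.ndarray] = []
        for train, _test in self.splits:
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)  # constant-in-fold genes stay at 0
            self.Z.append((X - mu) / sd)

    def pair_accuracy(self, i: int, j: int, c: float) -> float:
        clf = SVC(kernel="linear", C=c)  # refit per fold; state fully reset by fit
        accs = []
        for (train, test), Z in zip(self.splits, self.Z):
            cols = Z[:, (i, j)]
            clf.fit(cols[train], self.y[train])
            accs.append(float(np.mean(clf.predict(cols[test]) == self.y[test])))
        return float(np.mean(accs))


def pair_cv_score(
    dataset: ExpressionDataset,
    pair: tuple[str, str],
    c: float = DEFAULT_C,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> float:
    """Mean held-out accuracy of a linear SVM on one gene pair in one cohort.

    Stratified ``folds``-fold CV with per-fold feature standardization;
    deterministic given ``seed`` (which fixes the fold layout).
    """
    a, b = pair
    for g in (a, b):
        if g not in dataset.matrix.index:
            raise KeyError(f"gene {g!r} not in dataset {dataset.name!r}")
    fd = _FoldData(dataset, [a, b], folds, seed)
    return fd.pair_accuracy(0, 1, c)


@dataclass
class PairScoreTensor:
    """CV accuracy for every (gene pair, cohort) cell."""

    genes: list[str]
    pairs: list[tuple[str, str]]
    dataset_names: list[str]
    scores: np.ndarray  # n_pairs × n_datasets, values in [0, 1]
    cv_folds: int
    svm_c: float
    seed: int

    def __post_init__(self) -> None:
        n = len(self.genes)
        if len(self.pairs) != n * (n - 1) // 2:
            raise ValueError("pair count must be n(n-1)/2 for n genes")
        if self.scores.shape != (len(self.pairs), len(self.dataset_names)):
            raise ValueError("score array shape mismatch")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("CV scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.scores, columns=self.dataset_names)
        out.insert(0, "gene_a", [p[0] for p in self.pairs])
        out.insert(1, "gene_b", [p[1] for p in self.pairs])
        return out

    def score_of(self, pair: tuple[str, str]) -> np.ndarray:
        key = tuple(sorted(pair))
        try:
            idx = self.pairs.index(key)  # pairs list is small relative to lookups
        except ValueError:
            raise KeyError(f"pair {key} not in tensor") from None
        return self.scores[idx]


def score_all_pairs(
    collection: StudyCollection,
    genes: Sequence[str],
    c: float = DEFAULT_C,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> PairScoreTensor:
    """Fill the full (pair × cohort) CV-accuracy tensor.

    Results are independent of evaluation order; the per-cohort fold layout
    is fixed by ``seed`` so identical seeds give identical tensors.
    """
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in collection.gene_universe]
    if missing:
        raise KeyError(f"genes not in the collection's universe: {missing[:5]}")
    pairs = enumerate_pairs(genes)
    index = {g: i for i, g in enumerate(genes)}
    scores = np.empty((len(pairs), len(collection)), dtype=float)
    for d, dataset in enumerate(collection):
        fd = _FoldData(dataset, genes, folds, seed)
        for p, (a, b) in enumerate(pairs):
            scores[p, d] = fd.pair_accuracy(index[a], index[b], c)
    return PairScoreTensor(
        genes=list(genes),
        pairs=pairs,
        dataset_names=collection.names,
        scores=scores,
        cv_folds=folds,
        svm_c=c,
        seed=seed,
    )


@dataclass
class GeneRanking:
    """Per-gene thresholded aggregated scores (CV_sum) with ranks."""

    scores: pd.Series  # indexed by gene, non-negative
    threshold: float
    mode: str = "per_cell"

    @property
    def gene_order(self) -> list[str]:
        return sorted(self.scores.index, key=lambda g: (-self.scores[g], g))

    def table(self) -> pd.DataFrame:
        order = self.gene_order
        out = pd.DataFrame(
            {"gene": order, "cv_sum": self.scores.loc[order].to_numpy()}
        )
        out["rank"] = np.arange(1, len(out) + 1)
        return out

    def top(self, n: int) -> list[str]:
        return self.gene_order[:n]


def aggregate_gene_scores(
    tensor: PairScoreTensor,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "per_cell",
) -> GeneRanking:
    """Threshold the tensor and sum passing scores into per-gene CV_sum.

    ``mode="per_cell"`` (default): a (pair, cohort) cell passes when its own
    score strictly exceeds ``threshold``; each passing cell credits its
    score to both member genes.  ``mode="pair_sum"``: a pair passes when its
    mean score across cohorts exceeds ``threshold``, in which case all of
    its cells are credited.  Lowering the threshold can only add passing
    cells, so every gene's score is non-increasing in the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if mode not in ("per_cell", "pair_sum"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if mode == "per_cell":
        passing = tensor.scores > threshold
    else:
        passing = np.repeat(
            (tensor.scores.mean(axis=1) > threshold)[:, None],
            tensor.scores.shape[1],
            axis=1,
        )
    contrib = np.where(passing, tensor.scores, 0.0).sum(axis=1)  # per pair
    acc = {g: 0.0 for g in tensor.genes}
    for (a, b), v in zip(tensor.pairs, contrib):
        acc[a] += v
        acc[b] += v
    scores = pd.Series(acc, name="cv_sum").loc[tensor.genes]
    return GeneRanking(scores=scores, threshold=threshold, mode=mode)


def pair_statistics(tensor: PairScoreTensor) -> pd.DataFrame:
    """Per-pair aggregate and selectivity table.

    ``aggregate`` is the plain sum of the pair's CV scores across cohorts;
    ``selectivity`` is max(S_i²) − min(S_i²), zero iff all squared scores
    are equal and at most 1 by construction.
    """
    sq = tensor.scores**2
    out = tensor.to_frame()
    out["aggregate"] = tensor.scores.sum(axis=1)
    out["selectivity"] = sq.max(axis=1) - sq.min(axis=1)
    return out


def transfer_summary(
    tensor: PairScoreTensor,
    source: str,
    threshold: float = DEFAULT_THRESHOLD,
    passing_pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """How pairs passing in one cohort perform in the others.

    Selects the pairs whose CV score in ``source`` strictly exceeds
    ``threshold`` (or an explicit pair set), then reports each cohort's
    mean score over those pairs plus a Welch two-sample t-test (two-sided)
    between the source's and each other cohort's score vectors.
    """
    if source not in tensor.dataset_names:
        raise KeyError(f"unknown source cohort {source!r}")
    s = tensor.dataset_names.index(source)
    if passing_pairs is None:
        mask = tensor.scores[:, s] > threshold
    else:
        wanted = {tuple(sorted(p)) for p in passing_pairs}
        mask = np.array([p in wanted for p in tensor.pairs])
    if not mask.any():
        raise ValueError(f"no pairs pass threshold {threshold} in {source!r}")
    sel = tensor.scores[mask]
    rows = []
    for d, name in enumerate(tensor.dataset_names):
        if d == s:
            t_stat, p_val = np.nan, np.nan
        else:
            t_stat, p_val = stats.ttest_ind(sel[:, s], sel[:, d], equal_var=False)
        rows.append(
            {
                "cohort": name,
                "n_pairs": int(mask.sum()),
                "mean_score": float(sel[:, d].mean()),
                "welch_t": float(t_stat) if np.isfinite(t_stat) else np.nan,
                "welch_p": float(p_val) if np.isfinite(p_val) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("cohort")
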