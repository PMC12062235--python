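"""Robustness of the bivariate ranking: noise, thresholds, permutation null.

Three independent probes of how stable the gene ranking is:

1. **Noise injection** — add zero-mean Gaussian noise with per-gene sd
   ``alpha × sd(gene)`` and measure rank agreement (Kendall tau-b) between
   the clean and noisy runs of the filter (and optionally the full
   bivariate ranking).
2. **Threshold sensitivity** — recompute the ranking at several passing
   thresholds and report the pairwise tau-b matrix over the score vectors.
3. **Permutation null** — shuffle case/control labels within each cohort,
   re-score the fixed gene list and pool all aggregated gene scores into an
   empirical null; the per-gene p-value is the fraction of pooled null
   scores at or above the observed score (reported as a "< 1/N" bound when
   none reach it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bivariate import (
    DEFAULT_C,
    DEFAULT_FOLDS,
    DEFAULT_THRESHOLD,
    GeneRanking,
    PairScoreTensor,
    aggregate_gene_scores,
    score_all_pairs,
)
from .data_io import ExpressionDataset, StudyCollection
from .relief import relief_f_scores, select_top


def inject_noise(
    dataset: ExpressionDataset, alpha: float = 0.05, seed: int = 0
) -> ExpressionDataset:
    """Add per-gene Gaussian noise with sd = ``alpha`` × sd(gene).

    ``alpha = 0`` returns a bit-identical copy; constant genes (sd 0) are
    never perturbed.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    rng = np.random.default_rng(seed)
    values = dataset.matrix.to_numpy(dtype=float)
    sds = values.std(axis=1, ddof=1)
    noise = rng.normal(size=values.shape) * (alpha * sds)[:, None]
    noisy = pd.DataFrame(
        values + noise, index=dataset.matrix.index, columns=dataset.matrix.columns
    )
    return ExpressionDataset(
        name=dataset.name,
        matrix=noisy,
        labels=dataset.labels,
        platform=dataset.platform,
        metadata=dataset.metadata,
    )


def kendall_tau(rank_a: pd.Series, rank_b: pd.Series) -> float:
    """Tie-corrected Kendall tau-b between two score vectors over one item set.

    Returns NaN when either vector is constant (tau undefined under total
    ties); callers decide how to interpret that degenerate case.
    """
    if set(rank_a.index) != set(rank_b.index):
        raise ValueError("kendall_tau requires identical item sets")
    b = rank_b.loc[rank_a.index]
    tau = stats.kendalltau(rank_a.to_numpy(), b.to_numpy()).statistic
    return float(tau)


def _union_scores(
    top_a: pd.Series, top_b: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Align two top-n score vectors on their union; absent genes score 0."""
    union = sorted(set(top_a.index) | set(top_b.index))
    a = top_a.reindex(union, fill_value=0.0)
    b = top_b.reindex(union, fill_value=0.0)
    return a, b


@dataclass
class NoiseStabilityResult:
    """Clean-vs-noisy rank agreement for the filter and (optionally) the ranking."""

    tau_relief: float
    tau_bivariate: float | None
    alpha: float
    seed: int


def noise_stability(
    collection: StudyCollection,
    selection_dataset: str,
    alpha: float = 0.05,
    seed: int = 0,
    k: int = 3,
    top_n: int = 50,
    include_bivariate: bool = False,
    c: float = DEFAULT_C,
    folds: int = DEFAULT_FOLDS,
    threshold: float = DEFAULT_THRESHOLD,
    cv_seed: int = 0,
) -> NoiseStabilityResult:
    """Rerun the selection (and optionally pair-scoring) stage on noisy data.

    Tau is computed over the union of genes in either top-n list; a gene
    absent from one list contributes score 0 there (rank past the end).
    The same CV seed is used for both runs so only the injected noise
    differs.
    """
    clean_ds = collection[selection_dataset]
    root = np.random.SeedSequence([seed, 0x4E4F4953])  # namespaced stream
    ds_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(collection))]
    noisy_sets = [
        inject_noise(ds, alpha=alpha, seed=s) for ds, s in zip(collection, ds_seeds)
    ]
    noisy = StudyCollection(datasets=noisy_sets, gene_universe=collection.gene_universe)

    clean_relief = relief_f_scores(clean_ds, k=k)
    noisy_relief = relief_f_scores(noisy[selection_dataset], k=k)
    clean_top = select_top(clean_relief, top_n)
    noisy_top = select_top(noisy_relief, top_n)
    a, b = _union_scores(
        clean_relief.weights.loc[clean_top], noisy_relief.weights.loc[noisy_top]
    )
    tau_relief = kendall_tau(a, b)

    tau_bi = None
    if include_bivariate:
        clean_rank = aggregate_gene_scores(
            score_all_pairs(collection, clean_top, c=c, folds=folds, seed=cv_seed),
            threshold=threshold,
        )
        noisy_rank = aggregate_gene_scores(
            score_all_pairs(noisy, noisy_top, c=c, folds=folds, seed=cv_seed),
            threshold=threshold,
        )
        a, b = _union_scores(clean_rank.scores, noisy_rank.scores)
        tau_bi = kendall_tau(a, b)
    return NoiseStabilityResult(
        tau_relief=tau_relief, tau_bivariate=tau_bi, alpha=alpha, seed=seed
    )


@dataclass
class ThresholdSensitivityResult:
    """Pairwise tau-b between gene rankings at different passing thresholds."""

    thresholds: list[float]
    tau_matrix: pd.DataFrame
    rankings: dict[float, GeneRanking]
    degenerate: bool  # True when every ranking was all-ties (tau set to 1)


def threshold_sensitivity(
    tensor: PairScoreTensor,
    thresholds: tuple[float, ...] = (0.65, 0.70, 0.75),
) -> ThresholdSensitivityResult:
    """Gene rankings at each threshold plus their pairwise tau-b matrix.

    Tau is computed on the aggregated score vectors, so both rank position
    and score magnitude matter.  If two rankings are entirely tied (e.g.
    all-zero because no cell passes), tau-b is undefined; the conventional
    value 1 is reported and the result flagged degenerate.
    """
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    rankings = {t: aggregate_gene_scores(tensor, threshold=t) for t in thresholds}
    m = len(thresholds)
    mat = np.ones((m, m))
    degenerate = False
    for i in range(m):
        for j in range(i + 1, m):
            tau = kendall_tau(
                rankings[thresholds[i]].scores, rankings[thresholds[j]].scores
            )
            if np.isnan(tau):
                tau, degenerate = 1.0, True
            mat[i, j] = mat[j, i] = tau
    labels = [f"{t:g}" for t in thresholds]
    return ThresholdSensitivityResult(
        thresholds=list(thresholds),
        tau_matrix=pd.DataFrame(mat, index=labels, columns=labels),
        rankings=rankings,
        degenerate=degenerate,
    )


@dataclass
class NullDistribution:
    """Pooled permutation null of aggregated gene scores with empirical p-values.

    ``p`` is #(null ≥ observed) / N with N = n_permutations × n_genes; when
    no null score reaches the observed one, ``p`` is reported as the bound
    1/N with ``censored`` True (printed ``"< 1/N"``).
    """

    null_scores: np.ndarray  # length n_permutations × n_genes
    n_permutations: int
    per_gene: pd.DataFrame  # gene, observed, n_exceed, p, censored, p_label
    seed: int

    @property
    def n_pooled(self) -> int:
        return self.null_scores.size


def permutation_null(
    collection: StudyCollection,
    genes: list[str],
    observed: GeneRanking,
    n_permutations: int = 200,
    seed: int = 0,
    c: float = DEFAULT_C,
    folds: int = DEFAULT_FOLDS,
    cv_seed: int = 0,
) -> NullDistribution:
    """Label-permutation null for the aggregated gene scores.

    Per permutation, labels are shuffled independently within each cohort
    (cohorts are separate experiments), the full pair tensor is re-scored
    on the fixed gene list with the same CV layout seed, and the aggregated
    scores of all genes are pooled.  Each permutation's shuffle stream is
    derived from ``seed`` and its index, so any single permutation is
    reproducible in isolation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    # namespaced stream: must never replay the synthetic generator's (or
    # any other component's) random numbers when given the same user seed
    root = np.random.SeedSequence([seed, 0x5045524D])
    pooled = np.empty((n_permutations, len(genes)), dtype=float)
    gene_order = list(observed.scores.index)
    for p_idx, child in enumerate(root.spawn(n_permutations)):
        rng = np.random.default_rng(child)
        permuted = []
        for ds in collection:
            y = ds.labels.to_numpy().copy()
            rng.shuffle(y)
            permuted.append(
                ExpressionDataset(
                    name=ds.name,
                    matrix=ds.matrix,
                    labels=pd.Series(y, index=ds.labels.index, name="label"),
                    platform=ds.platform,
                )
            )
        pcoll = StudyCollection(
            datasets=permuted, gene_universe=collection.gene_universe
        )
        tensor = score_all_pairs(pcoll, genes, c=c, folds=folds, seed=cv_seed)
        ranking = aggregate_gene_scores(
            tensor, threshold=observed.threshold, mode=observed.mode
        )
        pooled[p_idx] = ranking.scores.reindex(sorted(genes)).to_numpy()

    null_scores = pooled.ravel()
    n_total = null_scores.size
    rows = []
    for g in gene_order:
        obs = float(observed.scores[g])
        n_exceed = int((null_scores >= obs).sum())
        censored = n_exceed == 0
        p = (n_exceed if not censored else 1) / n_total
        rows.append(
            {
                "gene": g,
                "observed": obs,
                "n_exceed": n_exceed,
                "p": p,
                "censored": censored,
                "p_label": f"< {1 / n_total:g}" if censored else f"{p:g}",
            }
        )
    return NullDistribution(
        null_scores=null_scores,
        n_permutations=n_permutations,
        per_gene=pd.DataFrame(rows).set_index("gene"),
        seed=seed,
    )
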