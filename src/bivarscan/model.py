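"""Model/Results interface over the bivariate screening pipeline.

:class:`BivariateBiomarkerScreen` is built from a harmonized
:class:`~bivarscan.data_io.StudyCollection` and holds the analysis design
(selection cohort, Relief-F k, top-n, SVM penalty, CV folds, passing
threshold, seed).  ``fit()`` runs filter → exhaustive pair CV → aggregation
and returns a :class:`BivariateScreenResults`, which carries the score
tensor, the gene ranking, pair-level statistics, and methods for the
robustness suite, permutation significance and plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bivariate, robustness
from .data_io import StudyCollection
from .relief import ReliefResult, relief_f_scores, select_top


class BivariateBiomarkerScreen:
    """Cross-cohort gene-pair screening model.

    Parameters
    ----------
    collection : StudyCollection
        Harmonized cohorts sharing one gene universe.
    selection_dataset : str, optional
        Cohort whose Relief-F ordering picks the candidate genes (defaults
        to the first cohort, mirroring selection in a discovery cohort).
    k : int
        Relief-F neighbour count.
    top_n : int
        Number of genes kept by the filter stage.
    c : float
        Linear-SVM penalty.
    folds : int
        Stratified CV folds.
    threshold : float
        Passing threshold on per-cell CV scores.
    seed : int
        Fixes the CV fold layout (the pipeline is otherwise deterministic).
    """

    def __init__(
        self,
        collection: StudyCollection,
        selection_dataset: str | None = None,
        k: int = 3,
        top_n: int = 500,
        c: float = bivariate.DEFAULT_C,
        folds: int = bivariate.DEFAULT_FOLDS,
        threshold: float = bivariate.DEFAULT_THRESHOLD,
        aggregation_mode: str = "per_cell",
        seed: int = 0,
    ) -> None:
        self.collection = collection
        self.selection_dataset = selection_dataset or collection.names[0]
        if self.selection_dataset not in collection.names:
            raise KeyError(f"unknown selection dataset {self.selection_dataset!r}")
        if top_n > len(collection.gene_universe):
            raise ValueError(
                f"top_n={top_n} exceeds the {len(collection.gene_universe)}-gene universe"
            )
        self.k = k
        self.top_n = top_n
        self.c = c
        self.folds = folds
        self.threshold = threshold
        self.aggregation_mode = aggregation_mode
        self.seed = seed

    @classmethod
    def from_datasets(cls, datasets, transform: str = "none", **kwargs):
        """Build the model directly from unharmonized cohorts."""
        from .data_io import harmonize

        return cls(harmonize(datasets, transform=transform), **kwargs)

    def fit(self, genes: list[str] | None = None) -> "BivariateScreenResults":
        """Run filter → pair scoring → aggregation.

        An explicit ``genes`` list bypasses the Relief-F filter (used by
        permutation reruns and tests); otherwise the top ``top_n`` genes of
        the selection cohort's Relief-F ordering are screened.
        """
        relief = relief_f_scores(self.collection[self.selection_dataset], k=self.k)
        selected = genes if genes is not None else select_top(relief, self.top_n)
        tensor = bivariate.score_all_pairs(
            self.collection, selected, c=self.c, folds=self.folds, seed=self.seed
        )
        ranking = bivariate.aggregate_gene_scores(
            tensor, threshold=self.threshold, mode=self.aggregation_mode
        )
        return BivariateScreenResults(
            model=self, relief=relief, selected_genes=list(selected),
            tensor=tensor, ranking=ranking,
        )


@dataclass
class BivariateScreenResults:
    """Fitted screen: tensor, ranking and derived statistics."""

    model: BivariateBiomarkerScreen
    relief: ReliefResult
    selected_genes: list[str]
    tensor: bivariate.PairScoreTensor
    ranking: bivariate.GeneRanking
    _pair_stats: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def pair_statistics(self) -> pd.DataFrame:
        """Per-pair cross-cohort aggregate and selectivity (cached)."""
        if self._pair_stats is None:
            self._pair_stats = bivariate.pair_statistics(self.tensor)
        return self._pair_stats

    def transfer_summary(self, source: str | None = None) -> pd.DataFrame:
        """Mean score of source-passing pairs in every cohort + Welch tests."""
        return bivariate.transfer_summary(
            self.tensor,
            source or self.model.selection_dataset,
            threshold=self.model.threshold,
        )

    # -- robustness -----------------------------------------------------------

    def permutation_null(
        self, n_permutations: int = 200, seed: int = 0
    ) -> robustness.NullDistribution:
        """Label-permutation null and empirical p-values for the ranking."""
        return robustness.permutation_null(
            self.model.collection,
            self.selected_genes,
            self.ranking,
            n_permutations=n_permutations,
            seed=seed,
            c=self.model.c,
            folds=self.model.folds,
            cv_seed=self.model.seed,
        )

    def threshold_sensitivity(
        self, thresholds: tuple[float, ...] = (0.65, 0.70, 0.75)
    ) -> robustness.ThresholdSensitivityResult:
        return robustness.threshold_sensitivity(self.tensor, thresholds)

    def noise_stability(
        self, alpha: float = 0.05, seed: int = 0, include_bivariate: bool = False
    ) -> robustness.NoiseStabilityResult:
        return robustness.noise_stability(
            self.model.collection,
            self.model.selection_dataset,
            alpha=alpha,
            seed=seed,
            k=self.model.k,
            top_n=self.model.top_n,
            include_bivariate=include_bivariate,
            c=self.model.c,
            folds=self.model.folds,
            threshold=self.model.threshold,
            cv_seed=self.model.seed,
        )

    # -- plotting -------------------------------------------------------------

    def plot_rgb_pairs(self, display_genes=None, path=None):
        """RGB-encoded pair-accuracy image of the top genes (3 cohorts)."""
        from . import viz

        genes = display_genes or self.ranking.top(min(10, len(self.selected_genes)))
        return viz.rgb_pair_image(self.tensor, genes)

    def plot_aggregate_selectivity(self, path, annotate_top: int = 10):
        from . import viz

        return viz.aggregate_selectivity_scatter(
            self.pair_statistics, annotate_top=annotate_top, path=path
        )

    # -- presentation ---------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Human-readable account of the fitted screen."""
        m = self.model
        counts = {ds.name: ds.class_counts() for ds in m.collection}
        lines = [
            "Bivariate biomarker screen",
            "=" * 60,
            f"cohorts:            {', '.join(f'{n} ({c[0]}c/{c[1]}d)' for n, c in counts.items())}",
            f"gene universe:      {len(m.collection.gene_universe)} genes",
            f"selection cohort:   {m.selection_dataset} (Relief-F k={m.k}, top {m.top_n})",
            f"pair grid:          {len(self.tensor.pairs)} pairs x {len(m.collection)} cohorts",
            f"linear SVM:         C={m.c:g}, {m.folds}-fold stratified CV, seed {m.seed}",
            f"passing threshold:  score > {m.threshold:g} ({m.aggregation_mode})",
            "",
            f"top {top} genes by aggregated score (CV_sum):",
        ]
        table = self.ranking.table().head(top)
        for _, row in table.iterrows():
            lines.append(f"  {int(row['rank']):>4d}  {row['gene']:<12s} {row['cv_sum']:8.2f}")
        n_pass = int((self.tensor.scores > m.threshold).sum())
        lines.append("")
        lines.append(
            f"passing cells: {n_pass} of {self.tensor.scores.size} "
            f"(pair, cohort) combinations"
        )
        return "\n".join(lines)
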