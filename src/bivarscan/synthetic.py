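"""Synthetic multi-cohort expression data with planted ground truth.

The generator emulates the statistical shape of a three-cohort hippocampal
case/control study — two RNA-Seq-like cohorts (skewed, positive,
multiplicative scale) and one microarray-like cohort (additive noise on a
compressed log-intensity range) — and plants four kinds of genes:

* **univariate-signal** genes: a standardized case/control mean shift in
  every cohort (the classical differentially-expressed gene);
* **synergy pairs**: two genes that are strongly correlated within each
  class, with the class centroids displaced along the direction the
  correlation does *not* explain.  The joint standardized separation is
  large (a linear classifier on the pair separates the classes) while each
  marginal mean shift stays below a small cap (neither gene alone does).
  The case class additionally inflates the pair's variance, a
  dysregulation-style broadening of expression in disease.  In the
  *discovery* cohort (the first one) the members carry an ordinary
  univariate shift on top, emulating the empirical cross-study pattern:
  genes that a filter can find in the discovery cohort because they
  separate classes by themselves there, but whose class signal in the
  replication cohorts is purely joint;
* **cohort-specific** genes: a univariate shift in exactly one cohort;
* **null** genes: class-independent noise.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset, StudyCollection, harmonize

_PLATFORMS = ("rnaseq", "microarray")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for :func:`generate_collection`.

    Effects are expressed in within-class standard-deviation units of the
    latent (log-scale) expression: ``univariate_effect`` is the per-gene
    standardized mean shift, ``synergy_effect`` the joint Mahalanobis
    separation of a planted pair (with respect to the control-class
    covariance), and ``synergy_marginal_cap`` the largest per-gene
    standardized mean shift a synergy member may show.
    """

    n_genes: int = 2000
    cohort_specs: tuple[tuple[int, int, str], ...] = (
        (10, 18, "rnaseq"),
        (15, 20, "rnaseq"),
        (32, 31, "microarray"),
    )
    n_univariate_signal: int = 20
    n_synergy_pairs: int = 10
    n_cohort_specific: int = 9
    univariate_effect: float = 1.5
    synergy_effect: float = 4.0
    synergy_marginal_cap: float = 0.3
    within_pair_correlation: float = 0.997
    case_variance_inflation: float = 1.0
    synergy_noise_scale: float = 0.4
    synergy_discovery_shift: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_univariate_signal
            + 2 * self.n_synergy_pairs
            + self.n_cohort_specific
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene counts ({planted}) exceed n_genes ({self.n_genes})"
            )
        if not -1.0 < self.within_pair_correlation < 1.0:
            raise ValueError("within_pair_correlation must lie in (-1, 1)")
        if self.synergy_marginal_cap >= self.univariate_effect:
            raise ValueError(
                "synergy_marginal_cap must be smaller than univariate_effect "
                "(synergy genes must look null univariately)"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.case_variance_inflation < 1.0:
            raise ValueError("case_variance_inflation must be >= 1")
        if self.synergy_discovery_shift < 0:
            raise ValueError("synergy_discovery_shift must be non-negative")
        if not 0 < self.synergy_noise_scale <= 1.0:
            raise ValueError("synergy_noise_scale must lie in (0, 1]")
        for spec in self.cohort_specs:
            n0, n1, platform = spec
            if platform not in _PLATFORMS:
                raise ValueError(f"unknown platform {platform!r}")
            if n0 < 2 or n1 < 2:
                raise ValueError("each cohort needs >= 2 samples per class")
        if self.synergy_marginal_shift > self.synergy_marginal_cap + 1e-12:
            raise ValueError(
                "infeasible synergy geometry: joint separation "
                f"{self.synergy_effect} with correlation "
                f"{self.within_pair_correlation} implies a marginal shift of "
                f"{self.synergy_marginal_shift:.3f} sd, above the cap "
                f"{self.synergy_marginal_cap}"
            )

    @property
    def synergy_marginal_shift(self) -> float:
        """Per-gene standardized mean shift implied by the pair geometry.

        The class centroids are displaced by (+a, −a) against a within-class
        correlation ρ, so the joint Mahalanobis separation is
        a·sqrt(2/(1−ρ)) and the marginal shift per gene is
        ``synergy_effect·sqrt((1−ρ)/2)``.
        """
        return self.synergy_effect * np.sqrt((1.0 - self.within_pair_correlation) / 2.0)


@dataclass
class GroundTruth:
    """Which planted role each gene plays."""

    univariate_genes: set[str]
    synergy_pairs: set[tuple[str, str]]
    cohort_specific_genes: dict[str, set[str]]
    null_genes: set[str]

    @property
    def synergy_genes(self) -> set[str]:
        return {g for pair in self.synergy_pairs for g in pair}

    def table(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.univariate_genes):
            rows.append({"gene": g, "role": "univariate", "detail": ""})
        for a, b in sorted(self.synergy_pairs):
            rows.append({"gene": a, "role": "synergy", "detail": b})
            rows.append({"gene": b, "role": "synergy", "detail": a})
        for cohort, genes in self.cohort_specific_genes.items():
            for g in sorted(genes):
                rows.append({"gene": g, "role": "cohort_specific", "detail": cohort})
        for g in sorted(self.null_genes):
            rows.append({"gene": g, "role": "null", "detail": ""})
        return pd.DataFrame(rows)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _latent_cohort(
    config: SyntheticConfig,
    n0: int,
    n1: int,
    cohort_index: int,
    truth_index: dict[str, object],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (log-scale) genes × samples matrix plus labels for one cohort."""
    sd = config.noise_sd
    n = n0 + n1
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    Z = rng.normal(0.0, sd, size=(config.n_genes, n))

    case = y == 1
    shift = config.univariate_effect * sd
    for gi, role in truth_index.items():
        kind = role[0]
        if kind == "univariate" or (kind == "cohort" and role[1] == cohort_index):
            Z[gi, case] += shift

    rho = config.within_pair_correlation
    # synergy genes are tightly co-regulated: their within-class sd is a
    # fraction of the global latent sd, so standardized effects (what a
    # classifier or Relief sees) can be large while absolute log-scale
    # shifts (what a fold-change cutoff sees) stay modest
    pair_sd = config.synergy_noise_scale * sd
    a = config.synergy_marginal_shift * pair_sd
    r = config.case_variance_inflation
    cov = pair_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    discovery = config.synergy_discovery_shift * sd if cohort_index == 0 else 0.0
    gene_sds = np.full(config.n_genes, sd)
    for gi, role in truth_index.items():
        if role[0] != "synergy_lead":
            continue
        gj = role[1]
        raw = rng.normal(size=(n, 2)) @ chol.T  # correlated within-class noise
        raw[case] *= r
        raw[case] += np.array([+a, -a]) / 2.0 + discovery
        raw[~case] += np.array([-a, +a]) / 2.0
        Z[gi] = raw[:, 0]
        Z[gj] = raw[:, 1]
        gene_sds[gi] = gene_sds[gj] = pair_sd
    return Z, y, gene_sds


def _to_platform(
    Z: np.ndarray, platform: str, rng: np.random.Generator, gene_sds: np.ndarray
) -> np.ndarray:
    if platform == "rnaseq":
        baselines = rng.uniform(4.0, 10.0, size=Z.shape[0])
        return 2.0 ** (Z + baselines[:, None])
    # microarray: compressed log-intensity range plus additive background
    # proportional to each gene's latent spread; the factor is kept small
    # so planted joint separations survive the platform mapping (a pair's
    # conditional spread can be far tighter than its marginal spread)
    compress = 0.5
    baselines = rng.uniform(6.0, 12.0, size=Z.shape[0])
    background = rng.normal(size=Z.shape) * (0.02 * compress * gene_sds)[:, None]
    return baselines[:, None] + compress * Z + background


def generate_collection(
    config: SyntheticConfig,
) -> tuple[StudyCollection, GroundTruth]:
    """Generate the harmonized multi-cohort collection plus its ground truth.

    All cohorts share the same gene symbols and planted roles; only the
    cohort-specific genes differ in which cohort carries their shift.
    Per-cohort random streams are spawned deterministically from the config
    seed.
    """
    genes = _gene_names(config.n_genes)
    nu, ns, nc = (
        config.n_univariate_signal,
        2 * config.n_synergy_pairs,
        config.n_cohort_specific,
    )
    univariate = genes[:nu]
    synergy_flat = genes[nu : nu + ns]
    cohort_specific = genes[nu + ns : nu + ns + nc]
    null = genes[nu + ns + nc :]

    pairs = [
        (synergy_flat[2 * i], synergy_flat[2 * i + 1])
        for i in range(config.n_synergy_pairs)
    ]
    n_cohorts = len(config.cohort_specs)
    cohort_assign = {g: i % n_cohorts for i, g in enumerate(cohort_specific)}

    gene_pos = {g: i for i, g in enumerate(genes)}
    truth_index: dict[int, object] = {}
    for g in univariate:
        truth_index[gene_pos[g]] = ("univariate",)
    for a, b in pairs:
        truth_index[gene_pos[a]] = ("synergy_lead", gene_pos[b])
    for g, ci in cohort_assign.items():
        truth_index[gene_pos[g]] = ("cohort", ci)

    # the extra entropy word namespaces this stream so that other seeded
    # components (e.g. permutation shuffles) given the same user seed can
    # never replay the generator's random numbers
    root = np.random.SeedSequence([config.seed, 0x53594E44])
    datasets = []
    for ci, ((n0, n1, platform), child) in enumerate(
        zip(config.cohort_specs, root.spawn(n_cohorts))
    ):
        rng = np.random.default_rng(child)
        Z, y, gene_sds = _latent_cohort(config, n0, n1, ci, truth_index, rng)
        X = _to_platform(Z, platform, rng, gene_sds)
        name = f"cohort{ci + 1}"
        sample_ids = [f"{name}_s{j + 1:03d}" for j in range(n0 + n1)]
        matrix = pd.DataFrame(X, index=genes, columns=sample_ids)
        labels = pd.Series(y, index=matrix.columns, name="label")
        datasets.append(
            ExpressionDataset(name=name, matrix=matrix, labels=labels, platform=platform)
        )

    collection = harmonize(datasets, transform="none")
    truth = GroundTruth(
        univariate_genes=set(univariate),
        synergy_pairs=set(pairs),
        cohort_specific_genes={
            f"cohort{ci + 1}": {g for g, c in cohort_assign.items() if c == ci}
            for ci in range(n_cohorts)
        },
        null_genes=set(null),
    )
    return collection, truth


_PRESETS = {
    "tiny": dict(
        n_genes=60,
        cohort_specs=((10, 10, "rnaseq"), (10, 10, "rnaseq"), (12, 12, "microarray")),
        n_univariate_signal=5,
        n_synergy_pairs=3,
        n_cohort_specific=3,
    ),
    "paperlike": dict(),  # the dataclass defaults ARE the paper-like design
}


def preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Named study designs: ``tiny`` (~60 genes, small balanced cohorts, for
    unit tests) and ``paperlike`` (2000 genes; cohorts of 28, 35 and 63
    samples split 10/18, 15/20 and 32/31)."""
    try:
        kwargs = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return SyntheticConfig(seed=seed, **kwargs)
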