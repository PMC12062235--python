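"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` captures everything a run depends on — input cohorts
(or a synthetic preset), the selection design, SVM/CV settings, thresholds,
robustness parameters and the mandatory seed — so any output directory can
be reproduced from its config echo alone.  :func:`run_pipeline` executes
the stages in order (simulate/load → filter → pair scoring → ranking →
pair statistics → robustness → permutation null → DE baseline → plots) and
writes a manifest with per-file SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data_io import harmonize, read_expression_matrix, write_dataset
from .model import BivariateBiomarkerScreen
from .robustness import noise_stability
from .synthetic import generate_collection, preset
from .univariate import de_analysis, overlap_report

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CohortSource:
    """Where one cohort's files live."""

    name: str
    matrix: str
    labels: str
    platform: str


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run.

    Either ``synthetic_preset`` (with ``synthetic_seed``) or an explicit
    list of ``cohorts`` must be given.  ``seed`` fixes the CV fold layout
    and all robustness randomness and is mandatory.
    """

    output_dir: str
    seed: int
    synthetic_preset: str | None = None
    synthetic_seed: int | None = None
    cohorts: list[CohortSource] = field(default_factory=list)
    transform: str = "none"
    selection_dataset: str | None = None
    k: int = 3
    top_n: int = 50
    svm_c: float = 100.0
    folds: int = 5
    threshold: float = 0.70
    thresholds: tuple[float, ...] = (0.65, 0.70, 0.75)
    alpha: float = 0.05
    n_permutations: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold {self.threshold} outside [0, 1]")
        for t in self.thresholds:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"sensitivity threshold {t} outside [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.k < 1 or self.top_n < 2 or self.folds < 2:
            raise ValueError("k >= 1, top_n >= 2 and folds >= 2 required")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if bool(self.synthetic_preset) == bool(self.cohorts):
            raise ValueError(
                "exactly one of synthetic_preset or cohorts must be provided"
            )
        if self.transform not in ("none", "log2p1"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohorts = [CohortSource(**c) for c in raw.pop("cohorts", [])]
        thresholds = tuple(raw.pop("thresholds", (0.65, 0.70, 0.75)))
        return cls(cohorts=cohorts, thresholds=thresholds, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the workflow and return the run manifest.

    Stages run in order; a failure aborts with :class:`PipelineError`
    naming the stage.  Every output is a delimited text file under
    ``config.output_dir``; the manifest (also written there as
    ``manifest.json``) echoes the config and checksums every file, so two
    runs with the same config produce identical manifests.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.synthetic_preset:
            syn_seed = (
                config.synthetic_seed if config.synthetic_seed is not None else config.seed
            )
            cfg = preset(config.synthetic_preset, seed=syn_seed)
            collection, truth = generate_collection(cfg)
            _write_tsv(truth.table(), out / "ground_truth.tsv", index=False)
            for ds in collection:
                write_dataset(
                    ds, out / f"{ds.name}_matrix.tsv", out / f"{ds.name}_labels.tsv"
                )
            datasets = list(collection)
        else:
            datasets = [
                read_expression_matrix(c.matrix, c.labels, c.platform, c.name)
                for c in config.cohorts
            ]
        collection = harmonize(datasets, transform=config.transform)

        stage = "fit"
        model = BivariateBiomarkerScreen(
            collection,
            selection_dataset=config.selection_dataset,
            k=config.k,
            top_n=config.top_n,
            c=config.svm_c,
            folds=config.folds,
            threshold=config.threshold,
            seed=config.seed,
        )
        results = model.fit()
        _write_tsv(results.relief.table(), out / "relief_weights.tsv", index=False)
        _write_tsv(results.tensor.to_frame(), out / "pair_scores.tsv", index=False)
        _write_tsv(results.ranking.table(), out / "gene_ranking.tsv", index=False)
        _write_tsv(
            results.pair_statistics[
                ["gene_a", "gene_b", "aggregate", "selectivity"]
            ],
            out / "pair_stats.tsv",
            index=False,
        )
        _write_tsv(results.transfer_summary(), out / "transfer_summary.tsv")

        stage = "robustness"
        sens = results.threshold_sensitivity(config.thresholds)
        _write_tsv(sens.tau_matrix, out / "threshold_tau.tsv")
        noise = results.noise_stability(alpha=config.alpha, seed=config.seed)
        _write_tsv(
            pd.DataFrame(
                [{"tau_relief": noise.tau_relief, "alpha": noise.alpha}]
            ),
            out / "noise_stability.tsv",
            index=False,
        )

        stage = "permutation"
        if config.n_permutations:
            null = results.permutation_null(
                n_permutations=config.n_permutations, seed=config.seed
            )
            _write_tsv(
                pd.DataFrame({"null_score": null.null_scores}),
                out / "null_scores.tsv",
                index=False,
            )
            _write_tsv(null.per_gene, out / "gene_pvalues.tsv")

        stage = "de"
        # DE runs on raw expression (it applies its own log handling);
        # the harmonized collection may already be log-transformed
        raw_selection = next(
            ds for ds in datasets if ds.name == model.selection_dataset
        )
        de = de_analysis(raw_selection)
        _write_tsv(de, out / "de_results.tsv")
        overlap = overlap_report(de, results.selected_genes)

        stage = "plots"
        if config.make_plots:
            from .viz import aggregate_selectivity_scatter, plot_rgb_pair_image

            if len(collection) == 3:
                top10 = results.ranking.top(min(10, len(results.selected_genes)))
                plot_rgb_pair_image(results.tensor, top10, out / "rgb_pairs.png")
            aggregate_selectivity_scatter(
                results.pair_statistics, out / "aggregate_selectivity.png"
            )

        stage = "manifest"
        (out / "summary.txt").write_text(results.summary() + "\n")
        files = sorted(
            p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "version": __version__,
            "python": platform.python_version(),
            "config": config.to_dict(),
            "selection_dataset": model.selection_dataset,
            "n_selected_genes": len(results.selected_genes),
            "n_pairs": len(results.tensor.pairs),
            "de_overlap_fraction": overlap["fraction_flagged"],
            "files": {p.name: _sha256(p) for p in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
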