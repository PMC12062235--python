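"""Reading, validation and harmonization of per-cohort expression matrices.

A cohort is a genes × samples matrix of continuous expression values
(RPKM-like for RNA-Seq, log-intensity-like for microarray) with a binary
case/control label per sample.  Cohorts measured on different platforms are
harmonized onto a shared gene universe before any cross-cohort analysis.

All delimited I/O is plain text: TSV or CSV, auto-detected by extension.
The matrix file has a gene-symbol first column (header ``gene``) and one
column per sample; the label table has two columns ``sample_id`` and
``label`` with values ``case`` / ``control``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("rnaseq", "microarray")

#: numeric encoding of the two diagnostic classes
CONTROL, CASE = 0, 1

_LABEL_CODES = {"control": CONTROL, "case": CASE}


class DataValidationError(ValueError):
    """Raised when an input matrix or label table violates an invariant."""


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionDataset:
    """One cohort: expression matrix, labels and platform tag.

    Parameters
    ----------
    name : str
        Cohort identifier.
    matrix : pandas.DataFrame
        Genes × samples, float values, index of unique upper-case gene
        symbols, columns of unique sample ids.
    labels : pandas.Series
        Per-sample class, 0 = control, 1 = case, indexed like the matrix
        columns.
    platform : str
        ``"rnaseq"`` or ``"microarray"``.
    metadata : pandas.DataFrame, optional
        Per-sample annotations (e.g. diagnosis subtype), indexed by sample
        id; carried through subsetting, never interpreted here.
    """

    name: str
    matrix: pd.DataFrame
    labels: pd.Series
    platform: str
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise DataValidationError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if self.matrix.size == 0:
            raise DataValidationError(f"{self.name}: empty expression matrix")
        genes = self.matrix.index.astype(str)
        if genes.str.upper().duplicated().any():
            dupes = genes[genes.str.upper().duplicated()].tolist()
            raise DataValidationError(f"{self.name}: duplicate gene symbols {dupes}")
        if self.matrix.columns.duplicated().any():
            raise DataValidationError(f"{self.name}: duplicate sample ids")
        if not self.matrix.columns.equals(self.labels.index):
            raise DataValidationError(
                f"{self.name}: label index does not match sample columns"
            )
        if np.isnan(self.matrix.to_numpy(dtype=float)).any():
            raise DataValidationError(f"{self.name}: matrix contains missing values")
        classes = set(self.labels.unique())
        if not classes <= {CONTROL, CASE}:
            raise DataValidationError(f"{self.name}: labels must be 0/1, got {classes}")
        if len(classes) < 2:
            raise DataValidationError(
                f"{self.name}: labels contain a single class; need both case and control"
            )
        if self.metadata is not None and not self.metadata.index.equals(
            self.matrix.columns
        ):
            raise DataValidationError(f"{self.name}: metadata index mismatch")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return self.matrix.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_control, n_case)."""
        y = self.labels.to_numpy()
        return int((y == CONTROL).sum()), int((y == CASE).sum())

    def values(self, genes: Sequence[str] | None = None) -> np.ndarray:
        """Samples × genes float array (the ML orientation)."""
        m = self.matrix if genes is None else self.matrix.loc[list(genes)]
        return m.to_numpy(dtype=float).T


@dataclass
class StudyCollection:
    """Ordered cohorts sharing one gene universe in identical row order."""

    datasets: list[ExpressionDataset]
    gene_universe: list[str]

    def __post_init__(self) -> None:
        if len(self.datasets) < 2:
            raise DataValidationError("a StudyCollection needs at least 2 datasets")
        if not self.gene_universe:
            raise DataValidationError("empty gene universe")
        for ds in self.datasets:
            if ds.gene_ids != self.gene_universe:
                raise DataValidationError(
                    f"{ds.name}: gene ids differ from the collection's gene universe"
                )

    @property
    def names(self) -> list[str]:
        return [ds.name for ds in self.datasets]

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    def __getitem__(self, key: int | str) -> ExpressionDataset:
        if isinstance(key, str):
            for ds in self.datasets:
                if ds.name == key:
                    return ds
            raise KeyError(key)
        return self.datasets[key]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column ``sample_id`` / ``label`` table into a 0/1 series."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = {"sample_id", "label"}
    if not required <= set(table.columns):
        raise DataValidationError(
            f"{path}: label table needs columns {sorted(required)}"
        )
    values = table["label"].str.strip().str.lower()
    bad = sorted(set(values) - set(_LABEL_CODES))
    if bad:
        raise DataValidationError(
            f"{path}: unknown labels {bad}; expected 'case' or 'control'"
        )
    out = pd.Series(
        values.map(_LABEL_CODES).to_numpy(dtype=int),
        index=pd.Index(table["sample_id"].astype(str), name="sample_id"),
        name="label",
    )
    if out.index.duplicated().any():
        raise DataValidationError(f"{path}: duplicate sample ids in label table")
    return out


def read_expression_matrix(
    path: str | Path,
    labels_path: str | Path,
    platform: str,
    name: str,
) -> ExpressionDataset:
    """Read one cohort from a delimited matrix plus a label table.

    Gene symbols are upper-cased; rows with missing values are dropped
    (logged); duplicate symbols are collapsed keeping the highest-mean row
    (logged).  Every sample column must appear in the label table.
    """
    path = Path(path)
    matrix = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if matrix.size == 0:
        raise DataValidationError(f"{path}: empty expression matrix")
    matrix.index = matrix.index.astype(str).str.strip().str.upper()
    matrix.columns = matrix.columns.astype(str)
    matrix = matrix.astype(float)

    n_missing = int(matrix.isna().any(axis=1).sum())
    if n_missing:
        dropped = matrix.index[matrix.isna().any(axis=1)].tolist()
        logger.info("%s: dropping %d gene rows with missing values: %s",
                    name, n_missing, dropped[:10])
        matrix = matrix.dropna(axis=0)

    if matrix.index.duplicated().any():
        means = matrix.mean(axis=1)
        # keep, per symbol, the row with the highest mean expression
        order = np.lexsort((np.arange(len(matrix)), -means.to_numpy()))
        matrix = matrix.iloc[order]
        dup_mask = matrix.index.duplicated(keep="first")
        logger.info("%s: collapsing %d duplicate gene symbols (keeping highest mean)",
                    name, int(dup_mask.sum()))
        matrix = matrix[~dup_mask]
        matrix = matrix.sort_index()

    labels = read_labels(labels_path)
    missing = [s for s in matrix.columns if s not in labels.index]
    if missing:
        raise DataValidationError(
            f"{name}: samples absent from label table: {missing}"
        )
    labels = labels.loc[matrix.columns]
    return ExpressionDataset(name=name, matrix=matrix, labels=labels, platform=platform)


def write_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write a cohort back to the delimited formats :func:`read_expression_matrix` reads."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    out = dataset.matrix.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep=_sep_for(matrix_path), float_format="%.10g")
    names = dataset.labels.map({CONTROL: "control", CASE: "case"})
    pd.DataFrame({"sample_id": dataset.sample_ids, "label": names.to_numpy()}).to_csv(
        labels_path, sep=_sep_for(labels_path), index=False
    )


# ---------------------------------------------------------------------------
# harmonization & subsetting
# ---------------------------------------------------------------------------


def harmonize(
    datasets: Iterable[ExpressionDataset],
    transform: str = "none",
) -> StudyCollection:
    """Restrict cohorts to their common gene set, in lexicographic order.

    ``transform="log2p1"`` applies log2(x+1) to RNA-Seq cohorts only;
    microarray intensities are treated as already log-scale.
    """
    datasets = list(datasets)
    if len(datasets) < 2:
        raise DataValidationError("harmonize needs at least 2 datasets")
    if transform not in ("none", "log2p1"):
        raise DataValidationError(f"unknown transform {transform!r}")
    universe: set[str] = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        universe &= set(ds.gene_ids)
    if not universe:
        raise DataValidationError("gene-set intersection across cohorts is empty")
    order = sorted(universe)
    out = []
    for ds in datasets:
        matrix = ds.matrix.loc[order]
        if transform == "log2p1" and ds.platform == "rnaseq":
            matrix = np.log2(matrix + 1.0)
        out.append(
            ExpressionDataset(
                name=ds.name,
                matrix=matrix,
                labels=ds.labels,
                platform=ds.platform,
                metadata=ds.metadata,
            )
        )
    return StudyCollection(datasets=out, gene_universe=order)


def subset_samples(
    dataset: ExpressionDataset,
    keep: Callable[[pd.Series], bool],
) -> ExpressionDataset:
    """Filter samples by a predicate over per-sample annotations.

    The predicate receives one row per sample containing the ``label``
    (``"case"`` / ``"control"`` string) plus any metadata columns, and the
    retained subset must still contain both classes.
    """
    rows = pd.DataFrame(
        {"label": dataset.labels.map({CONTROL: "control", CASE: "case"})},
        index=dataset.matrix.columns,
    )
    if dataset.metadata is not None:
        rows = rows.join(dataset.metadata)
    mask = rows.apply(keep, axis=1).astype(bool)
    kept = rows.index[mask]
    labels = dataset.labels.loc[kept]
    if len(set(labels.unique())) < 2:
        raise DataValidationError(
            f"{dataset.name}: sample predicate leaves a single class"
        )
    return ExpressionDataset(
        name=dataset.name,
        matrix=dataset.matrix.loc[:, kept],
        labels=labels,
        platform=dataset.platform,
        metadata=dataset.metadata.loc[kept] if dataset.metadata is not None else None,
    )
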