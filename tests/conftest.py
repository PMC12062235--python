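import numpy as np
import pandas as pd
import pytest

from bivarscan import (
    ExpressionDataset,
    PairScoreTensor,
    enumerate_pairs,
    generate_collection,
    harmonize,
    preset,
)


def make_dataset(
    values: np.ndarray,
    labels: list[int],
    genes: list[str] | None = None,
    name: str = "toy",
    platform: str = "microarray",
) -> ExpressionDataset:
    """Build a validated cohort from a genes × samples array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    samples = [f"s{i + 1}" for i in range(values.shape[1])]
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionDataset(
        name=name,
        matrix=matrix,
        labels=pd.Series(labels, index=samples, name="label"),
        platform=platform,
    )


@pytest.fixture(scope="session")
def tiny_study():
    """The tiny synthetic preset, harmonized on the log scale, plus truth."""
    collection, truth = generate_collection(preset("tiny", seed=0))
    return harmonize(list(collection), transform="log2p1"), truth


@pytest.fixture
def toy_tensor():
    """3 genes × 2 cohorts with hand-picked scores for aggregation checks."""
    genes = ["A", "B", "C"]
    pairs = enumerate_pairs(genes)  # (A,B), (A,C), (B,C)
    scores = np.array(
        [
            [0.90, 0.60],  # (A,B)
            [0.75, 0.72],  # (A,C)
            [0.50, 0.95],  # (B,C)
        ]
    )
    return PairScoreTensor(
        genes=genes,
        pairs=pairs,
        dataset_names=["d1", "d2"],
        scores=scores,
        cv_folds=5,
        svm_c=100.0,
        seed=0,
    )


def random_tensor(seed: int, n_genes: int = 6, n_datasets: int = 3) -> PairScoreTensor:
    """Deterministic pseudo-random tensor for property tests."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    pairs = enumerate_pairs(genes)
    scores = rng.uniform(0.0, 1.0, size=(len(pairs), n_datasets))
    return PairScoreTensor(
        genes=genes,
        pairs=pairs,
        dataset_names=[f"d{i + 1}" for i in range(n_datasets)],
        scores=scores,
        cv_folds=5,
        svm_c=100.0,
        seed=seed,
    )
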