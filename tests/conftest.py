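import numpy as np
import pytest

from mirclass.core import (
    KIND_DESCRIPTOR,
    KIND_GENE,
    FeatureTable,
)
from mirclass.dataset_builder import build_table, filter_annotations
from mirclass.synthetic_cohort import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic training cohort (44 selected / 44 random), seed 1."""
    cfg = SyntheticConfig(seed=1)
    records, ann = generate_cohort(cfg)
    return cfg, records, ann


@pytest.fixture(scope="session")
def default_table(default_cohort):
    _, records, ann = default_cohort
    return build_table(records, filter_annotations(ann))


def random_binary_table(n_rows: int, n_features: int, seed: int) -> FeatureTable:
    """Random binary table with labels correlated to the first feature."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n_rows, n_features)).astype(float)
    flip = rng.random(n_rows) < 0.3
    y = np.where(flip, 1 - X[:, 0], X[:, 0]).astype(int)
    if len(np.unique(y)) < 2:  # force both classes
        y[0], y[1] = 0, 1
    return FeatureTable(
        row_ids=[f"r{i}" for i in range(n_rows)],
        feature_names=[f"f{j}" for j in range(n_features)],
        matrix=X,
        labels=["selected" if v else "random" for v in y],
        column_kinds=[KIND_GENE] * n_features,
    )


def tiny_numeric_table() -> FeatureTable:
    """Small mixed binary/numeric table for learner unit tests."""
    rng = np.random.default_rng(7)
    n = 40
    y = np.array([0, 1] * (n // 2))
    b = (rng.random(n) < np.where(y == 1, 0.85, 0.15)).astype(float)
    g = rng.normal(np.where(y == 1, 2.0, -2.0), 1.0)
    noise = rng.integers(0, 2, n).astype(float)
    return FeatureTable(
        row_ids=[f"r{i}" for i in range(n)],
        feature_names=["gene_sig", "num_sig", "gene_noise"],
        matrix=np.column_stack([b, g, noise]),
        labels=["selected" if v else "random" for v in y],
        column_kinds=[KIND_GENE, KIND_DESCRIPTOR, KIND_GENE],
    )
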