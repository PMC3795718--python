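"""Shared fixtures: small hand-built and generated datasets."""

import numpy as np
import pandas as pd
import pytest

from rsnr.dataset import ExpressionDataset
from rsnr.simulate import default_config, generate


def build_dataset(values: dict, metadata: list, provenance: str = "fixture") -> ExpressionDataset:
    """values: gene_id -> list of per-sample expression values;
    metadata: list of (sample_id, condition_id, factors, time_point, replicate)."""
    sample_ids = [m[0] for m in metadata]
    frame = pd.DataFrame(values, index=sample_ids).T
    frame.index.name = "gene_id"
    meta = pd.DataFrame(
        metadata,
        columns=["sample_id", "condition_id", "factors", "time_point", "replicate"],
    ).set_index("sample_id")
    return ExpressionDataset(frame, meta, provenance=provenance)


@pytest.fixture
def two_condition_ds() -> ExpressionDataset:
    """2 conditions x 2 time points x 2 replicates, 3 genes, disjoint factors."""
    meta = [
        ("a_t0_r1", "condA", "facA", 0.0, 1),
        ("a_t0_r2", "condA", "facA", 0.0, 2),
        ("a_t1_r1", "condA", "facA", 1.0, 1),
        ("a_t1_r2", "condA", "facA", 1.0, 2),
        ("b_t0_r1", "condB", "facB", 0.0, 1),
        ("b_t0_r2", "condB", "facB", 0.0, 2),
        ("b_t1_r1", "condB", "facB", 1.0, 1),
        ("b_t1_r2", "condB", "facB", 1.0, 2),
    ]
    values = {
        "g1": [1.0, 1.2, 2.0, 2.2, 5.0, 5.2, 4.0, 4.2],
        "g2": [3.0, 3.1, 3.5, 3.6, 1.0, 1.1, 1.5, 1.6],
        "g3": [2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
    }
    return build_dataset(values, meta)


@pytest.fixture(scope="session")
def small_planted():
    """Generated dataset small enough for fast CV tests, with ground truth."""
    cfg = default_config(n_genes=240, n_planted_per_condition=6, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
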