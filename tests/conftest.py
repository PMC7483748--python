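"""Shared fixtures: a small simulated knowledgebase and its derived objects.

Everything is generated at test time; the expensive pipeline stages are
session-scoped so many tests can share one knowledgebase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from geneprio import pipeline, synthetic
from geneprio.types import ExpressionMatrix


@pytest.fixture(scope="session")
def kb_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("kb")
    synthetic.simulate_knowledgebase(synthetic.SMALL, out)
    return out


@pytest.fixture(scope="session")
def truth():
    # same config/seed as kb_dir; the generator is deterministic
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        _, t = synthetic.simulate_knowledgebase(synthetic.SMALL, d)
    return t


@pytest.fixture(scope="session")
def kb(kb_dir):
    return pipeline.load_knowledgebase(kb_dir)


@pytest.fixture(scope="session")
def sources(kb):
    return pipeline.prepare_sources(kb)


@pytest.fixture(scope="session")
def training_data(kb, sources):
    return pipeline.build_training_data(kb, sources, seed=1)


def make_expression(values: np.ndarray, tissues: list[str],
                    mapped_reads: list[int] | None = None) -> ExpressionMatrix:
    """Small helper: wrap an array into an ExpressionMatrix with metadata."""
    n_genes, n_samples = values.shape
    gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    if mapped_reads is None:
        mapped_reads = [10_000_000] * n_samples
    vals = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame({"tissue": tissues, "mapped_reads": mapped_reads},
                        index=sample_ids)
    return ExpressionMatrix(vals, meta)
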