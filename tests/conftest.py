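import logging

import numpy as np
import pandas as pd
import pytest

from mastreg.containers import ExpressionMatrix, Regulon

logging.disable(logging.INFO)  # keep Monte-Carlo tests quiet; warnings still shown


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_matrix(values, gene_ids=None, sample_ids=None, groups=None, batches=None):
    """Small ExpressionMatrix builder used across test modules."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "group": groups if groups is not None else ["unlabeled"] * n_samples,
            "batch": batches if batches is not None else ["batch0"] * n_samples,
            "cohort": "cohort0",
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), meta)


def make_regulon(tf, targets, mor, likelihood):
    return Regulon(
        tf,
        pd.DataFrame(
            {"mor": np.asarray(mor, dtype=float), "likelihood": np.asarray(likelihood, float)},
            index=pd.Index(list(targets), name="target"),
        ),
    )


@pytest.fixture
def two_group_matrix(rng):
    """30 genes x (6 treated + 6 control), pure noise around a baseline."""
    values = 7.0 + rng.normal(0, 0.5, size=(30, 12))
    return make_matrix(values, groups=["treated"] * 6 + ["control"] * 6)
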