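import numpy as np
import pandas as pd
import pytest

from flowsig.datatypes import ExpressionDataset, PhenotypeTable, QuerySet


def make_dataset(values, genes, samples=None, dataset_id="DS", species="human"):
    values = np.asarray(values, dtype=float)
    if samples is None:
        samples = [f"S{j}" for j in range(values.shape[1])]
    return ExpressionDataset(dataset_id, species, pd.DataFrame(values, index=genes, columns=samples))


def exact_correlated_dataset(corr, n_samples, genes, extra_noise_genes=0, seed=0):
    """Rows with EXACT sample correlation matrix ``corr`` (Cholesky on an
    orthonormal, mean-zero basis), plus optional pure-noise rows."""
    rng = np.random.default_rng(seed)
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    A = rng.normal(size=(n_samples, k))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    L = np.linalg.cholesky(corr)
    X = (Q @ L.T).T  # rows: exact correlations, mean zero
    rows = [X]
    if extra_noise_genes:
        rows.append(rng.normal(size=(extra_noise_genes, n_samples)))
    mat = np.vstack(rows)
    all_genes = list(genes) + [f"NOISE{i}" for i in range(extra_noise_genes)]
    return make_dataset(mat, all_genes)


@pytest.fixture
def small_dataset():
    return make_dataset(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [0.5, 0.5, 1.5, 1.5]],
        ["A", "B", "C"],
    )


@pytest.fixture
def simple_phenotypes():
    return PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": ["S0", "S1", "S2", "S3"],
                "cuspidity": ["BAV", "BAV", "TAV", "TAV"],
                "dilation": [0, 1, 0, 1],
                "stenosis": [0, 0, 0, 0],
                "regurgitation": [0, 0, 0, 0],
            }
        )
    )


@pytest.fixture
def two_queries():
    return QuerySet("q", ["Q1", "Q2"])
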